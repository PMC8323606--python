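"""Irreducible spherical-tensor operator basis for a spin-3/2 nucleus.

The density operator of an isolated spin-3/2 system (minus the identity)
lives in a 15-dimensional space spanned by unit-normalized irreducible
tensor operators ``T_lm`` with rank ``l`` in {1, 2, 3} and coherence order
``m`` in {-l, ..., l}.  All dynamics in :mod:`na_contrast.spin32` are
expressed as 15x15 superoperators on the coefficient vector in this basis.

Conventions
-----------
* ``T_lm`` are orthonormal under the Frobenius inner product
  ``Tr(A^H B)``.
* ``T_ll`` is proportional to ``(I+)^l`` with sign ``(-1)^l``; lower-``m``
  members follow from the commutator lowering relation
  ``[I-, T_lm] = sqrt((l+m)(l-m+1)) T_{l,m-1}``.
* Hermiticity of the density operator translates to
  ``a_{l,-m} = (-1)^m conj(a_{l,m})`` for the coefficient vector ``a``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DIM",
    "BASIS_KEYS",
    "spin_operators",
    "tensor_basis",
    "liouvillian_of",
    "index_of",
]

DIM = 4  # Hilbert-space dimension for spin 3/2

#: ordering of the coefficient vector: (l, m), l = 1..3, m = -l..l
BASIS_KEYS: tuple[tuple[int, int], ...] = tuple(
    (l, m) for l in (1, 2, 3) for m in range(-l, l + 1)
)

_INDEX = {k: i for i, k in enumerate(BASIS_KEYS)}


def index_of(l: int, m: int) -> int:
    """Position of the ``T_lm`` coefficient in the 15-vector."""
    return _INDEX[(l, m)]


def spin_operators() -> dict[str, np.ndarray]:
    """Cartesian and ladder angular-momentum matrices for spin 3/2."""
    j = 1.5
    ms = np.array([1.5, 0.5, -0.5, -1.5])
    Iz = np.diag(ms).astype(complex)
    Ip = np.zeros((DIM, DIM), dtype=complex)
    for i in range(1, DIM):
        m = ms[i]
        Ip[i - 1, i] = np.sqrt(j * (j + 1) - m * (m + 1))
    Im = Ip.conj().T
    Ix = (Ip + Im) / 2.0
    Iy = (Ip - Im) / 2.0j
    return {"Ix": Ix, "Iy": Iy, "Iz": Iz, "Ip": Ip, "Im": Im}


def _frob(a: np.ndarray, b: np.ndarray) -> complex:
    return complex(np.trace(a.conj().T @ b))


def tensor_basis() -> dict[tuple[int, int], np.ndarray]:
    """Unit-normalized irreducible tensor operators ``T_lm`` for spin 3/2."""
    ops = spin_operators()
    Ip, Im = ops["Ip"], ops["Im"]
    T: dict[tuple[int, int], np.ndarray] = {}
    for l in (1, 2, 3):
        top = np.linalg.matrix_power(Ip, l)
        top = top / np.sqrt(np.real(_frob(top, top)))
        T[(l, l)] = ((-1) ** l) * top
        for m in range(l, -l, -1):
            low = Im @ T[(l, m)] - T[(l, m)] @ Im
            T[(l, m - 1)] = low / np.sqrt((l + m) * (l - m + 1))
    return T


def liouvillian_of(action) -> np.ndarray:
    """Matrix of a linear operator-space map in the ``T_lm`` basis.

    ``action`` maps a 4x4 operator to a 4x4 operator; the returned 15x15
    matrix ``L`` satisfies ``L a = coefficients of action(rho(a))``.
    """
    T = tensor_basis()
    L = np.zeros((15, 15), dtype=complex)
    for col, bk in enumerate(BASIS_KEYS):
        out = action(T[bk])
        for row, ak in enumerate(BASIS_KEYS):
            L[row, col] = _frob(T[ak], out)
    return L
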
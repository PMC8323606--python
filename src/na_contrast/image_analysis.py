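"""Sodium image-analysis steps: PSF, CSF-mask expansion, ROI statistics.

Center-out sodium acquisitions sample the k-space center first, so the
rapid T2* decay of sodium acts as a low-pass k-space filter and widens
the point spread function (PSF).  CSF (150 mM, roughly four times
tissue sodium) therefore bleeds far outside its anatomical boundary;
voxels whose PSF-convolved CSF fraction exceeds a small threshold
(default 0.025, i.e. an effective 3.75 mmol/L-tissue of stray CSF
signal) are excluded from tissue regions of interest.

The PSF model is a center-out radial-equivalent: k-space sampling time
grows linearly with |k| over the readout duration, apodizing k-space by
``exp(-t(k)/T2*)``.  The actual twisted-projection trajectory is not
published, so the readout duration is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PSFParams",
    "ROIStats",
    "psf_kernel",
    "expand_csf_mask",
    "effective_csf_contribution",
    "roi_statistics",
    "intensity_to_tsc",
    "convolve_psf",
]


@dataclass(frozen=True)
class PSFParams:
    """Point-spread-function parameters.

    ``t2star`` in ms (saline default 53 ms at 4.7 T), ``readout_duration``
    in ms, anisotropic ``voxel_size`` in mm, ``grid_shape`` in voxels.
    """

    t2star: float = 53.0
    readout_duration: float = 10.0
    voxel_size: tuple[float, float, float] = (3.2, 3.2, 6.4)
    grid_shape: tuple[int, int, int] = (32, 32, 16)

    def __post_init__(self) -> None:
        if self.t2star <= 0:
            raise ValueError("t2star must be > 0")
        if self.readout_duration < 0:
            raise ValueError("readout_duration must be >= 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must be > 0")
        if any(n < 2 for n in self.grid_shape):
            raise ValueError("grid must have at least 2 voxels per axis")


@dataclass(frozen=True)
class ROIStats:
    """Summary statistics of one region of interest."""

    label: str
    mean: float
    sd: float
    n_voxels: int
    n_excluded: int

    def __post_init__(self) -> None:
        if self.n_voxels < 0 or self.n_excluded < 0:
            raise ValueError("voxel counts must be >= 0")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _kspace_time_fraction(shape: tuple[int, int, int], voxel: tuple[float, float, float]) -> np.ndarray:
    """|k| / k_max on the FFT grid (fraction of the readout)."""
    axes = [np.fft.fftfreq(n, d=d) for n, d in zip(shape, voxel)]
    kx, ky, kz = np.meshgrid(*axes, indexing="ij")
    kr = np.sqrt(kx**2 + ky**2 + kz**2)
    kmax = min(0.5 / d for d in voxel)  # first-truncated axis sets k_max
    return np.minimum(kr / kmax, 1.0)


def psf_kernel(p: PSFParams) -> np.ndarray:
    """Peak-normalized PSF on the image grid.

    k-space is apodized by ``exp(-t(k)/T2*)`` with sampling time linear
    in |k| (center-out readout); the kernel is its inverse transform,
    centered in the volume, with peak value exactly 1.
    """
    frac = _kspace_time_fraction(p.grid_shape, p.voxel_size)
    apod = np.exp(-(frac * p.readout_duration) / p.t2star)
    kern = np.fft.fftshift(np.real(np.fft.ifftn(apod)))
    peak = kern.flat[np.abs(kern).argmax()]
    return kern / peak


def convolve_psf(volume: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-padded FFT convolution of a volume with a centered kernel.

    The kernel is normalized to unit sum so a voxel deep inside a uniform
    region keeps its value ("full value" semantics).
    """
    if volume.shape != kernel.shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match kernel shape {kernel.shape}"
        )
    k = kernel / kernel.sum()
    shape = volume.shape
    padded = [2 * n for n in shape]
    center = tuple(n // 2 for n in shape)  # fftshift center of the kernel
    vol_p = np.zeros(padded)
    vol_p[tuple(slice(0, n) for n in shape)] = volume.astype(float)
    k_p = np.zeros(padded)
    k_p[tuple(slice(0, n) for n in shape)] = k
    # align the kernel center with the origin of the padded grid
    k_p = np.roll(k_p, [-c for c in center], axis=(0, 1, 2))
    out = np.fft.ifftn(np.fft.fftn(vol_p) * np.fft.fftn(k_p)).real
    return out[tuple(slice(0, n) for n in shape)]


def expand_csf_mask(
    csf_mask: np.ndarray, kernel: np.ndarray, threshold: float = 0.025
) -> np.ndarray:
    """Expand a binary CSF mask to all voxels with PSF spill above threshold.

    The mask is convolved with the (sum-normalized) PSF; the output marks
    voxels whose convolved value exceeds ``threshold`` (2.5% of the full
    CSF value by default) and is always a superset of the input mask.
    """
    csf_mask = np.asarray(csf_mask)
    if not np.isin(csf_mask, (0, 1)).all():
        raise ValueError("csf_mask must be binary")
    spill = convolve_psf(csf_mask.astype(float), kernel)
    return ((spill > threshold) | (csf_mask > 0)).astype(np.uint8)


def effective_csf_contribution(threshold: float = 0.025, c_csf: float = 150.0) -> float:
    """Stray CSF signal admitted at the mask threshold (mmol/L-tissue)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    return threshold * c_csf


def roi_statistics(
    image: np.ndarray,
    roi_mask: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
    label: str = "roi",
) -> ROIStats:
    """Mean/SD of image intensity over a region, minus excluded voxels.

    Raises if no voxels survive the exclusion (regions bordering CSF may
    not retain enough uncontaminated voxels to analyze).
    """
    image = np.asarray(image, dtype=float)
    roi = np.asarray(roi_mask) > 0
    if image.shape != roi.shape:
        raise ValueError("image and roi_mask shapes differ")
    if exclusion_mask is not None:
        excl = np.asarray(exclusion_mask) > 0
        if excl.shape != roi.shape:
            raise ValueError("exclusion_mask shape differs")
        keep = roi & ~excl
    else:
        keep = roi
    n_excl = int(roi.sum() - keep.sum())
    if keep.sum() == 0:
        raise ValueError(
            f"region {label!r} retains no voxels after CSF exclusion"
        )
    vals = image[keep]
    return ROIStats(
        label=label,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        n_voxels=int(keep.sum()),
        n_excluded=n_excl,
    )


def intensity_to_tsc(relative_intensity: float, c_agar: float = 64.0) -> float:
    """Convert agar-relative image intensity to TSC (mmol/L-tissue).

    The reference tubes have a known concentration (64 mM), so TSC is the
    relative intensity times that concentration; linear and invertible.
    """
    if relative_intensity < 0:
        raise ValueError("relative_intensity must be >= 0")
    return relative_intensity * c_agar
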
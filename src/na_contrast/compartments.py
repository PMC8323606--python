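"""Multi-compartment sodium bookkeeping for white matter.

White matter tissue is modeled as five volume compartments per liter of
reference tissue: myelin water (the thin ordered water layers between
myelin wraps), intracellular water, extracellular water, edema (added
free water, lesions only) and non-aqueous solids.  Each aqueous
compartment carries a fixed sodium concentration; summing
``volume fraction x concentration`` gives the compartment contributions
in mmol per liter of tissue and their total, the tissue sodium
concentration (TSC).

Because the intra- and extracellular layers inside myelin have equal
thickness, myelin water sodium is the plain average of the intra- and
extracellular concentrations: (12.5 + 145) / 2 = 78.75 mM.

Demyelination removes myelin water and its associated solids (ratio
``k`` solids per unit myelin water, default 1.5, i.e. myelin is ~40%
water); the lost volume shrinks the tissue (atrophy), which raises the
relative volume fractions of the untouched intra-/extracellular spaces
even though their absolute volumes are unchanged.  Lesions additionally
gain edema volume at free-water sodium concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "SodiumConcentrations",
    "CompartmentVolumes",
    "DemyelinationParams",
    "SodiumContributions",
    "TissueModelParams",
    "myelin_water_concentration",
    "control_volumes",
    "volumes_from_mwf_wc",
    "mwf_wc_of",
    "sodium_contributions",
    "apply_demyelination",
    "tsc_percent_difference",
    "tissue_states",
    "NAWM_PARAMS",
    "LESION_PARAMS",
]

_SUM_TOL = 1e-9


def myelin_water_concentration(c_intra: float = 12.5, c_extra: float = 145.0) -> float:
    """Average sodium concentration of the myelin water layers (mM).

    The intra- and extracellular layers within myelin have equal
    thickness, so the myelin water concentration is their plain average.
    """
    if c_intra < 0 or c_extra < 0:
        raise ValueError("concentrations must be >= 0")
    return (c_intra + c_extra) / 2.0


@dataclass(frozen=True)
class SodiumConcentrations:
    """Compartment sodium concentrations in mM (mmol/L of compartment water)."""

    c_intra: float = 12.5
    c_extra: float = 145.0
    c_edema: float = 145.0  # extracellular-like free water
    c_csf: float = 150.0
    c_agar: float = 64.0
    c_myelin: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.c_myelin is None:
            object.__setattr__(
                self, "c_myelin", myelin_water_concentration(self.c_intra, self.c_extra)
            )
        for name in ("c_intra", "c_extra", "c_myelin", "c_edema", "c_csf", "c_agar"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CompartmentVolumes:
    """Volume fractions of one liter of (current) tissue.

    ``volume_scale`` tracks the current tissue volume relative to the
    1 L healthy reference, so absolute compartment volumes are
    ``fraction * volume_scale`` liters.
    """

    v_myelin_water: float
    v_intra: float
    v_extra: float
    v_edema: float
    v_solids: float
    volume_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("v_myelin_water", "v_intra", "v_extra", "v_edema", "v_solids"):
            if getattr(self, name) < -_SUM_TOL:
                raise ValueError(f"{name} must be >= 0")
        total = (
            self.v_myelin_water + self.v_intra + self.v_extra + self.v_edema + self.v_solids
        )
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"volume fractions must sum to 1, got {total}")
        if self.volume_scale <= 0:
            raise ValueError("volume_scale must be > 0")

    @property
    def water_content(self) -> float:
        """WC: total water volume fraction of tissue."""
        return self.v_myelin_water + self.v_intra + self.v_extra + self.v_edema

    @property
    def myelin_water_fraction(self) -> float:
        """MWF: myelin water volume / total water volume."""
        return self.v_myelin_water / self.water_content


@dataclass(frozen=True)
class DemyelinationParams:
    """Demyelination / edema transform parameters.

    ``retention`` is the fraction of myelin water kept; ``k`` the myelin
    solids removed per unit of removed myelin water; ``edema_added`` the
    absolute free-water volume gained per liter of original tissue.
    """

    retention: float
    k: float = 1.5
    edema_added: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.retention <= 1.0):
            raise ValueError("retention must be in [0, 1]")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.edema_added < 0:
            raise ValueError("edema_added must be >= 0")


#: calibrated defaults reproducing the published atrophy and contrast numbers
NAWM_PARAMS = DemyelinationParams(retention=0.80, k=1.5, edema_added=0.0)
LESION_PARAMS = DemyelinationParams(retention=0.45, k=1.5, edema_added=0.089)


@dataclass(frozen=True)
class SodiumContributions:
    """Per-compartment sodium content of 1 L tissue (mmol/L-tissue)."""

    q_myelin: float
    q_intra: float
    q_extra: float
    q_edema: float

    def __post_init__(self) -> None:
        for name in ("q_myelin", "q_intra", "q_extra", "q_edema"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def tsc(self) -> float:
        """Tissue sodium concentration: total mmol per liter of tissue."""
        return self.q_myelin + self.q_intra + self.q_extra + self.q_edema

    def as_dict(self) -> dict[str, float]:
        return {
            "myelin": self.q_myelin,
            "intra": self.q_intra,
            "extra": self.q_extra,
            "edema": self.q_edema,
            "tsc": self.tsc,
        }


@dataclass(frozen=True)
class TissueModelParams:
    """Myelin water fraction and water content of a tissue state."""

    MWF: float
    WC: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.MWF < 1.0):
            raise ValueError("MWF must be in [0, 1)")
        if not (0.0 < self.WC < 1.0):
            raise ValueError("WC must be in (0, 1)")


def control_volumes() -> CompartmentVolumes:
    """Healthy control white matter volume fractions.

    The exact fractions are back-solved from the published per-compartment
    sodium contributions (6.2 / 6.8 / total 37.9 mmol per liter of
    tissue); rounded to the nearest percent they are the familiar
    9% myelin water, 17% extracellular, 50% intracellular.
    """
    v_m, v_e, v_i = 0.0865, 0.172, 0.495
    return CompartmentVolumes(
        v_myelin_water=v_m,
        v_intra=v_i,
        v_extra=v_e,
        v_edema=0.0,
        v_solids=1.0 - v_m - v_e - v_i,
        volume_scale=1.0,
    )


def volumes_from_mwf_wc(
    params: TissueModelParams, v_extra_fixed: float = 0.172
) -> CompartmentVolumes:
    """Compartment volumes from a (MWF, WC) pair with fixed extracellular fraction.

    ``v_myelin_water = MWF * WC``; the intracellular fraction absorbs the
    remaining water.  Raises if the pair is infeasible (negative
    intracellular volume).
    """
    if v_extra_fixed > params.WC:
        raise ValueError("extracellular fraction exceeds total water content")
    v_m = params.MWF * params.WC
    v_i = params.WC - v_m - v_extra_fixed
    if v_i < 0:
        raise ValueError(
            f"inconsistent MWF/WC pair: implied intracellular volume {v_i:.4f} < 0"
        )
    return CompartmentVolumes(
        v_myelin_water=v_m,
        v_intra=v_i,
        v_extra=v_extra_fixed,
        v_edema=0.0,
        v_solids=1.0 - params.WC,
    )


def mwf_wc_of(vols: CompartmentVolumes) -> TissueModelParams:
    """The (MWF, WC) pair describing an edema-free volume set."""
    return TissueModelParams(MWF=vols.myelin_water_fraction, WC=vols.water_content)


def sodium_contributions(
    vols: CompartmentVolumes, concs: SodiumConcentrations | None = None
) -> SodiumContributions:
    """mmol of sodium each water compartment contributes to 1 L of tissue."""
    if concs is None:
        concs = SodiumConcentrations()
    return SodiumContributions(
        q_myelin=vols.v_myelin_water * concs.c_myelin,
        q_intra=vols.v_intra * concs.c_intra,
        q_extra=vols.v_extra * concs.c_extra,
        q_edema=vols.v_edema * concs.c_edema,
    )


def apply_demyelination(
    vols: CompartmentVolumes, p: DemyelinationParams
) -> tuple[CompartmentVolumes, float]:
    """Demyelinate (and optionally add edema to) a tissue state.

    Removes ``(1 - retention)`` of the myelin water together with ``k``
    times as much myelin solids; the absolute intra-/extracellular
    volumes stay fixed, the tissue shrinks (atrophy) or swells (edema),
    and all fractions are renormalized to the new volume.

    Returns the new volumes and the fractional volume change of the
    tissue (e.g. ``-0.043`` for 4.3% atrophy).
    """
    removed_myelin_water = (1.0 - p.retention) * vols.v_myelin_water
    removed = removed_myelin_water * (1.0 + p.k)
    removed_solids = removed_myelin_water * p.k
    if removed_solids > vols.v_solids + _SUM_TOL:
        raise ValueError("demyelination removes more solids than the tissue contains")
    new_total = 1.0 - removed + p.edema_added  # relative to current volume
    if new_total <= 0:
        raise ValueError("demyelination removes the entire tissue volume")
    new = CompartmentVolumes(
        v_myelin_water=p.retention * vols.v_myelin_water / new_total,
        v_intra=vols.v_intra / new_total,
        v_extra=vols.v_extra / new_total,
        v_edema=(vols.v_edema + p.edema_added) / new_total,
        v_solids=(vols.v_solids - removed_solids) / new_total,
        volume_scale=vols.volume_scale * new_total,
    )
    volume_change = new.volume_scale / vols.volume_scale - 1.0
    return new, volume_change


def tsc_percent_difference(
    state: SodiumContributions, ref: SodiumContributions
) -> float:
    """Percent TSC difference of ``state`` relative to ``ref``."""
    if ref.tsc <= 0:
        raise ValueError("reference TSC must be > 0")
    return 100.0 * (state.tsc / ref.tsc - 1.0)


def tissue_states(
    nawm: DemyelinationParams = NAWM_PARAMS,
    lesion: DemyelinationParams = LESION_PARAMS,
    concs: SodiumConcentrations | None = None,
) -> dict[str, SodiumContributions]:
    """Sodium contribution sets for the three modeled white-matter states.

    ``control`` is healthy white matter; ``nawm`` applies demyelination
    with atrophy (retention 0.80 -> 4.3% volume loss); ``lesion`` applies
    stronger demyelination plus edema (retention 0.45, +0.089 L free
    water per original liter).
    """
    ctrl = control_volumes()
    nawm_vols, _ = apply_demyelination(ctrl, nawm)
    lesion_vols, _ = apply_demyelination(ctrl, lesion)
    return {
        "control": sodium_contributions(ctrl, concs),
        "nawm": sodium_contributions(nawm_vols, concs),
        "lesion": sodium_contributions(lesion_vols, concs),
    }
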
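"""Synthetic brain-like sodium phantom and cohort generator.

No raw study data are distributable, so every downstream stage is
exercised on seeded synthetic phantoms: a brain-shaped label volume with
white-matter tract regions (splenium of corpus callosum, posterior and
anterior limbs of the internal capsule), a gray-matter shell,
ventricular CSF, bilateral agar reference tubes at 64 mM, and a
configurable set of lesions from single-voxel up to several milliliters.

Rendering assigns each region the forward-model prediction of its tissue
state for the requested sequence (compartment sodium contributions
weighted by the sequence relaxation weightings, expressed relative to
the agar reference), convolves with the T2*-driven point spread
function and adds Rician noise.  The cohort simulator works at ROI level
and emulates between-subject biology as a multiplicative factor on the
compartment volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .compartments import SodiumConcentrations, tissue_states
from .image_analysis import PSFParams, convolve_psf, psf_kernel
from .signal_model import PRINTED_RW

__all__ = [
    "ImageVolume",
    "RegionSpec",
    "PhantomSpec",
    "GroundTruth",
    "build_phantom",
    "region_signal",
    "render_sodium_image",
    "simulate_cohort",
    "default_phantom_spec",
]

#: agar reference relaxation weighting per sequence (simulator output for
#: the shipped calibrated agar environment, frozen for table2-fixed use)
AGAR_RW: dict[str, float] = {"NaDW": 0.9438, "NaPACMAN": 0.3335, "NaSIRFLA": 0.4555}
#: csf relaxation weighting per sequence (same provenance)
CSF_RW: dict[str, float] = {"NaDW": 0.9580, "NaPACMAN": 0.4452, "NaSIRFLA": 0.0691}

_WM_REGIONS = ("scc", "plic", "alic")


@dataclass
class ImageVolume:
    """A voxel volume with physical voxel size and NIfTI affine."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.isfinite(self.data[np.isfinite(self.data)]).all() or not np.isfinite(
            self.data
        ).all():
            raise ValueError("image contains non-finite values")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must be > 0")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])

    def to_nifti(self) -> nib.Nifti1Image:
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        return nib.Nifti1Image(data, self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data=np.asarray(img.dataobj), voxel_size=zooms, affine=img.affine)


@dataclass(frozen=True)
class RegionSpec:
    """An ellipsoidal region: center and semi-axes in voxel units."""

    name: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    state: str  # control | nawm | lesion | csf | agar

    def __post_init__(self) -> None:
        if self.state not in ("control", "nawm", "lesion", "csf", "agar"):
            raise ValueError(f"unknown tissue state {self.state!r}")


@dataclass
class PhantomSpec:
    """Layout of the synthetic phantom."""

    grid_shape: tuple[int, int, int] = (48, 48, 24)
    voxel_size: tuple[float, float, float] = (3.2, 3.2, 6.4)
    wm_state: str = "control"
    lesions: tuple[RegionSpec, ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid too small for the phantom layout")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class GroundTruth:
    """True relative intensity per region per sequence, and lesion sizes."""

    intensity: dict[str, dict[str, float]]  # region -> sequence -> value
    lesion_voxels: dict[str, int] = field(default_factory=dict)
    label_of: dict[str, int] = field(default_factory=dict)
    state_of: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intensity": self.intensity,
                    "lesion_voxels": self.lesion_voxels,
                    "label_of": self.label_of,
                    "state_of": self.state_of,
                },
                fh,
                indent=2,
            )


def default_phantom_spec(
    wm_state: str = "control", lesion_state: str = "lesion", seed: int = 0
) -> PhantomSpec:
    """Brain-like phantom with three tract ROIs and six lesions (1 to >50 voxels)."""
    lesions = (
        RegionSpec("lesion_1vox", (14.0, 30.0, 12.0), (0.55, 0.55, 0.5), lesion_state),
        RegionSpec("lesion_small", (32.0, 30.0, 12.0), (1.2, 1.2, 0.8), lesion_state),
        RegionSpec("lesion_mid", (14.0, 17.0, 9.0), (1.8, 1.8, 1.0), lesion_state),
        RegionSpec("lesion_large", (33.0, 17.0, 9.0), (2.6, 2.6, 1.4), lesion_state),
        RegionSpec("lesion_xl", (24.0, 33.0, 15.0), (2.9, 2.9, 1.6), lesion_state),
        RegionSpec("lesion_xxl", (24.0, 14.0, 12.0), (3.6, 3.6, 2.0), lesion_state),
    )
    return PhantomSpec(wm_state=wm_state, lesions=lesions, seed=seed)


def _ellipsoid(shape, center, radii) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    d = sum(((idx[i] - center[i]) / radii[i]) ** 2 for i in range(3))
    return d <= 1.0


def build_phantom(spec: PhantomSpec) -> tuple[ImageVolume, GroundTruth, dict[str, int]]:
    """Deterministic label volume + ground truth for a phantom spec.

    Returns the label volume, the ground truth (filled with per-sequence
    relative intensities by :func:`region_signal`), and the name->label
    mapping.  Raises if agar tubes would overlap the brain.
    """
    nx, ny, nz = spec.grid_shape
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    names: dict[str, int] = {}

    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    brain_r = (nx * 0.30, ny * 0.36, nz * 0.40)
    brain = _ellipsoid(spec.grid_shape, (cx, cy, cz), brain_r)
    gm_inner = _ellipsoid(
        spec.grid_shape, (cx, cy, cz), tuple(r * 0.82 for r in brain_r)
    )

    def put(name: str, mask: np.ndarray, label: int) -> None:
        labels[mask] = label
        names[name] = label

    put("wm", gm_inner, 1)
    put("gm", brain & ~gm_inner, 2)
    # ventricles: two parasagittal CSF ellipsoids
    vent = _ellipsoid(spec.grid_shape, (cx - 3.5, cy + 1, cz), (2.2, 5.0, 2.2)) | _ellipsoid(
        spec.grid_shape, (cx + 3.5, cy + 1, cz), (2.2, 5.0, 2.2)
    )
    put("ventricles", vent & gm_inner, 3)
    # WM tract ROIs around the ventricles
    put("scc", _ellipsoid(spec.grid_shape, (cx, cy - 6.5, cz), (4.0, 2.2, 1.6)) & gm_inner & ~vent, 4)
    put("plic", _ellipsoid(spec.grid_shape, (cx - 8, cy - 2, cz), (2.0, 3.0, 1.6)) & gm_inner & ~vent, 5)
    put("alic", _ellipsoid(spec.grid_shape, (cx + 8, cy - 2, cz), (2.0, 3.0, 1.6)) & gm_inner & ~vent, 6)
    # bilateral agar tubes: z-axis cylinders outside the head
    xs = np.arange(nx)[:, None, None]
    ys = np.arange(ny)[None, :, None]
    tube_r2 = 2.0**2
    left = ((xs - 2.5) ** 2 + (ys - cy) ** 2) <= tube_r2
    right = ((xs - (nx - 3.5)) ** 2 + (ys - cy) ** 2) <= tube_r2
    tubes = np.broadcast_to(left | right, spec.grid_shape).copy()
    tubes[:, :, : nz // 6] = False
    tubes[:, :, -nz // 6 :] = False
    if (tubes & brain).any():
        raise ValueError("agar tubes overlap the brain")
    put("agar", tubes, 7)

    truth = GroundTruth(intensity={}, label_of=dict(names))
    truth.state_of = {
        "wm": spec.wm_state,
        "gm": "control",
        "ventricles": "csf",
        "scc": spec.wm_state,
        "plic": spec.wm_state,
        "alic": spec.wm_state,
        "agar": "agar",
    }
    next_label = 10
    for les in spec.lesions:
        mask = _ellipsoid(spec.grid_shape, les.center, les.radii)
        mask &= labels == 1  # carve lesions out of background WM only
        if not mask.any():
            raise ValueError(f"lesion {les.name!r} contains no voxels")
        put(les.name, mask, next_label)
        truth.state_of[les.name] = les.state
        truth.lesion_voxels[les.name] = int(mask.sum())
        next_label += 1
    truth.label_of = dict(names)
    return (
        ImageVolume(data=labels, voxel_size=spec.voxel_size),
        truth,
        names,
    )


def region_signal(
    state: str,
    sequence: str,
    rw: dict[str, dict[str, float]] | None = None,
    agar_rw: dict[str, float] | None = None,
    csf_rw: dict[str, float] | None = None,
    concs: SodiumConcentrations | None = None,
    ideal_reference: bool = False,
) -> float:
    """Forward-model relative intensity of a tissue state for one sequence.

    Tissue voxel value = sum of compartment sodium contributions weighted
    by the sequence relaxation weighting, divided by the agar reference
    ``c_agar * RW[agar]``; ``ideal_reference=True`` sets all reference
    weightings to 1 (pure sodium-density calibration).
    """
    rw = PRINTED_RW if rw is None else rw
    agar_rw = AGAR_RW if agar_rw is None else agar_rw
    csf_rw = CSF_RW if csf_rw is None else csf_rw
    concs = SodiumConcentrations() if concs is None else concs
    ref = concs.c_agar * (1.0 if ideal_reference else agar_rw[sequence])
    if state == "agar":
        return concs.c_agar * (1.0 if ideal_reference else agar_rw[sequence]) / ref
    if state == "csf":
        return concs.c_csf * (1.0 if ideal_reference else csf_rw[sequence]) / ref
    states = tissue_states(concs=concs)
    if state not in states:
        raise KeyError(f"unknown tissue state {state!r}")
    q = states[state]
    w = rw[sequence]
    sig = (
        q.q_intra * (1.0 if ideal_reference else w["intra"])
        + q.q_extra * (1.0 if ideal_reference else w["extra"])
        + q.q_myelin * (1.0 if ideal_reference else w["myelin"])
        + q.q_edema * (1.0 if ideal_reference else w["edema"])
    )
    return sig / ref


def render_sodium_image(
    labels: ImageVolume,
    truth: GroundTruth,
    sequence: str,
    rw: dict[str, dict[str, float]] | None = None,
    psf: PSFParams | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    ideal_reference: bool = False,
) -> ImageVolume:
    """Forward-render one sodium image (agar-relative units).

    Each labeled region receives its tissue-state intensity, the volume
    is PSF-convolved (``psf=None`` means a delta PSF) and Rician noise of
    scale ``noise_sigma`` (magnitude of a complex Gaussian perturbation)
    is added with the given seed.
    """
    lab = labels.data
    img = np.zeros(lab.shape, dtype=float)
    for name, label in truth.label_of.items():
        state = truth.state_of[name]
        value = region_signal(state, sequence, rw=rw, ideal_reference=ideal_reference)
        truth.intensity.setdefault(name, {})[sequence] = value
        img[lab == label] = value
    unknown = set(np.unique(lab)) - {0} - set(truth.label_of.values())
    if unknown:
        raise ValueError(f"label map contains unknown labels {sorted(unknown)}")
    if psf is not None:
        kernel = psf_kernel(
            PSFParams(
                t2star=psf.t2star,
                readout_duration=psf.readout_duration,
                voxel_size=labels.voxel_size,
                grid_shape=lab.shape,
            )
        )
        img = convolve_psf(img, kernel)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        re = img + rng.normal(0.0, noise_sigma, img.shape)
        im = rng.normal(0.0, noise_sigma, img.shape)
        img = np.sqrt(re**2 + im**2)
    return ImageVolume(data=img, voxel_size=labels.voxel_size, affine=labels.affine)


def simulate_cohort(
    n_controls: int = 9,
    n_patients: int = 30,
    effects: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    between_subject_sd: float = 0.032,
    lesion_severity_sd: float = 0.5,
    measurement_sd: float = 0.005,
    sequences: tuple[str, ...] = ("NaDW", "NaPACMAN", "NaSIRFLA"),
    regions: tuple[str, ...] = _WM_REGIONS,
) -> pd.DataFrame:
    """Seeded per-subject ROI table emulating the study cohort.

    Controls contribute control-WM ROI means; patients contribute both a
    NAWM and a lesion measurement per region.  ``effects`` optionally
    overrides the forward-model percent difference vs control per
    sequence and state, e.g. ``{"NaDW": {"lesion": 35.0}}``.  Biology
    varies between subjects as a multiplicative Gaussian factor
    (sd ``between_subject_sd``) on the compartment volumes, which scales
    all of a subject's signals; lesion severity varies per
    subject-region as a Gaussian factor (sd ``lesion_severity_sd``) on
    the lesion percent effect, shared across sequences (demyelination /
    edema extent is a tissue property, not a sequence property); ROI
    means carry additional Gaussian measurement error ``measurement_sd``
    (agar-relative units).
    """
    if n_controls < 2 or n_patients < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    base = {seq: region_signal("control", seq) for seq in sequences}
    from .signal_model import build_table3

    table = build_table3()
    pct: dict[str, dict[str, float]] = {
        seq: {st: table.pct_diff[seq][st] for st in ("control", "nawm", "lesion")}
        for seq in sequences
    }
    if effects:
        for seq, over in effects.items():
            pct.setdefault(seq, {}).update(over)

    rows = []
    subj = 0
    for group, n in (("control", n_controls), ("patient", n_patients)):
        for _ in range(n):
            subj += 1
            biology = rng.normal(1.0, between_subject_sd)
            age = float(
                np.clip(rng.normal(50.0, 16.0) if group == "control" else rng.normal(49.0, 11.0), 21, 75)
            )
            sex = int(rng.random() < 0.64)  # 1 = female, cohort-typical ratio
            states = ("control",) if group == "control" else ("nawm", "lesion")
            for region in regions:
                severity = max(rng.normal(1.0, lesion_severity_sd), 0.0)
                for state in states:
                    for seq in sequences:
                        eff = pct[seq][state] * (severity if state == "lesion" else 1.0)
                        mean = base[seq] * (1.0 + eff / 100.0) * biology
                        mean += rng.normal(0.0, measurement_sd)
                        rows.append(
                            {
                                "subject": f"S{subj:03d}",
                                "group": group,
                                "region": region,
                                "tissue_state": state,
                                "sequence": seq,
                                "mean_intensity": mean,
                                "age": age,
                                "sex": sex,
                            }
                        )
    return pd.DataFrame(rows)
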
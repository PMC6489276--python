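"""Synthetic thoracic phantom cohort with known dose-response ground truth.

Every downstream module is tested against phantoms from this generator: a
thorax-like planning CT (air / soft-tissue body / two aerated lungs with
smooth parenchymal texture / a dense tumor / intrapulmonary vessels), an
analytic dose field centred on the tumor, a smooth random inter-scan
deformation (posture/breathing surrogate), and follow-up scans in which lung
parenchyma gains density as a function of local dose.

The generator emulates the acquisition and cohort conditions of voxel-based
lung density studies: 2-mm-slice CT, prescription doses of 74/60/66 Gy for
NSCLC/SCLC/esophageal carcinoma, per-patient dose-response slopes with large
inter-individual spread (normal with mean 1.5, sd 2.0 HU/Gy), heavy per-voxel
HU noise (sd 60 HU), and a later timepoint with a moderately larger response.
The true response model, noise level and deformation per patient are returned
as :class:`SyntheticTruth` so recovery tests can compare estimates to truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .registration import DisplacementField, apply_displacement
from .volumes import (
    ENTITY_PRESCRIPTION_GY,
    MANIFEST_COLUMNS,
    BinaryMask,
    CohortManifest,
    ScalarVolume,
    load_cohort,
    write_mask,
    write_volume,
)

__all__ = [
    "ResponseModel",
    "SyntheticTruth",
    "CohortTemplate",
    "generate_planning_ct",
    "generate_dose_field",
    "generate_deformation",
    "simulate_followup",
    "generate_cohort",
]

DEFAULT_EXTENT = (56, 72, 72)  # (z, y, x) voxels
DEFAULT_SPACING = (2.0, 2.0, 2.0)  # mm; 2-mm slices as in the emulated scanner
DEFAULT_NOISE_SD = 60.0  # HU; sets the dispersion of voxel-wise ΔHU
DEFAULT_FALLOFF_MM = 24.0
DEFAULT_ENTITY_MIX = {"NSCLC": 35 / 81, "esophageal": 35 / 81, "SCLC": 11 / 81}
DEFAULT_SLOPE_MEAN = 1.5  # HU/Gy, cohort mean of per-patient slopes
DEFAULT_SLOPE_SD = 2.0  # HU/Gy, inter-patient spread
DEFAULT_TIMEPOINT_SCALE = {"12w": 1.0, "6m": 1.15}  # later scans densify more
LUNG_BASE_HU = -820.0
SOFT_TISSUE_HU = 20.0
TUMOR_HU = 30.0
VESSEL_HU = -50.0
AIR_HU = -1000.0


@dataclass
class ResponseModel:
    """Expected HU change as a function of local dose D (Gy).

    shapes:
      * ``linear``            r(D) = slope_b · D
      * ``threshold_linear``  r(D) = slope_b · (D − threshold_gy) for D above
        the threshold, else 0 — a fibrosis-threshold hypothesis
      * ``sigmoid``           r(D) = delta_max / (1 + exp(−(D − d50)/k))
    An optional ``low_dose_dip`` subtracts a fixed HU decrement below 10 Gy,
    probing the compensatory-overinflation hypothesis for low-dose lung.
    """

    shape: str = "linear"
    slope_b: float = DEFAULT_SLOPE_MEAN
    threshold_gy: float = 0.0
    d50: float = 40.0
    delta_max: float = 120.0
    steepness_k: float = 8.0
    low_dose_dip: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("linear", "threshold_linear", "sigmoid"):
            raise ValueError(f"unknown response shape {self.shape!r}")
        if self.delta_max < 0 or self.steepness_k <= 0 or self.threshold_gy < 0:
            raise ValueError("require delta_max >= 0, steepness_k > 0, threshold_gy >= 0")

    def response(self, dose: np.ndarray) -> np.ndarray:
        d = np.asarray(dose, dtype=np.float64)
        if self.shape == "linear":
            r = self.slope_b * d
        elif self.shape == "threshold_linear":
            r = self.slope_b * np.clip(d - self.threshold_gy, 0.0, None)
        else:
            r = self.delta_max / (1.0 + np.exp(-(d - self.d50) / self.steepness_k))
        if self.low_dose_dip:
            r = r - self.low_dose_dip * (d < 10.0)
        return r


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    seed: int
    noise_sd: float
    deformation_amplitude_mm: float
    deformation_scale_mm: float
    timepoint_scale: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TIMEPOINT_SCALE))
    models: dict[str, ResponseModel] = field(default_factory=dict)  # patient_id -> model

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "deformation_amplitude_mm": self.deformation_amplitude_mm,
            "deformation_scale_mm": self.deformation_scale_mm,
            "timepoint_scale": self.timepoint_scale,
            "models": {pid: asdict(m) for pid, m in self.models.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        models = {pid: ResponseModel(**m) for pid, m in payload.pop("models").items()}
        return cls(models=models, **payload)


@dataclass
class CohortTemplate:
    """Study conditions for a generated cohort (all defaults are the package's
    stated emulation of the target study; see docs/methods.md)."""

    extent: tuple[int, int, int] = DEFAULT_EXTENT
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    noise_sd: float = DEFAULT_NOISE_SD
    deformation_amplitude_mm: float = 3.0
    deformation_scale_mm: float = 24.0
    falloff_mm: float = DEFAULT_FALLOFF_MM
    entity_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ENTITY_MIX))
    slope_mean: float = DEFAULT_SLOPE_MEAN
    slope_sd: float = DEFAULT_SLOPE_SD
    response_shape: str = "linear"
    fixed_slope: float | None = None  # set to pin every patient to one slope
    sigmoid: dict[str, float] = field(
        default_factory=lambda: {"delta_max": 120.0, "d50": 40.0, "steepness_k": 8.0}
    )
    timepoint_scale: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TIMEPOINT_SCALE)
    )
    dropout_6m: float = 0.0  # fraction of patients missing the 6-month scan


def _ellipsoid(shape, center, semi, spacing) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    q = (
        ((zz - center[0]) * spacing[0] / semi[0]) ** 2
        + ((yy - center[1]) * spacing[1] / semi[1]) ** 2
        + ((xx - center[2]) * spacing[2] / semi[2]) ** 2
    )
    return q <= 1.0


def _smooth_field(shape, spacing, scale_mm, rng, normalize: str = "peak") -> np.ndarray:
    """Smooth zero-mean random field with correlation length ~scale_mm.

    normalize="peak" rescales to unit max-abs (displacement fields, where the
    amplitude bound matters); "std" rescales to unit standard deviation
    (texture, where the typical variation matters).
    """
    raw = rng.standard_normal(shape)
    sigma_vox = [scale_mm / s for s in spacing]
    # periodic filtering keeps the field variance stationary (no border spikes)
    smooth = ndimage.gaussian_filter(raw, sigma=sigma_vox, mode="wrap")
    smooth -= smooth.mean()
    denom = np.abs(smooth).max() if normalize == "peak" else smooth.std()
    return smooth / denom if denom > 0 else smooth


def generate_planning_ct(
    extent: tuple[int, int, int] = DEFAULT_EXTENT,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    seed: int = 0,
) -> tuple[ScalarVolume, BinaryMask, BinaryMask, BinaryMask]:
    """Build a thorax phantom: CT plus lung, tumor and vessel masks.

    The lung compartment is aerated (≈ −820 HU) with smooth parenchymal
    texture (|texture| ≤ 150 HU, so every lung voxel stays below −500 HU);
    the body is soft tissue near 0 HU inside exterior air; the tumor is a
    dense sphere in the right lung; vessels are dense tubes radiating from
    each hilum.
    """
    if any(n < 32 for n in extent):
        raise ValueError(f"extent must be >= 32 voxels per axis, got {extent}")
    rng = np.random.default_rng(seed)
    nz, ny, nx = extent
    sz, sy, sx = spacing
    fov = (nz * sz, ny * sy, nx * sx)

    ct = np.full(extent, AIR_HU)
    body = _ellipsoid(
        extent,
        center=(nz / 2, ny / 2, nx / 2),
        semi=(fov[0] * 0.50, fov[1] * 0.42, fov[2] * 0.45),
        spacing=spacing,
    )
    ct[body] = SOFT_TISSUE_HU

    lung_semi = (fov[0] * 0.36, fov[1] * 0.30, fov[2] * 0.17)
    left = _ellipsoid(extent, (nz / 2, ny / 2, nx * 0.30), lung_semi, spacing)
    right = _ellipsoid(extent, (nz / 2, ny / 2, nx * 0.70), lung_semi, spacing)
    lung = (left | right) & body
    texture = np.clip(_smooth_field(extent, spacing, 9.0, rng, normalize="std") * 45.0, -150, 150)
    ct[lung] = LUNG_BASE_HU + texture[lung]

    tumor_center = (nz / 2, ny / 2, nx * 0.70)
    tumor = _ellipsoid(extent, tumor_center, (11.0, 11.0, 11.0), spacing) & right
    ct[tumor] = TUMOR_HU

    # vessels: dense tubes radiating from each hilum, radii 1.5-3.5 mm
    # (roughly the vascular volume fraction of real parenchyma, ~5%)
    vessels = np.zeros(extent, dtype=bool)
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in extent], indexing="ij")
    for cx in (0.30, 0.70):
        hilum = np.array([nz / 2, ny / 2, nx * cx])
        n_tubes = 16
        for i in range(n_tubes):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            radius = rng.uniform(1.5, 3.5)
            p = np.stack([zz - hilum[0], yy - hilum[1], xx - hilum[2]], axis=-1) * spacing
            along = p @ direction
            perp2 = (p**2).sum(axis=-1) - along**2
            vessels |= (along > 0) & (along < 45.0) & (perp2 < radius**2)
    vessels &= lung & ~tumor
    ct[vessels] = VESSEL_HU

    vol = ScalarVolume(values=ct, spacing=spacing, kind="ct")
    mk = lambda arr, label: BinaryMask(values=arr, spacing=spacing, label=label)
    return vol, mk(lung, "lung"), mk(tumor, "tumor"), mk(vessels, "vessels")


def generate_dose_field(
    geometry: ScalarVolume,
    target_center_mm: tuple[float, float, float],
    prescription_gy: float,
    falloff_mm: float = DEFAULT_FALLOFF_MM,
    anisotropy: tuple[float, float, float] = (1.3, 1.0, 1.0),
) -> ScalarVolume:
    """Analytic dose field: exponential-of-quadratic falloff from the target.

    D(p) = prescription · exp(−Σ ((p−c)ᵢ / aᵢ)²) with aᵢ = falloff_mm ·
    anisotropyᵢ: the prescription is met at the target centre and dose decays
    monotonically along every ray — a smooth, analytic stand-in for a planned
    distribution (no treatment-planning engine is in scope).
    """
    if prescription_gy <= 0:
        raise ValueError(f"prescription must be > 0 Gy, got {prescription_gy}")
    c = np.asarray(target_center_mm)
    lo = np.asarray(geometry.origin)
    hi = lo + (np.asarray(geometry.shape) - 1) * np.asarray(geometry.spacing)
    if np.any(c < lo) or np.any(c > hi):
        raise ValueError("target_center must lie inside the volume")
    coords = np.meshgrid(
        *[
            geometry.origin[i] + np.arange(geometry.shape[i]) * geometry.spacing[i]
            for i in range(3)
        ],
        indexing="ij",
    )
    q = sum(
        ((coords[i] - c[i]) / (falloff_mm * anisotropy[i])) ** 2 for i in range(3)
    )
    dose = prescription_gy * np.exp(-q)
    return ScalarVolume(values=dose, spacing=geometry.spacing, origin=geometry.origin, kind="dose")


def generate_deformation(
    geometry: ScalarVolume | BinaryMask,
    amplitude_mm: float,
    scale_mm: float = 24.0,
    seed: int = 0,
) -> DisplacementField:
    """Smooth random displacement field, max magnitude exactly *amplitude_mm*.

    Each component is a Gaussian-smoothed white-noise field with correlation
    length ~scale_mm; the whole field is rescaled so the largest displacement
    vector has magnitude amplitude_mm.  A Jacobian check rejects amplitudes
    large enough to fold the mapping.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude must be >= 0")
    shape = geometry.shape
    field = DisplacementField.zero(shape, geometry.spacing, geometry.origin)
    if amplitude_mm == 0:
        return field
    rng = np.random.default_rng(seed)
    comps = np.stack(
        [_smooth_field(shape, geometry.spacing, scale_mm, rng) for _ in range(3)], axis=-1
    )
    mag = np.sqrt((comps**2).sum(axis=-1)).max()
    vectors = comps * (amplitude_mm / mag)
    field = DisplacementField(vectors, geometry.spacing, geometry.origin)
    if field.jacobian_min() <= 0:
        raise ValueError(
            f"amplitude {amplitude_mm} mm at scale {scale_mm} mm folds the mapping "
            "(non-positive Jacobian); reduce amplitude or increase scale"
        )
    return field


def simulate_followup(
    planning: ScalarVolume,
    dose: ScalarVolume,
    lung: BinaryMask,
    tumor: BinaryMask,
    model: ResponseModel,
    noise_sd: float = DEFAULT_NOISE_SD,
    deformation: DisplacementField | None = None,
    seed: int = 0,
) -> ScalarVolume:
    """Simulate a follow-up CT: dose response in the planning frame, additive
    Gaussian noise, then the inter-scan deformation.

    Lung voxels outside the tumor gain r(D) HU in expectation; the response
    is applied *before* the deformation so that identity-deformation cohorts
    admit exact closed-form recovery downstream.  Output HU are clipped to
    the valid CT range.
    """
    for other in (dose, lung, tumor):
        if not planning.same_geometry(other):
            raise ValueError("geometry mismatch between simulate_followup inputs")
    responding = lung.values & ~tumor.values
    values = planning.values.copy()
    values[responding] += model.response(dose.values[responding])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, -1024.0, 3071.0)
    followup = ScalarVolume(values, planning.spacing, planning.origin, kind="ct")
    if deformation is not None and deformation.max_magnitude_mm > 0:
        warped = apply_displacement(followup, deformation, interp="linear", fill=AIR_HU)
        assert isinstance(warped, ScalarVolume)
        followup = ScalarVolume(
            np.clip(warped.values, -1024.0, 3071.0),
            planning.spacing,
            planning.origin,
            kind="ct",
        )
    return followup


def _draw_entities(n: int, mix: dict[str, float], rng: np.random.Generator) -> list[str]:
    names = sorted(mix)
    probs = np.array([mix[k] for k in names], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError(f"entity_mix must sum to 1, got {probs.sum():.4f}")
    return list(rng.choice(names, size=n, p=probs))


def generate_cohort(
    out_dir: str | Path,
    n_patients: int = 12,
    template: CohortTemplate | None = None,
    master_seed: int = 0,
) -> tuple[CohortManifest, SyntheticTruth]:
    """Write a full phantom cohort to disk and return its ground truth.

    Each patient gets a planning CT, dose grid, lung/tumor masks and follow-up
    scans at 12 weeks and 6 months (NIfTI), plus a manifest CSV consumable by
    :func:`lungdelta.volumes.load_cohort` and a ``truth.json``.  Per-patient
    dose-response slopes are drawn from N(slope_mean, slope_sd²); entities and
    prescriptions follow the template mix.  Regeneration with the same seed is
    bit-identical.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    template = template or CohortTemplate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(master_seed)
    per_patient = master.spawn(n_patients)
    cohort_rng = np.random.default_rng(master.spawn(1)[0])
    entities = _draw_entities(n_patients, template.entity_mix, cohort_rng)

    truth = SyntheticTruth(
        seed=master_seed,
        noise_sd=template.noise_sd,
        deformation_amplitude_mm=template.deformation_amplitude_mm,
        deformation_scale_mm=template.deformation_scale_mm,
        timepoint_scale=dict(template.timepoint_scale),
    )
    rows = []
    for i, (entity, seq) in enumerate(zip(entities, per_patient)):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(seq)
        sub = rng.integers(0, 2**31 - 1, size=8)
        planning, lung, tumor, vessels = generate_planning_ct(
            template.extent, template.spacing, seed=int(sub[0])
        )
        prescription = ENTITY_PRESCRIPTION_GY[entity]
        center_idx = np.array([planning.shape[0] / 2, planning.shape[1] / 2, planning.shape[2] * 0.70])
        center_mm = tuple(center_idx * np.asarray(planning.spacing) + np.asarray(planning.origin))
        dose = generate_dose_field(planning, center_mm, prescription, template.falloff_mm)

        if template.response_shape == "sigmoid":
            model = ResponseModel(shape="sigmoid", **template.sigmoid)
        else:
            if template.fixed_slope is not None:
                slope = template.fixed_slope
            else:
                slope = float(rng.normal(template.slope_mean, template.slope_sd))
            model = ResponseModel(shape=template.response_shape, slope_b=slope)
        truth.models[pid] = model

        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        write_volume(planning, pdir / "planning_ct.nii.gz")
        write_volume(dose, pdir / "dose.nii.gz")
        write_mask(lung, pdir / "lung_mask.nii.gz")
        write_mask(tumor, pdir / "tumor_mask.nii.gz")

        row = {
            "patient_id": pid,
            "entity": entity,
            "prescription_gy": prescription,
            "planning_ct": f"{pid}/planning_ct.nii.gz",
            "dose": f"{pid}/dose.nii.gz",
            "lung_mask": f"{pid}/lung_mask.nii.gz",
            "tumor_mask": f"{pid}/tumor_mask.nii.gz",
            "followup_12w": "",
            "followup_6m": "",
        }
        has_6m = rng.random() >= template.dropout_6m
        for j, tp in enumerate(("12w", "6m")):
            if tp == "6m" and not has_6m:
                continue
            tp_model = ResponseModel(**{**asdict(model)})
            scale = template.timepoint_scale.get(tp, 1.0)
            if tp_model.shape == "sigmoid":
                tp_model.delta_max *= scale
            else:
                tp_model.slope_b *= scale
            if template.deformation_amplitude_mm > 0:
                deformation = generate_deformation(
                    planning,
                    template.deformation_amplitude_mm,
                    template.deformation_scale_mm,
                    seed=int(sub[2 + j]),
                )
            else:
                deformation = None
            fup = simulate_followup(
                planning,
                dose,
                lung,
                tumor,
                tp_model,
                noise_sd=template.noise_sd,
                deformation=deformation,
                seed=int(sub[4 + j]),
            )
            write_volume(fup, pdir / f"followup_{tp}.nii.gz")
            row[f"followup_{tp}"] = f"{pid}/followup_{tp}.nii.gz"
        rows.append(row)

    import pandas as pd

    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, index=False)
    truth.to_json(out_dir / "truth.json")
    return load_cohort(manifest_path), truth
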
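"""Core volume/mask containers and NIfTI + cohort-manifest I/O.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``(z, y, x)`` — slice axis first, matching the order in
  which CT slices are acquired.
* ``spacing`` and ``origin`` are given per array axis, i.e. also in
  ``(z, y, x)`` order, in millimetres.
* Voxel indices are 0-based; the physical position of voxel ``(i, j, k)`` is
  ``origin + (i, j, k) * spacing`` (identity orientation; oblique volumes are
  out of scope).
* CT values are Hounsfield units in ``[-1024, 3071]``; dose values are Gy and
  non-negative.
* Voxels that fall outside a source volume during resampling receive the
  sentinel :data:`OUT_OF_EXTENT`, far below any valid HU, and are excluded
  from statistics via validity masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "OUT_OF_EXTENT",
    "HU_MIN",
    "HU_MAX",
    "ScalarVolume",
    "BinaryMask",
    "PatientRecord",
    "CohortManifest",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_to_reference",
    "load_cohort",
    "MANIFEST_COLUMNS",
]

OUT_OF_EXTENT = -3000.0
HU_MIN = -1024.0
HU_MAX = 3071.0

VolumeKind = Literal["ct", "dose"]
MaskLabel = Literal["lung", "tumor", "vessels", "exclusion", "analysis"]

MANIFEST_COLUMNS = [
    "patient_id",
    "entity",
    "prescription_gy",
    "planning_ct",
    "dose",
    "lung_mask",
    "tumor_mask",
    "followup_12w",
    "followup_6m",
]

ENTITY_PRESCRIPTION_GY = {"NSCLC": 74.0, "SCLC": 60.0, "esophageal": 66.0}


@dataclass(frozen=True)
class ScalarVolume:
    """A 3-D scalar grid (HU for CT, Gy for dose) with physical geometry.

    Parameters
    ----------
    values
        3-D float array indexed ``(z, y, x)``.
    spacing
        Physical step per axis in mm, ``(z, y, x)`` order, all > 0.
    origin
        Physical position of voxel (0, 0, 0) in mm, ``(z, y, x)`` order.
    kind
        ``"ct"`` or ``"dose"``; selects the value-range validation.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: VolumeKind = "ct"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={values.ndim}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")
        self._validate_range()

    def _validate_range(self) -> None:
        finite = self.values[self.values > OUT_OF_EXTENT + 1]
        if self.kind == "ct":
            if finite.size and (finite.min() < HU_MIN or finite.max() > HU_MAX):
                raise ValueError(
                    f"CT values outside [{HU_MIN}, {HU_MAX}]: "
                    f"range [{finite.min():.1f}, {finite.max():.1f}]"
                )
        elif self.kind == "dose":
            if finite.size and finite.min() < 0:
                raise ValueError(f"dose values must be >= 0, min is {finite.min():.3f}")
        else:
            raise ValueError(f"unknown volume kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_geometry(self, other: "ScalarVolume | BinaryMask", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_values(self, values: np.ndarray, kind: VolumeKind | None = None) -> "ScalarVolume":
        return replace(self, values=values, kind=kind or self.kind)


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} volume sharing the geometry contract of :class:`ScalarVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: MaskLabel = "lung"

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.dtype != bool:
            uniq = np.unique(values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask values must be in {{0,1}}, got {uniq[:10]}")
            values = values.astype(bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if values.ndim != 3:
            raise ValueError(f"mask must be 3-D, got ndim={values.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def same_geometry(self, other: "ScalarVolume | BinaryMask", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_values(self, values: np.ndarray, label: MaskLabel | None = None) -> "BinaryMask":
        return replace(self, values=values, label=label or self.label)


@dataclass
class PatientRecord:
    """One patient's loaded imaging data, everything in the planning frame."""

    patient_id: str
    entity: str
    prescription_dose: float
    planning_ct: ScalarVolume
    dose_grid: ScalarVolume
    masks: dict[str, BinaryMask]
    followups: dict[str, ScalarVolume] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entity not in ENTITY_PRESCRIPTION_GY:
            raise ValueError(f"unknown entity {self.entity!r}")
        dmax = float(self.dose_grid.values.max())
        if dmax > 1.10 * self.prescription_dose:
            raise ValueError(
                f"dose grid max {dmax:.1f} Gy exceeds 110% of the "
                f"{self.prescription_dose:.0f} Gy prescription"
            )


@dataclass
class CohortManifest:
    """Validated per-patient rows of file paths and metadata."""

    rows: pd.DataFrame
    root: Path

    @property
    def patient_ids(self) -> list[str]:
        return list(self.rows["patient_id"])

    def n_available(self, timepoint: str) -> int:
        col = f"followup_{timepoint}"
        return int(self.rows[col].notna().sum())

    def load_patient(self, patient_id: str) -> PatientRecord:
        row = self.rows.set_index("patient_id").loc[patient_id]
        root = self.root

        def _p(cell: object) -> Path:
            return root / str(cell)

        planning = read_volume(_p(row["planning_ct"]), kind="ct")
        dose = read_volume(_p(row["dose"]), kind="dose")
        if not dose.same_geometry(planning):
            dose = resample_to_reference(dose, planning, interp="linear")
        masks = {
            "lung": read_mask(_p(row["lung_mask"]), label="lung"),
            "tumor": read_mask(_p(row["tumor_mask"]), label="tumor"),
        }
        followups = {}
        for tp in ("12w", "6m"):
            cell = row[f"followup_{tp}"]
            if pd.notna(cell) and str(cell):
                followups[tp] = read_volume(_p(cell), kind="ct")
        return PatientRecord(
            patient_id=str(patient_id),
            entity=str(row["entity"]),
            prescription_dose=float(row["prescription_gy"]),
            planning_ct=planning,
            dose_grid=dose,
            masks=masks,
            followups=followups,
        )


# ---------------------------------------------------------------------------
# SimpleITK bridge.  SimpleITK orders axes (x, y, z); everything here flips
# to/from the package's (z, y, x) convention in exactly one place.
# ---------------------------------------------------------------------------

def to_sitk(vol: ScalarVolume | BinaryMask) -> sitk.Image:
    arr = vol.values.astype(np.uint8) if isinstance(vol, BinaryMask) else vol.values
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(vol.spacing[::-1]))
    img.SetOrigin(tuple(vol.origin[::-1]))
    return img


def from_sitk(img: sitk.Image, kind: VolumeKind = "ct") -> ScalarVolume:
    arr = sitk.GetArrayFromImage(img).astype(np.float64)
    return ScalarVolume(
        values=arr,
        spacing=tuple(img.GetSpacing()[::-1]),
        origin=tuple(img.GetOrigin()[::-1]),
        kind=kind,
    )


# ---------------------------------------------------------------------------
# Volume I/O (NIfTI)
# ---------------------------------------------------------------------------

def write_volume(vol: ScalarVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (float64, so HU integers round-trip exactly)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(to_sitk(vol), str(path))
    return path


def read_volume(path: str | Path, kind: VolumeKind = "ct") -> ScalarVolume:
    """Read a NIfTI volume and validate its value range for *kind*.

    Raises
    ------
    IOError
        If the file is missing or unreadable.
    ValueError
        If the values violate the range contract (e.g. negative dose).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # sitk raises RuntimeError on bad files
        raise IOError(f"could not read volume file {path}: {exc}") from exc
    return from_sitk(img, kind=kind)


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = sitk.GetImageFromArray(mask.values.astype(np.uint8))
    img.SetSpacing(tuple(mask.spacing[::-1]))
    img.SetOrigin(tuple(mask.origin[::-1]))
    sitk.WriteImage(img, str(path))
    return path


def read_mask(path: str | Path, label: MaskLabel = "lung") -> BinaryMask:
    path = Path(path)
    if not path.exists():
        raise IOError(f"mask file not found: {path}")
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    return BinaryMask(
        values=arr,
        spacing=tuple(img.GetSpacing()[::-1]),
        origin=tuple(img.GetOrigin()[::-1]),
        label=label,
    )


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _physical_bounds(vol: ScalarVolume | BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    lo = np.asarray(vol.origin)
    hi = lo + (np.asarray(vol.shape) - 1) * np.asarray(vol.spacing)
    return lo, hi


def resample_to_reference(
    vol: ScalarVolume,
    ref: ScalarVolume | BinaryMask,
    interp: Literal["linear", "nearest"] = "linear",
) -> ScalarVolume:
    """Resample *vol* onto *ref*'s grid.

    Voxels of the reference grid that fall outside *vol*'s physical extent
    receive :data:`OUT_OF_EXTENT` so they can be flagged and excluded
    downstream; they are never valid HU or dose values.
    """
    lo_v, hi_v = _physical_bounds(vol)
    lo_r, hi_r = _physical_bounds(ref)
    if np.any(hi_v < lo_r) or np.any(lo_v > hi_r):
        raise ValueError("volumes have zero physical overlap; cannot resample")

    interpolator = sitk.sitkLinear if interp == "linear" else sitk.sitkNearestNeighbor
    ref_img = sitk.Image(tuple(int(n) for n in ref.shape[::-1]), sitk.sitkFloat64)
    ref_img.SetSpacing(tuple(ref.spacing[::-1]))
    ref_img.SetOrigin(tuple(ref.origin[::-1]))
    out = sitk.Resample(
        to_sitk(vol), ref_img, sitk.Transform(), interpolator, OUT_OF_EXTENT, sitk.sitkFloat64
    )
    arr = sitk.GetArrayFromImage(out)
    return ScalarVolume(
        values=arr,
        spacing=tuple(ref.spacing),
        origin=tuple(ref.origin),
        kind=vol.kind if vol.kind == "ct" else "dose",
    )


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

def load_cohort(manifest_path: str | Path) -> CohortManifest:
    """Load and validate a cohort manifest CSV.

    The manifest has columns ``patient_id,entity,prescription_gy,planning_ct,
    dose,lung_mask,tumor_mask,followup_12w,followup_6m``; empty follow-up
    cells mark scans unavailable at that timepoint (patients drop out of the
    later timepoint without being excluded from the earlier one).
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise IOError(f"manifest not found: {manifest_path}")
    rows = pd.read_csv(manifest_path, dtype={"patient_id": str})
    missing_cols = set(MANIFEST_COLUMNS) - set(rows.columns)
    if missing_cols:
        raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")

    dupes = rows["patient_id"][rows["patient_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate patient_id in manifest: {dupes}")

    root = manifest_path.parent
    required = ["planning_ct", "dose", "lung_mask", "tumor_mask"]
    optional = ["followup_12w", "followup_6m"]
    missing_files: list[str] = []
    for _, row in rows.iterrows():
        for col in required:
            if pd.isna(row[col]) or not (root / str(row[col])).exists():
                missing_files.append(f"{row['patient_id']}:{col}={row[col]}")
        for col in optional:
            if pd.notna(row[col]) and str(row[col]) and not (root / str(row[col])).exists():
                missing_files.append(f"{row['patient_id']}:{col}={row[col]}")
    if missing_files:
        raise ValueError("manifest references missing files: " + ", ".join(missing_files))
    return CohortManifest(rows=rows, root=root)
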
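"""Construction of the analyzed lung-parenchyma volume.

The analyzed volume is the lung minus everything denser than aerated
parenchyma — the tumor itself, vessels, atelectasis, other organs — each
removed together with a dilated safety margin so that partial-volume voxels
and small registration errors at structure edges never enter the statistics.
The mask is built once on the planning CT and reused for every follow-up
timepoint; dense consolidations that appear only on follow-up are the signal
being measured and are deliberately not re-masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, ScalarVolume

__all__ = [
    "MaskRecipe",
    "segment_lung",
    "build_exclusion_mask",
    "build_analysis_mask",
    "physical_ball",
]

DEFAULT_PARENCHYMA_MAX_HU = -300.0
DEFAULT_MARGIN_MM = 6.0


@dataclass
class MaskRecipe:
    """How to derive the analysis mask from a patient's data.

    ``hu_parenchyma_max`` separates aerated parenchyma from dense structures
    (vessels, atelectasis); ``margin_mm`` is the radius of the safety margin
    dilated around every excluded structure, in physical millimetres.
    """

    lung_source: str = "provided_mask"  # or "threshold_segmentation"
    hu_parenchyma_max: float = DEFAULT_PARENCHYMA_MAX_HU
    margin_mm: float = DEFAULT_MARGIN_MM
    lung_threshold_hu: float = -500.0
    extra_exclusions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.margin_mm < 0:
            raise ValueError(f"margin_mm must be >= 0, got {self.margin_mm}")
        if self.lung_source not in ("provided_mask", "threshold_segmentation"):
            raise ValueError(f"unknown lung_source {self.lung_source!r}")


def physical_ball(radius_mm: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Boolean structuring element: a ball of *radius_mm* in physical units.

    Voxels whose centre lies at distance <= radius_mm from the origin are
    included, so on anisotropic grids the voxel radius differs per axis
    (e.g. a 2 mm ball on (2, 1, 1) mm spacing spans 1 voxel through-plane and
    2 voxels in-plane).
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    dist2 = sum(g**2 for g in grids)
    ball = dist2 <= radius_mm**2 + 1e-9
    return ball


def segment_lung(ct: ScalarVolume, hu_threshold: float = -500.0) -> BinaryMask:
    """Threshold-based lung segmentation on a CT volume.

    Keeps the largest interior connected components below *hu_threshold*
    (up to two, for the two lungs), after discarding exterior air connected to
    the volume border.

    Raises
    ------
    ValueError
        If no interior low-HU component exists.
    """
    low = ct.values < hu_threshold
    labels, n = ndimage.label(low)
    if n == 0:
        raise ValueError(f"no voxels below {hu_threshold} HU; cannot segment lung")

    # drop components touching the border (exterior air)
    border_labels = set(np.unique(labels[0, :, :])) | set(np.unique(labels[-1, :, :]))
    border_labels |= set(np.unique(labels[:, 0, :])) | set(np.unique(labels[:, -1, :]))
    border_labels |= set(np.unique(labels[:, :, 0])) | set(np.unique(labels[:, :, -1]))
    border_labels.discard(0)

    counts = np.bincount(labels.ravel())
    counts[0] = 0
    for lab in border_labels:
        counts[lab] = 0
    if counts.max() == 0:
        raise ValueError("no interior low-HU component found (only exterior air)")

    # the two largest interior components (two lungs; one if they connect)
    order = np.argsort(counts)[::-1]
    keep = [lab for lab in order[:2] if counts[lab] > 0]
    mask = np.isin(labels, keep)
    return BinaryMask(values=mask, spacing=ct.spacing, origin=ct.origin, label="lung")


def _check_geometry(*objs: ScalarVolume | BinaryMask) -> None:
    first = objs[0]
    for other in objs[1:]:
        if not first.same_geometry(other):
            raise ValueError("geometry mismatch between volumes/masks")


def build_exclusion_mask(
    ct: ScalarVolume,
    lung: BinaryMask,
    tumor: BinaryMask | None = None,
    hu_parenchyma_max: float = DEFAULT_PARENCHYMA_MAX_HU,
    extra: list[BinaryMask] | None = None,
) -> BinaryMask:
    """Union of everything denser than parenchyma that must leave the analysis.

    exclusion = tumor ∪ {lung voxels with HU > hu_parenchyma_max} ∪ extras.
    """
    parts = [lung]
    if tumor is not None:
        parts.append(tumor)
    if extra:
        parts.extend(extra)
    _check_geometry(ct, *parts)

    excl = lung.values & (ct.values > hu_parenchyma_max)
    if tumor is not None:
        excl = excl | tumor.values
    for m in extra or []:
        excl = excl | m.values
    return BinaryMask(values=excl, spacing=ct.spacing, origin=ct.origin, label="exclusion")


def build_analysis_mask(
    lung: BinaryMask,
    exclusion: BinaryMask,
    margin_mm: float = DEFAULT_MARGIN_MM,
) -> BinaryMask:
    """analysis = lung ∖ dilate(exclusion, ball(margin_mm)).

    The dilation radius is honoured in physical millimetres, so anisotropic
    voxels dilate by different voxel counts per axis.

    Raises
    ------
    ValueError
        If the margin empties the mask (message reports the voxel counts).
    """
    _check_geometry(lung, exclusion)
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")

    if exclusion.values.any() and margin_mm > 0:
        # dilation by a physical ball == thresholded Euclidean distance map;
        # exact in mm on anisotropic grids and cheap for any margin
        dist = ndimage.distance_transform_edt(~exclusion.values, sampling=lung.spacing)
        dilated = dist <= margin_mm + 1e-9
    else:
        dilated = exclusion.values
    analysis = lung.values & ~dilated
    if not analysis.any():
        raise ValueError(
            f"analysis mask empty: lung {lung.voxel_count} voxels, "
            f"dilated exclusion {int(dilated.sum())} voxels, margin {margin_mm} mm"
        )
    return BinaryMask(
        values=analysis, spacing=lung.spacing, origin=lung.origin, label="analysis"
    )
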
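"""Deformable registration of follow-up CT scans into the planning frame.

The planning CT carries the dose grid and the structure masks, so the
follow-up scan is always the one that gets deformed — dose and masks are
never warped.  The default backend is multi-resolution diffeomorphic demons
(intensity-based, well suited to mono-modal CT/CT alignment); correctness is
defined by the result contract and recovery tests, not by the particular
algorithm, and other backends can be registered.

Displacement fields are stored as arrays of shape ``(nz, ny, nx, 3)`` with
the last axis ordered ``(dz, dy, dx)`` in millimetres, on the geometry of the
volume they displace.  The field maps a point of the *fixed* (planning) frame
to the location in the *moving* (follow-up) frame from which its intensity is
pulled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal

import numpy as np
import SimpleITK as sitk

from .volumes import (
    OUT_OF_EXTENT,
    BinaryMask,
    ScalarVolume,
    from_sitk,
    to_sitk,
)

__all__ = [
    "DisplacementField",
    "RegistrationResult",
    "RegistrationParams",
    "apply_displacement",
    "register_deformable",
    "REGISTRATION_BACKENDS",
]


@dataclass(frozen=True)
class DisplacementField:
    """Dense displacement field in mm on a volume's grid, (dz, dy, dx) last axis."""

    vectors: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vec = np.asarray(self.vectors, dtype=np.float64)
        object.__setattr__(self, "vectors", vec)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if vec.ndim != 4 or vec.shape[-1] != 3:
            raise ValueError(f"displacement field must have shape (nz,ny,nx,3), got {vec.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    @property
    def max_magnitude_mm(self) -> float:
        return float(np.sqrt((self.vectors**2).sum(axis=-1)).max())

    @classmethod
    def zero(
        cls,
        shape: tuple[int, int, int],
        spacing: tuple[float, float, float],
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "DisplacementField":
        return cls(np.zeros((*shape, 3)), spacing, origin)

    def to_sitk(self) -> sitk.Image:
        # sitk vector images order components (x, y, z)
        img = sitk.GetImageFromArray(self.vectors[..., ::-1].copy(), isVector=True)
        img.SetSpacing(tuple(self.spacing[::-1]))
        img.SetOrigin(tuple(self.origin[::-1]))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "DisplacementField":
        arr = sitk.GetArrayFromImage(img).astype(np.float64)
        return cls(
            vectors=arr[..., ::-1].copy(),
            spacing=tuple(img.GetSpacing()[::-1]),
            origin=tuple(img.GetOrigin()[::-1]),
        )

    def jacobian_min(self) -> float:
        """Minimum determinant of the mapping Jacobian I + ∇u (foldover check)."""
        det = sitk.DisplacementFieldJacobianDeterminant(self.to_sitk())
        return float(sitk.GetArrayFromImage(det).min())

    def save(self, path: str | Path) -> Path:
        """Write the field as a 3-component vector NIfTI."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        sitk.WriteImage(self.to_sitk(), str(path))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DisplacementField":
        return cls.from_sitk(sitk.ReadImage(str(path)))


@dataclass
class RegistrationParams:
    """Knobs of the demons backend.

    ``smoothing_sigmas`` regularize the displacement field per pyramid level
    (in voxels of that level); coarser levels get stronger smoothing.  The
    aligned output is resampled with B-spline interpolation, which preserves
    edges better than linear and measurably lowers the residual at
    lung/vessel boundaries.
    """

    backend: str = "demons"
    pyramid_shrinks: tuple[int, ...] = (4, 2, 1)
    iterations_per_level: tuple[int, ...] = (100, 100, 80)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.5, 1.0)
    highpass_sigma_mm: float = 20.0  # 0 disables the high-pass prefilter
    final_interpolator: str = "bspline"  # or "linear"
    convergence_tolerance: float = 0.0  # min required fractional metric improvement


@dataclass
class RegistrationResult:
    aligned: ScalarVolume
    displacement: DisplacementField
    validity: BinaryMask
    pre_mad: float  # mean abs HU difference in the lung mask, before
    post_mad: float  # ... after registration
    converged: bool = True
    jacobian_positive: bool = True


_INTERPOLATORS = {
    "linear": sitk.sitkLinear,
    "nearest": sitk.sitkNearestNeighbor,
    "bspline": sitk.sitkBSpline,
}


def apply_displacement(
    vol: ScalarVolume | BinaryMask,
    displacement: DisplacementField,
    interp: Literal["linear", "nearest", "bspline"] = "linear",
    fill: float = OUT_OF_EXTENT,
) -> ScalarVolume | BinaryMask:
    """Warp *vol* by a displacement field (zero field is the identity map).

    The output lives on the displacement field's grid; the value at each
    output voxel is sampled from *vol* at position + displacement.  Masks are
    warped with nearest-neighbour and stay binary.
    """
    is_mask = isinstance(vol, BinaryMask)
    if vol.shape != displacement.shape:
        raise ValueError(
            f"geometry mismatch: volume {vol.shape} vs field {displacement.shape}"
        )
    if is_mask:
        interpolator = sitk.sitkNearestNeighbor
    else:
        interpolator = _INTERPOLATORS[interp]
    tx = sitk.DisplacementFieldTransform(displacement.to_sitk())
    src = to_sitk(vol)
    ref = sitk.Image(src.GetSize(), sitk.sitkFloat64)
    ref.SetSpacing(tuple(displacement.spacing[::-1]))
    ref.SetOrigin(tuple(displacement.origin[::-1]))
    out = sitk.Resample(src, ref, tx, interpolator, 0.0 if is_mask else fill, sitk.sitkFloat64)
    arr = sitk.GetArrayFromImage(out)
    if is_mask:
        return BinaryMask(
            values=arr > 0.5,
            spacing=displacement.spacing,
            origin=displacement.origin,
            label=vol.label,
        )
    # clip interpolation overshoot back into the valid range, sparing the
    # out-of-extent sentinel so validity masks still see it
    inside = arr > OUT_OF_EXTENT + 1
    if vol.kind == "ct":
        arr = np.where(inside, np.clip(arr, -1024.0, 3071.0), arr)
    else:
        arr = np.where(inside, np.clip(arr, 0.0, None), arr)
    return ScalarVolume(
        values=arr, spacing=displacement.spacing, origin=displacement.origin, kind=vol.kind
    )


def _masked_mad(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    return float(np.abs(a[mask] - b[mask]).mean())


def _demons_backend(
    fixed: sitk.Image, moving: sitk.Image, params: RegistrationParams
) -> sitk.Image:
    """Multi-resolution symmetric-forces demons; returns the displacement field.

    The force images are high-pass filtered first (subtracting a Gaussian
    blur at ``highpass_sigma_mm``): genuine radiation-induced density change
    varies on the scale of the dose distribution and would otherwise be
    "explained away" by spurious deformation, whereas the anatomy that should
    drive alignment (parenchymal texture, vessels, organ boundaries) lives at
    finer scales.
    """
    fixed_f = sitk.Cast(fixed, sitk.sitkFloat32)
    moving_f = sitk.Cast(moving, sitk.sitkFloat32)
    if params.highpass_sigma_mm > 0:
        hp = [params.highpass_sigma_mm] * 3
        fixed_f = sitk.Subtract(fixed_f, sitk.SmoothingRecursiveGaussian(fixed_f, hp))
        moving_f = sitk.Subtract(moving_f, sitk.SmoothingRecursiveGaussian(moving_f, hp))
    field: sitk.Image | None = None
    for shrink, iters, sigma in zip(
        params.pyramid_shrinks, params.iterations_per_level, params.smoothing_sigmas
    ):
        if shrink > 1:
            # anti-alias before shrinking; sigma in physical units
            aa = [shrink * s / 2 for s in fixed.GetSpacing()]
            f = sitk.Shrink(sitk.SmoothingRecursiveGaussian(fixed_f, aa), [shrink] * 3)
            m = sitk.Shrink(sitk.SmoothingRecursiveGaussian(moving_f, aa), [shrink] * 3)
        else:
            f, m = fixed_f, moving_f
        demons = sitk.SymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(iters)
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(sigma)
        if field is None:
            field = demons.Execute(f, m)
        else:
            up = sitk.Resample(
                field, f, sitk.Transform(), sitk.sitkLinear, 0.0, field.GetPixelID()
            )
            field = demons.Execute(f, m, up)
    assert field is not None
    if field.GetSize() != fixed.GetSize():
        field = sitk.Resample(
            field, fixed, sitk.Transform(), sitk.sitkLinear, 0.0, field.GetPixelID()
        )
    return field


REGISTRATION_BACKENDS: dict[str, Callable[[sitk.Image, sitk.Image, RegistrationParams], sitk.Image]] = {
    "demons": _demons_backend,
}


def register_deformable(
    fixed: ScalarVolume,
    moving: ScalarVolume,
    lung_mask: BinaryMask,
    params: RegistrationParams | None = None,
) -> RegistrationResult:
    """Deformably register a follow-up scan (*moving*) onto the planning CT.

    Returns the follow-up resampled onto the planning grid, the displacement
    field, a validity mask of voxels whose pull-back stayed inside the
    follow-up extent, and the pre/post mean absolute intensity difference
    inside the lung mask.  If the metric does not improve, the unwarped
    resampling is returned with ``converged=False`` rather than a silently
    degraded result.
    """
    params = params or RegistrationParams()
    if not lung_mask.same_geometry(fixed):
        raise ValueError("lung mask must be on the fixed (planning) geometry")
    backend = REGISTRATION_BACKENDS.get(params.backend)
    if backend is None:
        raise ValueError(f"unknown registration backend {params.backend!r}")

    fixed_img = to_sitk(fixed)
    moving_img = to_sitk(moving)

    # bounds check: require physical overlap
    from .volumes import resample_to_reference

    moving_on_fixed = resample_to_reference(moving, fixed, interp="linear")
    mask = lung_mask.values & (moving_on_fixed.values > OUT_OF_EXTENT + 1)
    if not mask.any():
        raise ValueError("no lung-mask overlap between fixed and moving volumes")
    pre_mad = _masked_mad(fixed.values, moving_on_fixed.values, mask)

    field_img = backend(fixed_img, moving_img, params)
    field = DisplacementField.from_sitk(field_img)
    aligned = apply_displacement(moving, field, interp=params.final_interpolator)
    assert isinstance(aligned, ScalarVolume)

    valid_arr = aligned.values > OUT_OF_EXTENT + 1
    post_mask = lung_mask.values & valid_arr
    post_mad = _masked_mad(fixed.values, aligned.values, post_mask)

    converged = True
    already_aligned = pre_mad < 1e-9  # nothing to improve (e.g. moving == fixed)
    if not already_aligned and post_mad > pre_mad * (1 - params.convergence_tolerance):
        converged = False
    if post_mad > pre_mad + 1e-9:
        # contract: registration never worsens its own metric
        warnings.warn(
            "registration failed to improve the lung MAD metric; "
            "returning the rigidly resampled follow-up",
            stacklevel=2,
        )
        aligned = moving_on_fixed
        field = DisplacementField.zero(fixed.shape, fixed.spacing, fixed.origin)
        valid_arr = aligned.values > OUT_OF_EXTENT + 1
        post_mad = pre_mad
        converged = already_aligned

    jac_ok = field.jacobian_min() > 0
    if not jac_ok:
        warnings.warn("displacement field has non-positive Jacobian voxels", stacklevel=2)

    validity = BinaryMask(
        values=valid_arr, spacing=fixed.spacing, origin=fixed.origin, label="analysis"
    )
    # clamp interpolation overshoot into the valid HU range
    clamped = np.where(
        valid_arr, np.clip(aligned.values, -1024.0, 3071.0), OUT_OF_EXTENT
    )
    aligned = ScalarVolume(clamped, fixed.spacing, fixed.origin, kind="ct")
    return RegistrationResult(
        aligned=aligned,
        displacement=field,
        validity=validity,
        pre_mad=pre_mad,
        post_mad=post_mad,
        converged=converged,
        jacobian_positive=jac_ok,
    )
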
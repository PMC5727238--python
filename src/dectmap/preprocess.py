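"""Alignment, denoising and mask construction for dual-energy volume pairs.

The two energy volumes are acquired sequentially, so the sample may have
moved rigidly between scans; decomposition requires voxel-wise congruence.
Registration here is post-reconstruction, rigid (translation + rotation),
driven by normalized cross-correlation — the two spectra scale each material
differently, which rules out a plain sum-of-squares metric. Median filtering
is the standard noise-reduction step before decomposition, and sample masks
are built from sparse manual slice annotations by signed-distance
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .transforms import RigidTransform, apply_rigid_transform
from .volume import AttenuationVolume


def median_filter(vol: AttenuationVolume, radius: int) -> AttenuationVolume:
    """Cubic-neighborhood median filter with reflecting edges; radius 0 is identity."""
    if radius < 0 or int(radius) != radius:
        raise ValueError(f"radius must be a non-negative integer, got {radius}")
    if radius == 0:
        return vol.with_data(vol.data.copy())
    size = 2 * int(radius) + 1
    return vol.with_data(ndimage.median_filter(vol.data, size=size, mode="reflect"))


@dataclass(frozen=True)
class RegistrationOptions:
    """Knobs for :func:`register_rigid`.

    The optimizer refines all six rigid parameters (voxel translations, Euler
    angles in degrees) with Powell's method from a phase-correlation
    translation estimate; ``max_rotation_deg`` bounds the expected rotation
    (sequential scans of a fixtured sample move by small angles only).
    """

    metric: str = "ncc"
    refine: bool = True
    max_rotation_deg: float = 10.0
    max_translation_vox: float = 15.0
    xtol: float = 1e-3
    min_ncc_converged: float = 0.5

    def __post_init__(self) -> None:
        if self.metric != "ncc":
            raise ValueError(f"unsupported similarity metric {self.metric!r}")


@dataclass
class RegistrationResult:
    """Transform, resampled moving volume and convergence diagnostics."""

    transform: RigidTransform
    resampled: AttenuationVolume
    ncc_before: float
    ncc_after: float
    converged: bool
    message: str = ""


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def register_rigid(
    moving: AttenuationVolume,
    fixed: AttenuationVolume,
    options: RegistrationOptions = RegistrationOptions(),
    fill: float | None = None,
) -> RegistrationResult:
    """Rigidly align ``moving`` onto ``fixed``.

    Returns the transform maximizing normalized cross-correlation, such that
    ``apply_rigid_transform(moving, transform)`` matches ``fixed``; the
    resampled volume is included. A result with poor final correlation is
    flagged ``converged=False`` with a diagnostic message, never silently
    returned as identity.

    ``fill`` is the attenuation assigned to voxels leaving the field of view
    during resampling (default: the minimum of ``moving``, an air estimate).
    """
    moving.check_congruent(fixed)
    if fill is None:
        fill = float(moving.data.min())
    ncc_before = _ncc(moving.data, fixed.data)

    # Coarse translation initialisation via phase correlation (moving -> fixed
    # shift sign convention: phase_cross_correlation returns the shift to
    # apply to `moving` to match `reference`).
    shift, _, _ = phase_cross_correlation(
        fixed.data, moving.data, upsample_factor=10, normalization=None
    )
    params0 = np.concatenate([shift, np.zeros(3)])

    def cost(params: np.ndarray) -> float:
        tf = RigidTransform(tuple(params[:3]), tuple(params[3:]))
        resampled = apply_rigid_transform(moving, tf, fill=fill)
        return -_ncc(resampled.data, fixed.data)

    if options.refine:
        tb = options.max_translation_vox
        rb = options.max_rotation_deg
        bounds = [(-tb + s, tb + s) for s in shift] + [(-rb, rb)] * 3
        res = optimize.minimize(
            cost,
            params0,
            method="Powell",
            bounds=bounds,
            options={"xtol": options.xtol, "ftol": 1e-8},
        )
        params = res.x
        message = res.message
    else:
        params = params0
        message = "phase correlation only (refine disabled)"

    transform = RigidTransform(tuple(params[:3]), tuple(params[3:]))
    resampled = apply_rigid_transform(moving, transform, fill=fill)
    ncc_after = _ncc(resampled.data, fixed.data)
    # already-aligned inputs lose a hair of correlation to interpolation, so
    # allow a small margin below the pre-alignment value
    converged = ncc_after >= options.min_ncc_converged and ncc_after >= ncc_before - 0.01
    if not converged:
        message = (
            f"registration did not improve similarity to a trustworthy level "
            f"(ncc {ncc_before:.3f} -> {ncc_after:.3f}); {message}"
        )
    return RegistrationResult(
        transform=transform,
        resampled=resampled,
        ncc_before=ncc_before,
        ncc_after=ncc_after,
        converged=bool(converged),
        message=str(message),
    )


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary: negative inside."""
    mask = mask.astype(bool)
    if mask.all():
        return np.full(mask.shape, -np.inf)
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask) - ndimage.distance_transform_edt(mask)


def interpolate_masks(
    annotated: list[tuple[int, np.ndarray]],
    n_slices: int | None = None,
) -> np.ndarray:
    """Build a 3D mask from sparse 2D slice annotations.

    Annotated slices are reproduced exactly. Between two annotated slices the
    mask is the negative region of the linearly blended signed distance
    transforms of the bracketing annotations (the standard shape-based
    interpolation of hand-drawn ROIs). Outside the annotated range the nearest
    annotation is extended unchanged.
    """
    if not annotated:
        raise ValueError("at least one annotated slice is required")
    indices = [int(i) for i, _ in annotated]
    if any(b <= a for a, b in zip(indices, indices[1:])):
        raise ValueError("annotated slice indices must be strictly increasing")
    if indices[0] < 0:
        raise ValueError("slice indices must be non-negative")
    planes = [np.asarray(m).astype(bool) for _, m in annotated]
    shape2d = planes[0].shape
    if any(p.shape != shape2d for p in planes):
        raise ValueError("annotated masks must share one 2D shape")
    if n_slices is None:
        n_slices = indices[-1] + 1
    if indices[-1] >= n_slices:
        raise ValueError("annotated index beyond the requested number of slices")

    out = np.zeros((n_slices, *shape2d), dtype=bool)
    out[: indices[0]] = planes[0]
    out[indices[-1] :] = planes[-1]
    for (i0, m0), (i1, m1) in zip(zip(indices, planes), zip(indices[1:], planes[1:])):
        sd0, sd1 = _signed_distance(m0), _signed_distance(m1)
        out[i0] = m0
        for k in range(i0 + 1, i1):
            alpha = (k - i0) / (i1 - i0)
            with np.errstate(invalid="ignore"):
                blend = (1.0 - alpha) * sd0 + alpha * sd1
            out[k] = blend < 0
    out[indices[-1]] = planes[-1]
    return out
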
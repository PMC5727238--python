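"""Volumetric containers shared across the pipeline.

Axis convention throughout the package: arrays are indexed ``(z, y, x)``,
0-based, with voxel centers at integer coordinates. Attenuation values are
effective polychromatic linear attenuation coefficients in mm^-1, as produced
by a reconstructed micro-CT scan acquired with one broad-band spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class AttenuationVolume:
    """A reconstructed 3D attenuation volume for one energy spectrum.

    Parameters
    ----------
    data:
        3D float array of linear attenuation coefficients (mm^-1), indexed
        ``(z, y, x)``. Negative values are legitimate (scattering artifacts)
        and are never clipped.
    voxel_size_um:
        Isotropic voxel edge length in micrometres. Must be positive.
    spectrum:
        Free-text label for the spectrum, e.g. ``"LE"`` or ``"HE"``.
    meta:
        Arbitrary provenance metadata carried through the pipeline.
    """

    data: np.ndarray
    voxel_size_um: float
    spectrum: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not (self.voxel_size_um > 0):
            raise ValueError(f"voxel size must be positive, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "AttenuationVolume":
        """Return a copy of this volume carrying new voxel data."""
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def check_congruent(self, other: "AttenuationVolume | np.ndarray") -> None:
        other_shape = other.shape if isinstance(other, np.ndarray) else other.data.shape
        if self.data.shape != other_shape:
            raise ValueError(
                f"volumes are not congruent: {self.data.shape} vs {other_shape}"
            )


def as_mask(mask: np.ndarray, like: AttenuationVolume | None = None) -> np.ndarray:
    """Validate and coerce a sample mask to a boolean 3D array."""
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"mask must be 3D, got ndim={mask.ndim}")
    if like is not None and mask.shape != like.data.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume {like.data.shape}"
        )
    return mask.astype(bool)
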
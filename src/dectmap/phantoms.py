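"""Synthetic dual-energy phantoms with exact ground truth.

Real dual-energy micro-CT scans of stained organs are not redistributable, so
this module generates reconstructed-domain stand-ins with known truth:

* a calibration phantom — a PMMA rod and a tube of staining solution in air —
  from which basis coefficients can be re-estimated; and
* an organ-like sample (ellipsoid with "heart" and "lung" compartments inside
  a plastic tube) whose stain fraction follows a diffusion-from-the-surface
  profile growing with staining time, with optional volume shrinkage between
  staining rounds, additive Gaussian noise, radial cupping bias and rigid
  misalignment between the two energy volumes.

Unstained tissue is modelled on the PMMA basis (PMMA is the soft-tissue
equivalent used for calibration), so noise-free phantoms lie exactly in the
span of the decomposition basis: per voxel and spectrum,

    mu = mu_stain * F_stain + mu_pmma * F_pmma + mu_air * F_air.

F values are fractions of the calibration staining solution and may exceed 1
where the tissue concentrates the stain beyond the bath concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import erfc

from .calibration import CalibrationSet
from .transforms import RigidTransform, apply_rigid_transform
from .volume import AttenuationVolume


@dataclass(frozen=True)
class NoiseSpec:
    """Additive reconstruction-domain noise and artifact model.

    sigma: i.i.d. Gaussian standard deviation on attenuation (mm^-1).
    beta: radial cupping strength (dimensionless, |beta| < 1); 0 disables.
    seed: RNG seed; identical specs and seeds give bit-identical volumes.
    """

    sigma: float = 0.0
    beta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"noise sigma must be >= 0, got {self.sigma}")
        if not abs(self.beta) < 1:
            raise ValueError(f"cupping strength must satisfy |beta| < 1, got {self.beta}")


@dataclass(frozen=True)
class CompartmentParams:
    """Diffusion parameters of one tissue compartment.

    diffusivity: D in voxel^2 / min.
    f_surface: stain fraction maintained at the organ surface (relative to the
        calibration solution; may exceed 1 for tissues that concentrate it).
    f_max: saturation cap on the stain fraction.
    """

    diffusivity: float
    f_surface: float
    f_max: float

    def __post_init__(self) -> None:
        if self.diffusivity < 0:
            raise ValueError(f"diffusivity must be >= 0, got {self.diffusivity}")
        if self.f_surface < 0:
            raise ValueError(f"f_surface must be >= 0, got {self.f_surface}")
        if self.f_max < 0:
            raise ValueError(f"f_max must be >= 0, got {self.f_max}")


@dataclass(frozen=True)
class OrganPhantomSpec:
    """Parametric organ-like sample: ellipsoid split into heart and lung.

    The organ is an ellipsoid (semi-axes in voxels, (z, y, x) order) centred
    at ``center``. The "heart" compartment is the part of the organ with
    x-index below ``center[2] + heart_split_offset``; the remainder is
    "lung". Both compartments reach the organ surface, as in an organ pair
    bathed in staining solution. An optional container tube (PMMA-like wall,
    axis along z) surrounds the organ.

    ``shrink_history`` records volume ratios applied by :func:`apply_shrinkage`.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: float = 12.0
    center: tuple[float, float, float] = (31.5, 31.5, 31.5)
    semiaxes: tuple[float, float, float] = (26.0, 22.0, 20.0)
    heart_split_offset: float = -4.0
    compartments: dict = field(
        default_factory=lambda: {
            "heart": CompartmentParams(diffusivity=1.0, f_surface=1.5, f_max=1.3),
            "lung": CompartmentParams(diffusivity=0.35, f_surface=1.0, f_max=1.0),
        }
    )
    container_inner_radius: float | None = 26.0
    container_wall: float = 2.0
    shrink_history: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for name, p in self.compartments.items():
            if not isinstance(p, CompartmentParams):
                raise TypeError(f"compartment {name!r} must be CompartmentParams")
        for s in self.shrink_history:
            if not (0 < s <= 1.25):
                raise ValueError(f"shrinkage factor must be in (0, 1.25], got {s}")

    # --- rasterization -----------------------------------------------------

    def _grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nz, ny, nx = self.shape
        return np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij", sparse=True
        )

    def organ_mask(self) -> np.ndarray:
        z, y, x = self._grids()
        cz, cy, cx = self.center
        az, ay, ax = self.semiaxes
        return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0

    def compartment_masks(self) -> dict[str, np.ndarray]:
        organ = self.organ_mask()
        _, _, x = self._grids()
        split = self.center[2] + self.heart_split_offset
        heart = organ & np.broadcast_to(x < split, organ.shape)
        return {"heart": heart, "lung": organ & ~heart}

    def container_mask(self) -> np.ndarray:
        if self.container_inner_radius is None:
            return np.zeros(self.shape, dtype=bool)
        _, y, x = self._grids()
        cy, cx = self.center[1], self.center[2]
        r = np.sqrt((y - cy) ** 2 + (x - cx) ** 2)
        wall = (r >= self.container_inner_radius) & (
            r < self.container_inner_radius + self.container_wall
        )
        return np.broadcast_to(wall, self.shape).copy()


@dataclass
class GroundTruth:
    """Exact generative truth accompanying a simulated volume pair."""

    f_stain: np.ndarray
    f_pmma: np.ndarray
    f_air: np.ndarray
    organ_mask: np.ndarray
    compartment_masks: dict[str, np.ndarray]
    container_mask: np.ndarray
    time_min: float
    applied_transform: RigidTransform | None = None
    shrink_history: tuple[float, ...] = ()

    def reconstruct(self, calset: CalibrationSet, spectrum: str) -> np.ndarray:
        """Noise-free attenuation implied by the fractions (mixture identity)."""
        coeffs = calset.le if spectrum.upper() == "LE" else calset.he
        return (
            coeffs["stain"] * self.f_stain
            + coeffs["pmma"] * self.f_pmma
            + coeffs["air"] * self.f_air
        )


def diffusion_profile(
    depth: np.ndarray | float,
    diffusivity: float,
    t: float,
    f_surface: float,
    f_max: float,
) -> np.ndarray | float:
    """Stain fraction at a given depth below the surface after time t.

    Half-space diffusion from a constant-concentration bath:
    ``min(f_max, f_surface * erfc(depth / (2 sqrt(D t))))``. By convention the
    profile is 0 for ``t = 0`` at positive depth and ``f_surface`` (capped) at
    depth 0 for any t.
    """
    depth_arr = np.asarray(depth, dtype=float)
    if np.any(depth_arr < 0):
        raise ValueError("depth must be >= 0")
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    if diffusivity < 0:
        raise ValueError(f"diffusivity must be >= 0, got {diffusivity}")
    spread = 2.0 * np.sqrt(diffusivity * t)
    if spread == 0.0:
        profile = np.where(depth_arr == 0.0, float(f_surface), 0.0)
    else:
        profile = f_surface * erfc(depth_arr / spread)
    profile = np.minimum(profile, f_max)
    return float(profile) if np.isscalar(depth) else profile


@dataclass(frozen=True)
class CalibrationPhantomGeometry:
    """PMMA rod + stain tube, both cylinders along z, surrounded by air."""

    shape: tuple[int, int, int] = (48, 64, 64)
    voxel_size_um: float = 12.0
    rod_center_yx: tuple[float, float] = (31.5, 16.0)
    rod_radius: float = 10.0
    tube_center_yx: tuple[float, float] = (31.5, 47.0)
    tube_radius: float = 10.0

    def labels(self) -> np.ndarray:
        """0 = air, 1 = PMMA rod, 2 = stain tube content."""
        ny, nx = self.shape[1], self.shape[2]
        y, x = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij", sparse=True)

        def disk(center: tuple[float, float], radius: float) -> np.ndarray:
            cy, cx = center
            if (
                cy - radius < -0.5
                or cx - radius < -0.5
                or cy + radius > ny - 0.5
                or cx + radius > nx - 0.5
            ):
                raise ValueError("phantom geometry does not fit inside the grid")
            return (y - cy) ** 2 + (x - cx) ** 2 <= radius**2

        rod = disk(self.rod_center_yx, self.rod_radius)
        tube = disk(self.tube_center_yx, self.tube_radius)
        if (rod & tube).any():
            raise ValueError("PMMA rod and stain tube overlap")
        plane = np.zeros((ny, nx), dtype=np.uint8)
        plane[rod] = 1
        plane[tube] = 2
        return np.broadcast_to(plane, self.shape).copy()


def _noisy_pair(
    mu_le: np.ndarray,
    mu_he: np.ndarray,
    noise: NoiseSpec,
    voxel_size_um: float,
    center: tuple[float, float, float] | None = None,
) -> tuple[AttenuationVolume, AttenuationVolume]:
    vol_le = AttenuationVolume(mu_le, voxel_size_um, spectrum="LE")
    vol_he = AttenuationVolume(mu_he, voxel_size_um, spectrum="HE")
    if noise.beta != 0.0:
        vol_le = add_cupping_bias(vol_le, noise.beta, center)
        vol_he = add_cupping_bias(vol_he, noise.beta, center)
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        vol_le = vol_le.with_data(
            vol_le.data + rng.normal(0.0, noise.sigma, vol_le.data.shape)
        )
        vol_he = vol_he.with_data(
            vol_he.data + rng.normal(0.0, noise.sigma, vol_he.data.shape)
        )
    return vol_le, vol_he


def make_calibration_phantom(
    geometry: CalibrationPhantomGeometry,
    calset: CalibrationSet,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[AttenuationVolume, AttenuationVolume, np.ndarray]:
    """Simulate a dual-energy scan of the calibration phantom.

    Returns the low- and high-energy volumes and the label field
    (0 air, 1 PMMA, 2 stain) for selecting calibration regions.
    """
    labels = geometry.labels()
    mu_le = np.empty(labels.shape, dtype=float)
    mu_he = np.empty(labels.shape, dtype=float)
    for code, name in ((0, "air"), (1, "pmma"), (2, "stain")):
        mu_le[labels == code] = calset.le[name]
        mu_he[labels == code] = calset.he[name]
    vol_le, vol_he = _noisy_pair(mu_le, mu_he, noise, geometry.voxel_size_um)
    return vol_le, vol_he, labels


def make_organ_phantom(
    spec: OrganPhantomSpec,
    calset: CalibrationSet,
    t: float,
    noise: NoiseSpec = NoiseSpec(),
    misalign_he: RigidTransform | None = None,
) -> tuple[AttenuationVolume, AttenuationVolume, GroundTruth]:
    """Simulate a dual-energy scan of the organ phantom at staining time t.

    The stain fraction at each organ voxel follows the compartment's
    diffusion profile evaluated at the voxel's Euclidean distance below the
    organ surface. Unstained tissue volume is PMMA-basis; the remainder of
    the unit mixture is air. Noise-free values satisfy the mixture identity
    to machine precision (see :meth:`GroundTruth.reconstruct`).

    ``misalign_he`` optionally moves the high-energy volume rigidly, creating
    the misregistration that the preprocessing stage must undo.
    """
    if t < 0:
        raise ValueError(f"staining time must be >= 0, got {t}")
    calset.validate()
    organ = spec.organ_mask()
    compartments = spec.compartment_masks()
    container = spec.container_mask()
    if (container & organ).any():
        raise ValueError("container wall intersects the organ")

    depth = ndimage.distance_transform_edt(organ)
    f_stain = np.zeros(spec.shape, dtype=float)
    for name, mask in compartments.items():
        p = spec.compartments[name]
        f_stain[mask] = diffusion_profile(
            depth[mask], p.diffusivity, t, p.f_surface, p.f_max
        )
    f_pmma = np.where(organ, np.maximum(0.0, 1.0 - f_stain), 0.0)
    f_pmma[container] = 1.0
    f_air = np.where(organ | container, 0.0, 1.0)

    truth = GroundTruth(
        f_stain=f_stain,
        f_pmma=f_pmma,
        f_air=f_air,
        organ_mask=organ,
        compartment_masks=compartments,
        container_mask=container,
        time_min=float(t),
        applied_transform=misalign_he,
        shrink_history=spec.shrink_history,
    )
    mu_le = truth.reconstruct(calset, "LE")
    mu_he = truth.reconstruct(calset, "HE")
    vol_le, vol_he = _noisy_pair(mu_le, mu_he, noise, spec.voxel_size_um, spec.center)
    if misalign_he is not None and not misalign_he.is_identity():
        vol_he = apply_rigid_transform(vol_he, misalign_he, fill=calset.he["air"])
    return vol_le, vol_he, truth


def apply_shrinkage(spec: OrganPhantomSpec, s: float) -> OrganPhantomSpec:
    """Shrink (or swell) the organ by volume ratio s about its centroid.

    All linear organ dimensions scale by ``s**(1/3)`` so the enclosed volume
    scales by ``s``; the container and grid are unchanged.
    """
    if not (0 < s <= 1.25):
        raise ValueError(f"shrinkage factor must be in (0, 1.25], got {s}")
    if s == 1.0:
        return replace(spec, shrink_history=spec.shrink_history + (1.0,))
    lin = s ** (1.0 / 3.0)
    return replace(
        spec,
        semiaxes=tuple(a * lin for a in spec.semiaxes),
        heart_split_offset=spec.heart_split_offset * lin,
        shrink_history=spec.shrink_history + (float(s),),
    )


def add_cupping_bias(
    vol: AttenuationVolume,
    beta: float,
    center: tuple[float, float, float] | None = None,
) -> AttenuationVolume:
    """Apply a radial cupping bias emulating beam hardening.

    ``mu'(p) = mu(p) * (1 - beta * (1 - r(p)/R))`` where ``r`` is the distance
    from ``center`` (grid center by default) and ``R`` the largest in-grid
    distance from it; values at the center are depressed by the full factor
    ``1 - beta`` and recover towards the periphery.
    """
    if not abs(beta) < 1:
        raise ValueError(f"cupping strength must satisfy |beta| < 1, got {beta}")
    if beta == 0.0:
        return vol.with_data(vol.data.copy())
    shape = np.asarray(vol.data.shape)
    c = (
        np.asarray(center, dtype=float)
        if center is not None
        else (shape - 1.0) / 2.0
    )
    z, y, x = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij", sparse=True)
    r = np.sqrt((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2)
    corners = np.array(
        [[dz, dy, dx] for dz in (0, shape[0] - 1) for dy in (0, shape[1] - 1) for dx in (0, shape[2] - 1)],
        dtype=float,
    )
    big_r = float(np.max(np.linalg.norm(corners - c, axis=1)))
    return vol.with_data(vol.data * (1.0 - beta * (1.0 - r / big_r)))


def simulate_staining_series(
    spec: OrganPhantomSpec,
    calset: CalibrationSet,
    times_min: list[float],
    shrinkages: list[float] | None = None,
    noise: NoiseSpec = NoiseSpec(),
    misalign_he: RigidTransform | None = None,
) -> list[tuple[float, AttenuationVolume, AttenuationVolume, GroundTruth]]:
    """Simulate a sequential staining experiment.

    ``shrinkages[i]`` is the volume ratio applied going into time point ``i``
    (the baseline entry, if given, should be 1). Each time point gets an
    independent noise realisation derived from ``noise.seed``.
    """
    if shrinkages is not None and len(shrinkages) != len(times_min):
        raise ValueError("shrinkages must align with times")
    out = []
    current = spec
    for i, t in enumerate(times_min):
        if shrinkages is not None and i > 0:
            current = apply_shrinkage(current, shrinkages[i])
        step_noise = replace(noise, seed=noise.seed + i)
        out.append((t, *make_organ_phantom(current, calset, t, step_noise, misalign_he)))
    return out
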
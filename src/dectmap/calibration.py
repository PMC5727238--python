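"""Phantom-based calibration of the dual-energy basis materials.

A calibration scan images a PMMA rod (soft-tissue-equivalent) and a tube of
the staining solution under the same settings as the sample scans. The basis
attenuation coefficient of each material, per spectrum, is the mean of the
reconstructed values over its region; air comes from phantom-free regions.
These six numbers form the matrix of the voxel-wise decomposition system, so
calibration also checks that the two spectra actually separate the materials
(the columns of the system must not be collinear).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import trim_mean

from .volume import AttenuationVolume, as_mask

MATERIALS = ("stain", "pmma", "air")

#: Warn when the column-normalized 2x2 system is worse-conditioned than this.
DEFAULT_CONDITION_THRESHOLD = 20.0


@dataclass
class CalibrationSet:
    """Basis attenuation coefficients (mm^-1) for stain, PMMA and air.

    ``le`` and ``he`` each map material name -> coefficient for the low- and
    high-energy spectrum respectively. ``kvp`` carries the peak tube voltages
    of the two spectra; ``meta`` records provenance (region sizes, labels).
    """

    le: dict[str, float]
    he: dict[str, float]
    kvp: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for coeffs in (self.le, self.he):
            missing = set(MATERIALS) - set(coeffs)
            if missing:
                raise ValueError(f"calibration set missing materials: {sorted(missing)}")

    def matrix2(self) -> np.ndarray:
        """2x2 system matrix [[mu_stain,LE, mu_pmma,LE], [mu_stain,HE, mu_pmma,HE]]."""
        return np.array(
            [
                [self.le["stain"], self.le["pmma"]],
                [self.he["stain"], self.he["pmma"]],
            ]
        )

    def matrix3(self) -> np.ndarray:
        """2x3 attenuation rows for the three-material system (stain, PMMA, air)."""
        return np.array(
            [
                [self.le[m] for m in MATERIALS],
                [self.he[m] for m in MATERIALS],
            ]
        )

    def validate(self, condition_threshold: float = DEFAULT_CONDITION_THRESHOLD) -> None:
        """Raise if the set cannot support a meaningful decomposition."""
        report = conditioning(self, condition_threshold)
        if not np.isfinite(report.condition):
            raise ValueError(
                "calibration set is singular: the two spectra do not separate "
                "stain from PMMA (collinear response)"
            )
        mu_pmma = max(abs(self.le["pmma"]), abs(self.he["pmma"]))
        if max(abs(self.le["air"]), abs(self.he["air"])) >= 0.1 * mu_pmma:
            raise ValueError("air coefficients are not small relative to PMMA")


@dataclass(frozen=True)
class ConditioningReport:
    """Angular conditioning of the dual-energy system."""

    condition: float
    passed: bool
    threshold: float


def synthetic_calibration_i2e() -> CalibrationSet:
    """Synthetic I2E-like basis coefficients (mm^-1) for demonstrations/tests.

    These are plausible effective values for an iodine-stained acquisition at
    40.2/70.1 kVp (strong photoelectric uptake of iodine at low energy); they
    are package defaults, not measured values.
    """
    return CalibrationSet(
        le={"stain": 3.2, "pmma": 0.7, "air": 0.0},
        he={"stain": 1.1, "pmma": 0.5, "air": 0.0},
        kvp=(40.2, 70.1),
        meta={"provenance": "synthetic preset (I2E-like)"},
    )


def synthetic_calibration_gadovist() -> CalibrationSet:
    """Synthetic Gadovist-like basis coefficients (mm^-1); 60.2/140.0 kVp."""
    return CalibrationSet(
        le={"stain": 2.1, "pmma": 0.55, "air": 0.0},
        he={"stain": 0.75, "pmma": 0.45, "air": 0.0},
        kvp=(60.2, 140.0),
        meta={"provenance": "synthetic preset (Gadovist-like)"},
    )


def estimate_basis(
    vol_le: AttenuationVolume,
    vol_he: AttenuationVolume,
    regions: dict[str, np.ndarray],
    estimator: str = "mean",
    trim: float = 0.1,
    kvp: tuple[float, float] | None = None,
) -> CalibrationSet:
    """Estimate the basis coefficients from a calibration phantom pair.

    Parameters
    ----------
    regions:
        Material name -> boolean mask of the voxels to average, one per
        material in ``("stain", "pmma", "air")``. Masks must be non-empty,
        mutually disjoint and congruent with the volumes.
    estimator:
        ``"mean"`` (the standard estimator) or ``"trimmed"`` (symmetric
        trimmed mean with fraction ``trim`` cut from each tail, for
        artifact-laden regions).
    """
    vol_le.check_congruent(vol_he)
    masks = {}
    for name in MATERIALS:
        if name not in regions:
            raise ValueError(f"missing region for material {name!r}")
        masks[name] = as_mask(regions[name], like=vol_le)
        if not masks[name].any():
            raise ValueError(f"region for material {name!r} is empty")
    total = sum(m.astype(int) for m in masks.values())
    if (total > 1).any():
        raise ValueError("calibration regions overlap")

    def estimate(values: np.ndarray) -> float:
        if estimator == "mean":
            return float(values.mean())
        if estimator == "trimmed":
            return float(trim_mean(values, trim))
        raise ValueError(f"unknown estimator {estimator!r}")

    le = {name: estimate(vol_le.data[masks[name]]) for name in MATERIALS}
    he = {name: estimate(vol_he.data[masks[name]]) for name in MATERIALS}
    meta = {
        "region_voxels": {name: int(masks[name].sum()) for name in MATERIALS},
        "estimator": estimator,
        "spectra": (vol_le.spectrum or "LE", vol_he.spectrum or "HE"),
    }
    for name, n in meta["region_voxels"].items():
        if n < 100:
            meta.setdefault("warnings", []).append(
                f"region {name!r} has only {n} voxels (< 100); noisy estimate"
            )
    return CalibrationSet(le=le, he=he, kvp=kvp, meta=meta)


def conditioning(
    calset: CalibrationSet, threshold: float = DEFAULT_CONDITION_THRESHOLD
) -> ConditioningReport:
    """2-norm condition number of the column-normalized 2x2 system.

    Columns are normalized to unit length first, so the number measures the
    angular separation of the stain and PMMA responses across the two spectra
    (1 = orthogonal, infinity = collinear, i.e. no separation).
    """
    a = calset.matrix2()
    norms = np.linalg.norm(a, axis=0)
    if np.any(norms == 0):
        return ConditioningReport(np.inf, False, threshold)
    a = a / norms
    if abs(np.linalg.det(a)) < 1e-15:
        return ConditioningReport(np.inf, False, threshold)
    cond = float(np.linalg.cond(a, 2))
    return ConditioningReport(cond, cond <= threshold, threshold)
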
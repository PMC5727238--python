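"""Downstream quantification of staining experiments.

Covers the standard read-outs of a sequential staining study: sample volume
by voxel counting (internal cavities included), relative volume time-courses,
mean attenuation over a mask, 2D low/high-energy correlation histograms, and
per-tissue stain-uptake summaries from fraction maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .decomposition import FractionMap
from .volume import AttenuationVolume, as_mask


@dataclass
class VolumeTimeSeries:
    """Sample volume versus staining time."""

    times_min: np.ndarray
    volumes_um3: np.ndarray
    relative: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times_min,
                "volume_um3": self.volumes_um3,
                "relative_volume": self.relative,
            }
        )


@dataclass
class CorrelationHistogram2D:
    """Joint histogram of (mu_LE, mu_HE) voxel pairs over a mask.

    ``counts[i, j]`` is the number of voxels whose LE value falls in LE bin i
    and HE value in HE bin j. Out-of-range values are clipped into the edge
    bins, so the total count always equals the mask cardinality.
    """

    le_edges: np.ndarray
    he_edges: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        le_centers = 0.5 * (self.le_edges[:-1] + self.le_edges[1:])
        he_centers = 0.5 * (self.he_edges[:-1] + self.he_edges[1:])
        le, he = np.meshgrid(le_centers, he_centers, indexing="ij")
        return pd.DataFrame(
            {
                "mu_le_mm^-1": le.ravel(),
                "mu_he_mm^-1": he.ravel(),
                "count": self.counts.ravel().astype(int),
            }
        )


@dataclass
class UptakeSummary:
    """Per-tissue stain fraction statistics at one staining time."""

    time_min: float
    per_label: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": label,
                "time_min": self.time_min,
                "mean_f_stain": stats["mean"],
                "max_f_stain": stats["max"],
                "voxel_count": stats["count"],
            }
            for label, stats in self.per_label.items()
        ]
        return pd.DataFrame(rows)


def auto_threshold(vol: AttenuationVolume) -> float:
    """Automatic two-class (Otsu) attenuation threshold, for synthetic demos."""
    return float(threshold_otsu(vol.data))


def sample_volume(
    vol: AttenuationVolume,
    threshold: float,
    container_mask: np.ndarray | None = None,
    voxel_size_um: float | None = None,
) -> float:
    """Sample volume in um^3 by thresholding and voxel counting.

    Voxels below ``threshold`` are treated as air; container voxels are
    removed before thresholding. Holes and chambers fully enclosed by the
    sample cannot be reached by a flood fill from the grid border and are
    counted as part of the sample (they are filled before counting). The
    result is the filled-voxel count times the cubed voxel size.
    """
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    voxel = vol.voxel_size_um if voxel_size_um is None else voxel_size_um
    if voxel <= 0:
        raise ValueError(f"voxel size must be positive, got {voxel}")
    binary = vol.data >= threshold
    if container_mask is not None:
        binary &= ~as_mask(container_mask, like=vol)
    filled = ndimage.binary_fill_holes(binary)
    return float(filled.sum()) * voxel**3


def relative_volume_series(
    measurements: list[tuple[float, float]]
) -> VolumeTimeSeries:
    """Relative volume time-course, normalised to the first (baseline) point."""
    if not measurements:
        raise ValueError("at least one (time, volume) measurement is required")
    times = np.asarray([t for t, _ in measurements], dtype=float)
    vols = np.asarray([v for _, v in measurements], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(vols < 0):
        raise ValueError("volumes must be >= 0")
    if vols[0] == 0:
        raise ValueError("baseline volume is zero; relative volumes undefined")
    return VolumeTimeSeries(times, vols, vols / vols[0])


def mean_attenuation(vol: AttenuationVolume, mask: np.ndarray) -> float:
    """Arithmetic mean attenuation (mm^-1) over the in-mask voxels."""
    mask = as_mask(mask, like=vol)
    if not mask.any():
        raise ValueError("mask is empty")
    return float(vol.data[mask].mean())


def correlation_histogram2d(
    vol_le: AttenuationVolume,
    vol_he: AttenuationVolume,
    mask: np.ndarray | None = None,
    le_edges: np.ndarray | None = None,
    he_edges: np.ndarray | None = None,
    bins: int = 256,
) -> CorrelationHistogram2D:
    """2D correlation histogram of low- vs high-energy attenuation.

    Default edges span the 0.1-99.9 percentile range per channel with
    ``bins`` bins; values outside the range are clipped into the edge bins so
    every in-mask voxel is counted exactly once.
    """
    vol_le.check_congruent(vol_he)
    mask = (
        np.ones(vol_le.data.shape, dtype=bool)
        if mask is None
        else as_mask(mask, like=vol_le)
    )
    le = vol_le.data[mask]
    he = vol_he.data[mask]

    def default_edges(values: np.ndarray) -> np.ndarray:
        lo, hi = np.percentile(values, [0.1, 99.9])
        if hi <= lo:
            hi = lo + 1e-6
        return np.linspace(lo, hi, bins + 1)

    le_edges = default_edges(le) if le_edges is None else np.asarray(le_edges, float)
    he_edges = default_edges(he) if he_edges is None else np.asarray(he_edges, float)
    for edges in (le_edges, he_edges):
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("histogram edges must be strictly increasing 1D arrays")

    le = np.clip(le, le_edges[0], le_edges[-1])
    he = np.clip(he, he_edges[0], he_edges[-1])
    counts, _, _ = np.histogram2d(le, he, bins=(le_edges, he_edges))
    return CorrelationHistogram2D(le_edges, he_edges, counts)


def uptake_summary(
    fmap: FractionMap,
    tissue_masks: dict[str, np.ndarray],
    t: float,
) -> UptakeSummary:
    """Per-tissue mean/max stain fraction at staining time ``t``.

    Labels whose mask contains no computed voxel are reported with zero
    count (never silently dropped). Masks must be mutually disjoint.
    """
    total = None
    for name, m in tissue_masks.items():
        m = np.asarray(m).astype(bool)
        total = m.astype(int) if total is None else total + m.astype(int)
    if total is not None and (total > 1).any():
        raise ValueError("tissue masks overlap")
    summary = UptakeSummary(time_min=float(t))
    for name, m in tissue_masks.items():
        m = np.asarray(m).astype(bool) & fmap.valid
        values = fmap.f_stain[m]
        if values.size == 0:
            summary.per_label[name] = {"mean": np.nan, "max": np.nan, "count": 0}
        else:
            summary.per_label[name] = {
                "mean": float(values.mean()),
                "max": float(values.max()),
                "count": int(values.size),
            }
    return summary
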
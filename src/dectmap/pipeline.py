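"""End-to-end analysis: register -> filter -> decompose -> quantify.

A :class:`PipelineConfig` lists the on-disk inputs (one LE/HE volume pair per
staining time point, a calibration file, optional masks) and the analysis
settings. :func:`run_pipeline` executes every stage per time point, writes
fraction maps, CSV tables and histograms into the output directory, and
records a manifest with the config hash, seed and content hashes of all
numeric outputs so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as dio
from .decomposition import decompose_volume
from .preprocess import RegistrationOptions, median_filter, register_rigid
from .quantify import (
    correlation_histogram2d,
    mean_attenuation,
    relative_volume_series,
    sample_volume,
    uptake_summary,
)
from .volume import as_mask

log = logging.getLogger("dectmap")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending file."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Inputs and settings for a full staining-series analysis."""

    time_points: list[dict]  # each: {time_min, le, he}
    calibration: str
    output_dir: str
    mode: str = "three_material_soft"
    sum_weight: float = 1.0
    median_radius: int = 1
    register: bool = True
    volume_threshold: float | None = None
    sample_mask: str | None = None
    container_mask: str | None = None
    tissue_masks: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def digest(self) -> str:
        doc = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()


def _require(path: str | None, stage: str) -> Path | None:
    if path is None:
        return None
    p = Path(path)
    if not p.exists():
        raise PipelineError(stage, f"missing input file: {p}")
    return p


def _array_digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    log.addHandler(handler)
    try:
        return _run(config, out_dir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out_dir: Path) -> dict:
    calset = dio.read_calibration(_require(config.calibration, "calibrate"))
    calset.validate()

    sample_mask = container_mask = None
    if config.sample_mask:
        sample_mask = dio.read_mask(_require(config.sample_mask, "masks"))
    if config.container_mask:
        container_mask = dio.read_mask(_require(config.container_mask, "masks"))
    tissue_masks = {
        name: dio.read_mask(_require(path, "masks"))
        for name, path in config.tissue_masks.items()
    }

    volume_rows: list[tuple[float, float]] = []
    attenuation_rows: list[dict] = []
    uptake_frames = []
    hashes: dict[str, str] = {}

    for point in sorted(config.time_points, key=lambda p: p["time_min"]):
        t = float(point["time_min"])
        tag = f"t{t:g}min"
        try:
            vol_le = dio.read_volume(_require(point["le"], "read"))
            vol_he = dio.read_volume(_require(point["he"], "read"))
        except (ValueError, FileNotFoundError) as e:
            raise PipelineError("read", str(e)) from e

        if config.register:
            reg = register_rigid(vol_he, vol_le, RegistrationOptions())
            if not reg.converged:
                raise PipelineError("register", f"{tag}: {reg.message}")
            vol_he = reg.resampled
            dio.write_transform(reg.transform, out_dir / f"{tag}_he_to_le.yaml")
        else:
            log.warning("%s: registration disabled; volumes assumed aligned", tag)

        vol_le = median_filter(vol_le, config.median_radius)
        vol_he = median_filter(vol_he, config.median_radius)

        fmap = decompose_volume(
            vol_le, vol_he, calset, config.mode, sample_mask, config.sum_weight
        )
        dio.write_fraction_map(fmap, out_dir / f"{tag}_fractions", vol_le.voxel_size_um)
        hashes[f"{tag}/f_stain"] = _array_digest(np.nan_to_num(fmap.f_stain))

        threshold = config.volume_threshold
        if threshold is None:
            from .quantify import auto_threshold

            threshold = auto_threshold(vol_le)
        vol_um3 = sample_volume(vol_le, threshold, container_mask)
        volume_rows.append((t, vol_um3))

        att_mask = (
            sample_mask
            if sample_mask is not None
            else vol_le.data >= threshold
        )
        attenuation_rows.append(
            {
                "time_min": t,
                "mean_mu_le_mm^-1": mean_attenuation(vol_le, att_mask),
                "mean_mu_he_mm^-1": mean_attenuation(vol_he, att_mask),
                "threshold_mm^-1": threshold,
            }
        )

        hist = correlation_histogram2d(vol_le, vol_he, mask=as_mask(att_mask))
        hist.to_frame().to_csv(out_dir / f"{tag}_histogram.csv", index=False)
        hashes[f"{tag}/histogram"] = _array_digest(hist.counts)

        if tissue_masks:
            uptake_frames.append(uptake_summary(fmap, tissue_masks, t).to_frame())

    series = relative_volume_series(volume_rows)
    series.to_frame().to_csv(out_dir / "volume_timecourse.csv", index=False)
    hashes["volume_timecourse"] = _array_digest(series.relative)

    import pandas as pd

    att = pd.DataFrame(attenuation_rows)
    att.to_csv(out_dir / "attenuation_timecourse.csv", index=False)
    hashes["attenuation_timecourse"] = _array_digest(att["mean_mu_le_mm^-1"].to_numpy())

    if uptake_frames:
        pd.concat(uptake_frames, ignore_index=True).to_csv(
            out_dir / "uptake_summary.csv", index=False
        )

    import dectmap

    manifest = {
        "package_version": dectmap.__version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "mode": config.mode,
        "n_time_points": len(config.time_points),
        "output_hashes": dict(sorted(hashes.items())),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
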
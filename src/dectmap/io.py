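"""On-disk formats.

Canonical volume format: a multi-page 32-bit float TIFF stack (one page per
z-slice) plus a YAML sidecar of the same stem carrying the voxel size and
optional metadata. Integer TIFFs are supported when the sidecar provides a
``scale`` (attenuation per stored unit); a missing voxel size is always an
explicit error, never a silent default. Directories of per-slice 2D TIFFs are
read as stacks in sorted filename order. Masks are 8-bit TIFFs (0/255).
Calibration sets and rigid transforms are YAML with units stated.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .calibration import CalibrationSet
from .decomposition import FractionMap
from .transforms import RigidTransform
from .volume import AttenuationVolume


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml") if path.is_dir() else path.with_suffix(".yaml")


def write_volume(vol: AttenuationVolume, path: str | Path, dtype: str = "float32") -> Path:
    """Write a volume as a multi-page TIFF with a YAML sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "voxel_size_um": float(vol.voxel_size_um),
        "axis_order": "zyx",
        "units": "mm^-1",
    }
    if vol.spectrum:
        sidecar["spectrum"] = vol.spectrum
    tifffile.imwrite(path, vol.data.astype(dtype))
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path


def read_volume(path: str | Path) -> AttenuationVolume:
    """Read a TIFF stack (file or directory of slices) with its YAML sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not slices:
            raise ValueError(f"directory {path} contains no TIFF slices")
        planes = [tifffile.imread(p) for p in slices]
        shapes = {p.shape for p in planes}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        data = np.stack(planes)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise ValueError(
            f"missing voxel-size metadata: expected sidecar {sidecar_path}"
        )
    sidecar = yaml.safe_load(sidecar_path.read_text()) or {}
    if "voxel_size_um" not in sidecar:
        raise ValueError(f"sidecar {sidecar_path} lacks required key 'voxel_size_um'")
    data = np.asarray(data, dtype=np.float64)
    if "scale" in sidecar:
        data = data * float(sidecar["scale"])
    return AttenuationVolume(
        data,
        float(sidecar["voxel_size_um"]),
        spectrum=str(sidecar.get("spectrum", "")),
        meta={k: v for k, v in sidecar.items() if k not in ("voxel_size_um", "spectrum")},
    )


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask).astype(bool) * np.uint8(255)))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    data = tifffile.imread(Path(path))
    if data.ndim == 2:
        data = data[None]
    return data > 0


def write_calibration(calset: CalibrationSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "units": "mm^-1",
        "le": {k: float(v) for k, v in calset.le.items()},
        "he": {k: float(v) for k, v in calset.he.items()},
        "kvp": list(calset.kvp) if calset.kvp else None,
        "meta": calset.meta,
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_calibration(path: str | Path) -> CalibrationSet:
    doc = yaml.safe_load(Path(path).read_text())
    return CalibrationSet(
        le={k: float(v) for k, v in doc["le"].items()},
        he={k: float(v) for k, v in doc["he"].items()},
        kvp=tuple(doc["kvp"]) if doc.get("kvp") else None,
        meta=doc.get("meta", {}),
    )


def write_transform(tf: RigidTransform, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "translation_vox_zyx": [float(v) for v in tf.translation],
        "rotation_deg_intrinsic_zyx": [float(a) for a in tf.rotation_deg],
        "convention": "content-moving; rotation about volume center",
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_transform(path: str | Path) -> RigidTransform:
    doc = yaml.safe_load(Path(path).read_text())
    return RigidTransform(
        tuple(doc["translation_vox_zyx"]), tuple(doc["rotation_deg_intrinsic_zyx"])
    )


def write_fraction_map(fmap: FractionMap, directory: str | Path, voxel_size_um: float) -> Path:
    """Write a fraction map as one TIFF per channel plus residual and validity.

    Not-computed voxels are NaN in the float channels; ``valid.tiff`` is the
    accompanying bit-exact validity mask.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    channels = {
        "f_stain": fmap.f_stain,
        "f_pmma": fmap.f_pmma,
        "f_air": fmap.f_air,
        "residual": fmap.residual,
    }
    for name, data in channels.items():
        vol = AttenuationVolume(np.nan_to_num(data, nan=np.nan), voxel_size_um)
        write_volume(vol, directory / f"{name}.tiff")
    write_mask(fmap.valid, directory / "valid.tiff")
    (directory / "mode.yaml").write_text(
        yaml.safe_dump({"mode": fmap.mode, "meta": _yaml_safe(fmap.meta)}, sort_keys=False)
    )
    return directory


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
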
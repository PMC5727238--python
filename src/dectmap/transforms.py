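"""Rigid 3D transforms on voxel grids.

Convention (fixed package-wide): a :class:`RigidTransform` moves content. A
point ``p`` (index coordinates, ``(z, y, x)`` order) maps to

    T(p) = R (p - c) + c + t

where ``R`` is the rotation given by intrinsic z-y-x Euler angles in degrees,
``c`` is the rotation center (the volume center by default) and ``t`` the
translation in voxels. "Rotation about z" therefore rotates within the (y, x)
slice plane. Resampling uses trilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import AttenuationVolume


def _wrap_angle(a: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def _rot_z(a: float) -> np.ndarray:
    # acts on (z, y, x) index vectors: mixes y and x
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion: translation in voxels plus intrinsic z-y-x Euler rotation.

    Attributes
    ----------
    translation:
        ``(tz, ty, tx)`` in voxels.
    rotation_deg:
        ``(rz, ry, rx)`` Euler angles in degrees, applied intrinsically in
        z, then y, then x order; reported wrapped to (-180, 180].
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vals = (*self.translation, *self.rotation_deg)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"transform parameters must be finite, got {vals}")
        object.__setattr__(
            self, "translation", tuple(float(v) for v in self.translation)
        )
        object.__setattr__(
            self, "rotation_deg", tuple(_wrap_angle(float(a)) for a in self.rotation_deg)
        )

    @property
    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix acting on (z, y, x) index vectors."""
        rz, ry, rx = np.deg2rad(self.rotation_deg)
        return _rot_z(rz) @ _rot_y(ry) @ _rot_x(rx)

    def is_identity(self, tol: float = 0.0) -> bool:
        return all(abs(v) <= tol for v in self.translation) and all(
            abs(a) <= tol for a in self.rotation_deg
        )

    def inverse(self) -> "RigidTransform":
        """The transform undoing this one (about the same center)."""
        r_inv = self.matrix.T
        t_inv = -r_inv @ np.asarray(self.translation)
        rz, ry, rx = _euler_zyx_from_matrix(r_inv)
        return RigidTransform(tuple(t_inv), (rz, ry, rx))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        r = self.matrix @ other.matrix
        t = self.matrix @ np.asarray(other.translation) + np.asarray(self.translation)
        return RigidTransform(tuple(t), _euler_zyx_from_matrix(r))


def _euler_zyx_from_matrix(r: np.ndarray) -> tuple[float, float, float]:
    """Recover intrinsic z-y-x Euler angles (degrees) in index-vector space.

    For R = Rz Ry Rx in the (z, y, x) basis used here: R[0,2] = sin(ry),
    R[1,2] = -sin(rz)cos(ry), R[2,2] = cos(rz)cos(ry),
    R[0,1] = -cos(ry)sin(rx), R[0,0] = cos(ry)cos(rx).
    """
    sy = float(np.clip(r[0, 2], -1.0, 1.0))
    ry = np.arcsin(sy)
    if abs(sy) < 1.0 - 1e-12:
        rz = np.arctan2(-r[1, 2], r[2, 2])
        rx = np.arctan2(-r[0, 1], r[0, 0])
    else:  # gimbal lock; fold the x-rotation into z
        rz = np.arctan2(sy * r[1, 0], r[1, 1])
        rx = 0.0
    return (float(np.rad2deg(rz)), float(np.rad2deg(ry)), float(np.rad2deg(rx)))


def apply_rigid_transform(
    vol: AttenuationVolume,
    tf: RigidTransform,
    fill: float = 0.0,
    order: int = 1,
) -> AttenuationVolume:
    """Resample a volume under a rigid motion of its content.

    The output satisfies ``out(p) = vol(T^-1(p))`` with trilinear interpolation
    (``order=1``); voxels mapping outside the input grid take ``fill``.
    Identity transforms and pure integer translations are exact (no
    interpolation smoothing).
    """
    if tf.is_identity():
        return vol.with_data(vol.data.copy())
    center = (np.asarray(vol.data.shape, dtype=float) - 1.0) / 2.0
    r = tf.matrix
    t = np.asarray(tf.translation)
    # ndimage: input_coord = matrix @ output_coord + offset = T^-1(output)
    r_inv = r.T
    offset = center - r_inv @ (center + t)
    # Pure integer translation: resample exactly by index shifting.
    if np.allclose(r, np.eye(3)) and np.allclose(t, np.round(t)):
        out = np.full_like(vol.data, fill)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        n = vol.data.shape
        for ax, shift in enumerate(np.round(t).astype(int)):
            if shift >= 0:
                dst[ax] = slice(shift, n[ax])
                src[ax] = slice(0, n[ax] - shift)
            else:
                dst[ax] = slice(0, n[ax] + shift)
                src[ax] = slice(-shift, n[ax])
        out[tuple(dst)] = vol.data[tuple(src)]
        return vol.with_data(out)
    out = ndimage.affine_transform(
        vol.data, r_inv, offset=offset, order=order, mode="constant", cval=fill
    )
    return vol.with_data(out)
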
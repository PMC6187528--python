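"""Orthographic spherical back-projection and 3D rotation recovery.

A near-spherical object imaged by a microscope camera is modelled as a
perfect sphere of radius ``r`` (pixels) centred at ``(cx, cy)`` in the
image. Under orthographic projection an image pixel inside the disc maps to
the camera-facing surface point

    x = col - cx,   y = cy - row,   z = +sqrt(r^2 - x^2 - y^2),

in a right-handed frame (x right, y up, z toward the camera). A 2D optical
flow vector (u, v) at that pixel is lifted to the 3D surface velocity
``vo = (u, -v, w)`` with ``w = -(x*u' + y*v')/z`` — the unique z-component
making ``vo`` tangent to the sphere (``vo . p = 0``). For a rigid rotation
at angular rate ``w_rad`` about unit axis ``a`` the surface velocity is
``w_rad * (a x p)``, so every lifted flow vector is perpendicular to the
rotation axis; the axis is recovered as the common perpendicular of all
lifted flows, and the per-pixel rotation amplitude (degrees/frame) follows
from ``V = 360 * |vo| / (2 * pi * d)`` where ``d`` is the distance of the
surface point from the axis line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SphereModel",
    "RotationEstimate",
    "DegeneratePairError",
    "InsufficientMotionError",
    "back_project",
    "back_project_grid",
    "lift_flow",
    "lift_flow_grid",
    "axis_from_pair",
    "estimate_axis",
    "point_velocity",
    "estimate_rotation",
    "to_angular_velocity",
]

#: fraction of the radius beyond which the limb is excluded (z lift diverges)
RHO_MAX = 0.95
#: minimum z as a fraction of r for the tangential lift
Z_MIN_FRAC = 0.1
#: flow magnitude (pixels) below which a pixel is treated as noise
MAG_FLOOR = 0.05
#: minimum distance from the axis, as a fraction of r, for velocity votes
D_MIN_FRAC = 0.2
#: minimum number of moving pixels required for an estimate
MIN_VALID_PIXELS = 50
#: rotation amplitudes above this (deg/frame) are outside the validated band
VALID_BAND_DEG = 4.0


class DegeneratePairError(ValueError):
    """Two lifted flow vectors are (near-)parallel; their cross product
    carries no axis information."""


class InsufficientMotionError(ValueError):
    """Too few pixels carry usable motion to estimate a rotation."""


@dataclass(frozen=True)
class SphereModel:
    """Sphere centre (subpixel image coordinates, x = column, y = row,
    origin top-left) and radius, all in pixels."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError(f"radius must be positive, got {self.r}")


@dataclass
class RotationEstimate:
    """Recovered rotation for one frame pair.

    ``axis`` is a unit 3D vector (x right, y up, z toward camera; positive
    amplitude means counter-clockwise about the axis by the right-hand
    rule). ``deg_per_frame`` is the non-negative rotation amplitude.
    ``residual`` is the RMS of the dot products between the unit lifted
    flows and the axis (0 for a perfect rigid rotation).
    """

    axis: np.ndarray
    deg_per_frame: float
    n_valid_pixels: int
    residual: float
    out_of_band: bool = False
    frame_pair: str = ""

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=np.float64)
        n = np.linalg.norm(self.axis)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"axis must be unit length, |axis| = {n}")
        if self.deg_per_frame < 0:
            raise ValueError("deg_per_frame must be non-negative")


def back_project(pixel: tuple[float, float], sphere: SphereModel,
                 rho_max: float = RHO_MAX) -> np.ndarray:
    """Map an image pixel ``(row, col)`` to the camera-facing sphere point.

    Raises ``ValueError`` when the pixel lies outside the admissible disc
    of radius ``rho_max * r``.
    """
    row, col = pixel
    x = col - sphere.cx
    y = sphere.cy - row
    rho2 = x * x + y * y
    if rho2 > (rho_max * sphere.r) ** 2:
        raise ValueError(
            f"pixel {pixel} outside admissible disc (rho_max={rho_max})"
        )
    z = np.sqrt(sphere.r ** 2 - rho2)
    return np.array([x, y, z])


def back_project_grid(shape: tuple[int, int], sphere: SphereModel,
                      rho_max: float = RHO_MAX
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised back-projection of every admissible pixel in an image.

    Returns ``(points, mask)`` with ``points`` of shape (h, w, 3) (zeros
    outside the mask) and ``mask`` the admissible-disc boolean grid.
    """
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    x = cols - sphere.cx
    y = sphere.cy - rows
    rho2 = x * x + y * y
    mask = rho2 <= (rho_max * sphere.r) ** 2
    z = np.sqrt(np.maximum(sphere.r ** 2 - rho2, 0.0))
    points = np.stack([x, y, z], axis=-1)
    points[~mask] = 0.0
    return points, mask


def lift_flow(point: np.ndarray, uv: tuple[float, float],
              z_min: float | None = None, r: float | None = None) -> np.ndarray:
    """Lift a 2D flow vector (u, v), image convention (u = rightward,
    v = downward), to the tangential 3D surface velocity at ``point``.

    ``z_min`` defaults to ``Z_MIN_FRAC * r`` when the radius is given,
    else ``Z_MIN_FRAC * |point|``.
    """
    x, y, z = np.asarray(point, dtype=np.float64)
    if z_min is None:
        z_min = Z_MIN_FRAC * (r if r is not None else float(np.linalg.norm(point)))
    if z <= z_min:
        raise ValueError(f"z = {z} at/below the rim guard z_min = {z_min}")
    u_math = float(uv[0])
    v_math = -float(uv[1])  # image rows grow downward, y grows upward
    w = -(x * u_math + y * v_math) / z
    return np.array([u_math, v_math, w])


def lift_flow_grid(points: np.ndarray, u: np.ndarray, v: np.ndarray,
                   mask: np.ndarray, r: float,
                   z_min_frac: float = Z_MIN_FRAC
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`lift_flow` over a masked grid.

    Returns ``(vo, valid)`` where ``vo`` has shape (h, w, 3) and ``valid``
    excludes pixels with z at or below the rim guard.
    """
    z = points[..., 2]
    valid = mask & (z > z_min_frac * r)
    u_math = u
    v_math = -v
    with np.errstate(divide="ignore", invalid="ignore"):
        w = -(points[..., 0] * u_math + points[..., 1] * v_math) / z
    vo = np.stack([u_math, v_math, np.where(valid, w, 0.0)], axis=-1)
    vo[~valid] = 0.0
    return vo, valid


def axis_from_pair(vo1: np.ndarray, vo2: np.ndarray, r: float,
                   eps: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Axis direction from two tangential surface velocities.

    Both velocities are perpendicular to the rotation axis, so their cross
    product points along it. Returns ``(unit_direction, scaled_vector)``
    where the scaled vector is ``r * (vo1 x vo2) / |vo1 . vo2|`` — kept for
    reporting; it diverges when the two velocities are orthogonal, so only
    the direction is used downstream.

    Raises :class:`DegeneratePairError` for (near-)parallel inputs.
    """
    vo1 = np.asarray(vo1, dtype=np.float64)
    vo2 = np.asarray(vo2, dtype=np.float64)
    cross = np.cross(vo1, vo2)
    n1, n2 = np.linalg.norm(vo1), np.linalg.norm(vo2)
    nc = np.linalg.norm(cross)
    if n1 == 0 or n2 == 0 or nc < eps * n1 * n2:
        raise DegeneratePairError("flow vectors are zero or (near-)parallel")
    direction = cross / nc
    dot = abs(float(vo1 @ vo2))
    if dot > eps * n1 * n2:
        scaled = direction * (r * nc / dot)
    else:  # orthogonal pair: the reported scale diverges, direction is fine
        scaled = np.zeros(3)
        nonzero = direction != 0
        scaled[nonzero] = direction[nonzero] * np.inf
    return direction, scaled


def _valid_flow_mask(points: np.ndarray, mask: np.ndarray,
                     u: np.ndarray, v: np.ndarray, r: float,
                     mag_floor: float) -> np.ndarray:
    mag = np.hypot(u, v)
    return mask & (points[..., 2] > Z_MIN_FRAC * r) & (mag >= mag_floor)


def estimate_axis(flow, sphere: SphereModel,
                  min_pixels: int = MIN_VALID_PIXELS,
                  mag_floor: float = MAG_FLOOR,
                  ) -> tuple[np.ndarray, float, int]:
    """Estimate the unit rotation axis from a dense flow field.

    Every lifted surface velocity of a rigid rotation is perpendicular to
    the axis, so the axis is the direction minimising the projections of
    the unit lifted flows: the eigenvector of the smallest eigenvalue of
    the 3x3 scatter matrix sum_i v_i v_i^T. The sign is fixed by the net
    angular momentum direction of the flow field, sum_i p_i x vo_i, which
    for a rotation at rate w about axis ``a`` equals
    w * sum_i (r^2 a - (p_i . a) p_i) and always has positive component
    along ``a``.

    Returns ``(unit_axis, residual, n_valid)``; raises
    :class:`InsufficientMotionError` when fewer than ``min_pixels`` pixels
    carry flow above ``mag_floor``.
    """
    u, v = flow.u, flow.v
    points, mask = back_project_grid(u.shape, sphere)
    valid = _valid_flow_mask(points, mask, u, v, sphere.r, mag_floor)
    n_valid = int(valid.sum())
    if n_valid < min_pixels:
        raise InsufficientMotionError(
            f"only {n_valid} pixels with |flow| >= {mag_floor} "
            f"(need {min_pixels})"
        )
    vo, lift_ok = lift_flow_grid(points, u, v, valid, sphere.r)
    valid = valid & lift_ok
    p = points[valid]
    vecs = vo[valid]
    units = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    scatter = units.T @ units
    eigvals, eigvecs = np.linalg.eigh(scatter)
    axis = eigvecs[:, 0]  # smallest eigenvalue: most-perpendicular direction
    moment = np.cross(p, vecs).sum(axis=0)
    if moment @ axis < 0:
        axis = -axis
    residual = float(np.sqrt(np.mean((units @ axis) ** 2)))
    return axis, residual, int(valid.sum())


def point_velocity(vo: np.ndarray, point: np.ndarray, axis: np.ndarray,
                   d_min: float) -> float:
    """Rotation amplitude (degrees/frame) implied by one surface velocity.

    ``d`` is the distance from the surface point to the axis line through
    the sphere centre; the amplitude is ``360 * |vo| / (2 * pi * d)``.
    Raises ``ValueError`` when ``d < d_min`` (near-axis points amplify
    flow noise without bound and are skipped upstream).
    """
    point = np.asarray(point, dtype=np.float64)
    axis = np.asarray(axis, dtype=np.float64)
    d = float(np.linalg.norm(point - (point @ axis) * axis))
    if d < d_min:
        raise ValueError(f"point at distance {d} from axis below d_min = {d_min}")
    return 360.0 * float(np.linalg.norm(vo)) / (2.0 * np.pi * d)


def estimate_rotation(flow, sphere: SphereModel,
                      min_pixels: int = MIN_VALID_PIXELS,
                      mag_floor: float = MAG_FLOOR,
                      d_min_frac: float = D_MIN_FRAC,
                      frame_pair: str = "") -> RotationEstimate:
    """Full rotation estimate (axis + amplitude) for one frame pair.

    The axis comes from :func:`estimate_axis`; the amplitude is the median
    of the per-pixel :func:`point_velocity` values over pixels farther than
    ``d_min_frac * r`` from the axis (the median is robust to the limb and
    near-axis outliers the d-division amplifies). Estimates above the
    validated 0-4 degrees/frame operating band are flagged ``out_of_band``
    but still returned.
    """
    axis, residual, _ = estimate_axis(flow, sphere, min_pixels, mag_floor)
    u, v = flow.u, flow.v
    points, mask = back_project_grid(u.shape, sphere)
    valid = _valid_flow_mask(points, mask, u, v, sphere.r, mag_floor)
    vo, lift_ok = lift_flow_grid(points, u, v, valid, sphere.r)
    valid &= lift_ok
    p = points[valid]
    vecs = vo[valid]
    d = np.linalg.norm(p - np.outer(p @ axis, axis), axis=1)
    far = d >= d_min_frac * sphere.r
    if not far.any():
        raise InsufficientMotionError("all moving pixels lie too close to the axis")
    speeds = 360.0 * np.linalg.norm(vecs[far], axis=1) / (2.0 * np.pi * d[far])
    deg = float(np.median(speeds))
    return RotationEstimate(
        axis=axis,
        deg_per_frame=deg,
        n_valid_pixels=int(far.sum()),
        residual=residual,
        out_of_band=deg > VALID_BAND_DEG,
        frame_pair=frame_pair,
    )


def to_angular_velocity(deg_per_frame: float, fps: float) -> tuple[float, float]:
    """Convert a per-frame amplitude to (rad/min, rpm) given the camera
    frame rate. 4 degrees/frame at 32 fps is 134.04 rad/min."""
    if fps <= 0:
        raise ValueError(f"fps must be positive, got {fps}")
    rad_per_min = deg_per_frame * fps * 60.0 * np.pi / 180.0
    rpm = deg_per_frame * fps * 60.0 / 360.0
    return rad_per_min, rpm
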
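"""Ground-truth synthetic data: rendered rotating globes and exact flow.

Two generators validate the measurement chain end to end:

* :func:`render_globe_sequence` draws a procedurally textured sphere
  rotating a fixed amplitude per frame about a fixed axis, orthographically
  projected onto a square image (default 207 x 207), optionally
  semi-transparent over a mid-grey background and degraded with additive
  Gaussian noise, a global brightness drift, and sinusoidal interference
  fringes — the disturbances microscope sequences actually exhibit.
* :func:`analytic_flow` writes down the exact image-plane velocity field
  of the same rigid rotation, ``omega * (a x p)`` orthographically
  projected — the oracle the flow and rotation estimators are tested
  against without any rendering in the loop.

The texture is 3-octave band-limited value noise evaluated on the sphere
surface (no external image assets), contrast-stretched with a fixed affine
map so that frames remain mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow import FlowField
from .io import ImageSequence
from .sphere import SphereModel

__all__ = ["GlobeSpec", "rotation_matrix", "render_globe_sequence",
           "analytic_flow"]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("axis must be nonzero")
    return v / n


@dataclass
class GlobeSpec:
    """Parameters of a rendered rotating globe.

    Defaults reproduce the standard validation condition: a 207 x 207
    frame, radius 50 px (sub-2-pixel rim displacement at 2 degrees/frame,
    inside the flow solver's single-level range), an oblique axis, a
    semi-transparent surface (alpha = 0.7) over a mid-grey background, and
    no added noise (animated templates are noise-free; noise terms are
    opt-in degradations).
    """

    image_size: int = 207
    radius: float = 50.0
    axis: np.ndarray = field(default_factory=lambda: _unit([1.0, 1.0, 2.0]))
    deg_per_frame: float = 2.0
    n_frames: int = 20
    texture_seed: int = 0
    transparency: float = 0.7  # 1 = opaque surface
    noise_sigma: float = 0.0
    fringe_amplitude: float = 0.0
    fringe_period: float = 16.0
    brightness_drift: float = 0.0
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        self.axis = _unit(self.axis)
        if not (0 < self.radius < self.image_size / 2):
            raise ValueError("radius must satisfy 0 < r < image_size / 2")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if not 0.0 <= self.transparency <= 1.0:
            raise ValueError("transparency must lie in [0, 1]")
        if self.noise_sigma < 0 or self.fringe_amplitude < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.fringe_period <= 0:
            raise ValueError("fringe_period must be positive")

    @property
    def center(self) -> float:
        return (self.image_size - 1) / 2.0

    @property
    def sphere(self) -> SphereModel:
        return SphereModel(cx=self.center, cy=self.center, r=self.radius)


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis (right-hand rule)."""
    a = _unit(axis)
    th = np.deg2rad(angle_deg)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


def _value_noise3(points: np.ndarray, freq: float, seed: int) -> np.ndarray:
    """Trilinearly interpolated lattice value noise on unit-sphere points.

    ``points`` has shape (..., 3) with components in [-1, 1]; the lattice
    has ``freq`` cells per unit length, values drawn from a seeded RNG,
    smoothstep-weighted interpolation.
    """
    q = (points + 1.0) * freq  # coordinates in [0, 2 freq]
    n = int(np.ceil(2 * freq)) + 2
    lattice = np.random.default_rng(seed).random((n, n, n))
    i0 = np.floor(q).astype(int)
    i0 = np.clip(i0, 0, n - 2)
    f = q - i0
    f = f * f * (3.0 - 2.0 * f)  # smoothstep
    out = np.zeros(points.shape[:-1])
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wgt = (
                    (f[..., 0] if dx else 1 - f[..., 0])
                    * (f[..., 1] if dy else 1 - f[..., 1])
                    * (f[..., 2] if dz else 1 - f[..., 2])
                )
                out += wgt * lattice[i0[..., 0] + dx, i0[..., 1] + dy,
                                     i0[..., 2] + dz]
    return out


def sphere_texture(points: np.ndarray, r: float, seed: int,
                   octaves: int = 3, base_freq: float = 3.0,
                   contrast: float = 2.5) -> np.ndarray:
    """Seeded 3-octave value-noise texture sampled at sphere-surface
    points, contrast-stretched with a fixed affine map and clipped to
    [0, 1]. A function of 3D position only, so rotating the sample points
    rotates the texture rigidly."""
    p = np.asarray(points, dtype=np.float64) / r
    amps = np.array([0.5 ** o for o in range(octaves)])
    raw = sum(
        a * _value_noise3(p, base_freq * 2 ** o, seed + o)
        for o, a in enumerate(amps)
    ) / amps.sum()
    return np.clip(0.5 + contrast * (raw - 0.5), 0.0, 1.0)


def render_globe_sequence(spec: GlobeSpec
                          ) -> tuple[ImageSequence, np.ndarray, float]:
    """Render the rotating globe; returns (sequence, true_axis,
    true_deg_per_frame).

    Frame k shows the sphere rotated by ``k * deg_per_frame`` about the
    axis: each camera-facing surface point p is mapped back through the
    inverse rotation and the texture sampled there, so the texture rides
    rigidly on the surface. The surface is alpha-composited over a
    mid-grey (0.5) background; fringes, brightness drift and Gaussian
    noise are added afterwards. Bit-reproducible for fixed seeds.
    """
    size, r = spec.image_size, spec.radius
    c = spec.center
    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    x = cols - c
    y = c - rows
    rho2 = x * x + y * y
    disc = rho2 <= r * r
    z = np.sqrt(np.maximum(r * r - rho2, 0.0))
    p = np.stack([x, y, z], axis=-1)

    fringes = spec.fringe_amplitude * np.sin(
        2.0 * np.pi * (rows + cols) / spec.fringe_period)
    noise_rng = np.random.default_rng(
        spec.noise_seed if spec.noise_seed is not None else spec.texture_seed + 1)

    frames = np.empty((spec.n_frames, size, size))
    background = 0.5
    for k in range(spec.n_frames):
        r_inv = rotation_matrix(spec.axis, -k * spec.deg_per_frame)
        p0 = p[disc] @ r_inv.T
        tex = sphere_texture(p0, r, spec.texture_seed)
        frame = np.full((size, size), background)
        frame[disc] = spec.transparency * tex + (1 - spec.transparency) * background
        frame += fringes + k * spec.brightness_drift
        if spec.noise_sigma > 0:
            frame = frame + noise_rng.normal(0.0, spec.noise_sigma, frame.shape)
        frames[k] = np.clip(frame, 0.0, 1.0)
    seq = ImageSequence(frames, source=f"synthetic-globe(seed={spec.texture_seed})")
    return seq, spec.axis.copy(), spec.deg_per_frame


def analytic_flow(sphere: SphereModel, axis, deg_per_frame: float,
                  shape: tuple[int, int] | None = None) -> FlowField:
    """Exact image-plane velocity field of a rigid sphere rotation.

    At each pixel inside the disc the surface velocity is
    ``omega_rad * (a x p)`` with p the camera-facing back-projection; its
    orthographic projection gives ``u = velocity_x`` and ``v = -velocity_y``
    (image rows grow downward). Zero outside the disc.
    """
    a = _unit(axis)
    omega = np.deg2rad(deg_per_frame)
    if shape is None:
        side = int(np.ceil(max(sphere.cx, sphere.cy) + sphere.r + 2))
        shape = (side, side)
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    x = cols - sphere.cx
    y = sphere.cy - rows
    rho2 = x * x + y * y
    disc = rho2 < sphere.r ** 2
    z = np.sqrt(np.maximum(sphere.r ** 2 - rho2, 0.0))
    # a x p, componentwise on the grid
    vx = a[1] * z - a[2] * y
    vy = a[2] * x - a[0] * z
    u = np.where(disc, omega * vx, 0.0)
    v = np.where(disc, -omega * vy, 0.0)
    return FlowField(u, v)
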
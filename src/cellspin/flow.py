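"""Horn-Schunck dense optical flow.

The classical variational formulation: the brightness-constancy constraint
``Ix*u + Iy*v + It = 0`` is combined with a global smoothness penalty on
the flow gradients, and the Euler-Lagrange system is solved by relaxation,

    u <- ubar - Ix * (Ix*ubar + Iy*vbar + It) / (alpha + Ix^2 + Iy^2)
    v <- vbar - Iy * (Ix*ubar + Iy*vbar + It) / (alpha + Ix^2 + Iy^2)

where (ubar, vbar) is the 3x3 weighted neighbourhood average of the
current field. Derivatives are the classical 2x2x2 cube averages over both
frames. No coarse-to-fine pyramid is used: the validated operating band
is at most ~4 degrees/frame, i.e. sub-2-pixel rim displacements for radii
up to ~50 px, which single-level relaxation handles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["FlowField", "HSParams", "compute_derivatives", "horn_schunck",
           "hs_energy"]

#: intensity units per normalised [0, 1] intensity: the regularisation
#: weight alpha is quoted on the classical 0..255 grayscale scale
INTENSITY_SCALE = 255.0

# 3x3 weighted Laplacian surrogate: 1/6 edge-adjacent, 1/12 diagonal
_AVG_KERNEL = np.array([
    [1 / 12, 1 / 6, 1 / 12],
    [1 / 6, 0.0, 1 / 6],
    [1 / 12, 1 / 6, 1 / 12],
])


@dataclass
class FlowField:
    """Per-pixel displacement field between two frames (pixels/frame).

    ``u`` is horizontal (positive rightward along columns), ``v`` vertical
    (positive downward along rows, the image convention).
    """

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must share one shape")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("flow components must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape  # type: ignore[return-value]

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass(frozen=True)
class HSParams:
    """Relaxation parameters: ``alpha`` is the regularisation weight
    (larger = smoother flow), ``tol`` the mean-update stopping threshold
    in pixels."""

    alpha: float = 10.0
    max_iter: int = 300
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be non-negative")


def compute_derivatives(frame1: np.ndarray, frame2: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spatiotemporal intensity derivatives (Ix, Iy, It).

    Each derivative is the average of the four first differences over the
    2x2x2 cube spanning both frames (edge-replicated at the right/bottom
    borders so the output matches the frame shape).
    """
    f1 = np.asarray(frame1, dtype=np.float64)
    f2 = np.asarray(frame2, dtype=np.float64)
    if f1.shape != f2.shape:
        raise ValueError(f"frame shapes differ: {f1.shape} vs {f2.shape}")
    p1 = np.pad(f1, ((0, 1), (0, 1)), mode="edge")
    p2 = np.pad(f2, ((0, 1), (0, 1)), mode="edge")
    ix = 0.25 * ((p1[:-1, 1:] - p1[:-1, :-1]) + (p1[1:, 1:] - p1[1:, :-1])
                 + (p2[:-1, 1:] - p2[:-1, :-1]) + (p2[1:, 1:] - p2[1:, :-1]))
    iy = 0.25 * ((p1[1:, :-1] - p1[:-1, :-1]) + (p1[1:, 1:] - p1[:-1, 1:])
                 + (p2[1:, :-1] - p2[:-1, :-1]) + (p2[1:, 1:] - p2[:-1, 1:]))
    diff = p2 - p1
    it = 0.25 * (diff[:-1, :-1] + diff[:-1, 1:] + diff[1:, :-1] + diff[1:, 1:])
    return ix, iy, it


def _neighborhood_average(a: np.ndarray) -> np.ndarray:
    return ndimage.correlate(a, _AVG_KERNEL, mode="reflect")


def horn_schunck(frame1: np.ndarray, frame2: np.ndarray,
                 params: HSParams | None = None) -> FlowField:
    """Dense flow between two (already preprocessed) frames.

    Starts from zero flow and relaxes until the mean absolute update
    ``mean|du| + mean|dv|`` drops below ``params.tol`` or ``max_iter`` is
    reached. Identical frames are an exact fixed point (zero flow at every
    iteration, since It == 0 there).
    """
    if params is None:
        params = HSParams()
    # alpha is calibrated for the canonical 0..255 intensity scale; frames
    # arrive normalised to [0, 1], so rescale before differentiation (the
    # recovered displacements are unchanged by a common intensity scale).
    ix, iy, it = compute_derivatives(INTENSITY_SCALE * np.asarray(frame1),
                                     INTENSITY_SCALE * np.asarray(frame2))
    den = params.alpha + ix * ix + iy * iy
    u = np.zeros_like(ix)
    v = np.zeros_like(ix)
    for k in range(params.max_iter):
        ubar = _neighborhood_average(u)
        vbar = _neighborhood_average(v)
        t = (ix * ubar + iy * vbar + it) / den
        u_new = ubar - ix * t
        v_new = vbar - iy * t
        if not (np.isfinite(u_new).all() and np.isfinite(v_new).all()):
            raise FloatingPointError(
                f"non-finite flow values at relaxation iteration {k}"
            )
        delta = float(np.mean(np.abs(u_new - u)) + np.mean(np.abs(v_new - v)))
        u, v = u_new, v_new
        if delta < params.tol:
            break
    return FlowField(u, v)


def hs_energy(u: np.ndarray, v: np.ndarray, ix: np.ndarray, iy: np.ndarray,
              it: np.ndarray, alpha: float) -> float:
    """Discrete objective: data term plus alpha-weighted smoothness term.

    Used by the test suite to check that relaxation does not increase the
    energy; not needed by the solver itself.
    """
    uy, ux = np.gradient(u)
    vy, vx = np.gradient(v)
    smooth = ux ** 2 + uy ** 2 + vx ** 2 + vy ** 2
    data = (ix * u + iy * v + it) ** 2
    return float(np.sum(data + alpha * smooth))
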
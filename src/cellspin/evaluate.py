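"""Validation metrics against ground truth.

A recovered axis counts as correct when it lies within 10 degrees of the
true axis, compared sign-agnostically (the visible-hemisphere ambiguity
makes the axis sign unobservable in principle); a recovered amplitude
counts as correct within 10% relative error by default. Error rates are
the percentage of incorrect frame-pair results. Amplitude series over a
frame gap n multiply the per-frame step: a sequence stepping delta per
frame analysed at gap n should report n * delta.
"""

from __future__ import annotations

import numpy as np

from .flow import HSParams
from .io import ImageSequence
from .pipeline import analyze_sequence
from .preprocess import DEFAULT_SIGMA
from .sphere import RotationEstimate, SphereModel

__all__ = [
    "rotation_series",
    "amplitude_series",
    "axis_angle_deg",
    "axis_error_rate",
    "velocity_error_rate",
]


def rotation_series(sequence: ImageSequence, sphere: SphereModel, gap: int = 1,
                    hs_params: HSParams | None = None,
                    sigma: float = DEFAULT_SIGMA) -> list[RotationEstimate]:
    """Full rotation estimates for every frame pair (i, i + gap)."""
    if gap < 1:
        raise ValueError("gap must be >= 1")
    if len(sequence) <= gap:
        raise ValueError(f"gap {gap} leaves no frame pairs in a "
                         f"{len(sequence)}-frame sequence")
    return analyze_sequence(sequence, sphere=sphere, gap=gap,
                            hs_params=hs_params, sigma=sigma)


def amplitude_series(sequence: ImageSequence, sphere: SphereModel, gap: int = 1,
                     hs_params: HSParams | None = None,
                     sigma: float = DEFAULT_SIGMA) -> list[float]:
    """Per-pair rotation amplitudes (degrees) at frame gap ``gap``.

    A sequence of L frames at gap 1 yields L - 1 amplitudes.
    """
    return [e.deg_per_frame
            for e in rotation_series(sequence, sphere, gap, hs_params, sigma)]


def axis_angle_deg(axis: np.ndarray, truth: np.ndarray) -> float:
    """Sign-agnostic angle (degrees) between two axis lines:
    min(theta, 180 - theta)."""
    a = np.asarray(axis, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    cosang = abs(a @ t) / (np.linalg.norm(a) * np.linalg.norm(t))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def axis_error_rate(axes, truth, threshold: float = 10.0) -> float:
    """Percentage of recovered axes farther than ``threshold`` degrees
    from the true axis line."""
    axes = list(axes)
    if not axes:
        raise ValueError("estimates must be nonempty")
    wrong = sum(axis_angle_deg(a, truth) >= threshold for a in axes)
    return 100.0 * wrong / len(axes)


def velocity_error_rate(amplitudes, truth: float,
                        rel_threshold: float = 0.1) -> float:
    """Percentage of amplitudes with relative error above
    ``rel_threshold`` of the true amplitude."""
    if truth <= 0:
        raise ValueError("truth must be positive")
    amps = np.asarray(list(amplitudes), dtype=np.float64)
    if amps.size == 0:
        raise ValueError("estimates must be nonempty")
    wrong = np.abs(amps - truth) / truth > rel_threshold
    return 100.0 * float(wrong.sum()) / amps.size
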
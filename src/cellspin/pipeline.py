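"""End-to-end rotation analysis: detection -> preprocessing -> optical
flow -> spherical rotation recovery, applied over a whole image sequence.
"""

from __future__ import annotations

import logging

import numpy as np

from .detect import Template, Trajectory, track_cell
from .flow import HSParams, horn_schunck
from .io import ImageSequence
from .preprocess import DEFAULT_SIGMA, normalize_brightness, smooth_sequence
from .sphere import RotationEstimate, SphereModel, estimate_rotation

__all__ = ["analyze_sequence", "static_trajectory"]

log = logging.getLogger(__name__)

#: crop half-size margin beyond the sphere radius (covers the admissible
#: disc plus the flow solver's neighbourhood support)
ROI_MARGIN = 1.1


def static_trajectory(sequence: ImageSequence, sphere: SphereModel) -> Trajectory:
    """Trajectory for an object known to be stationary (e.g. a rendered
    globe pinned at the frame centre)."""
    return Trajectory([sphere] * len(sequence), [1.0] * len(sequence))


def _crop_box(sphere: SphereModel, shape: tuple[int, int]) -> tuple[int, int, int, int]:
    half = int(np.ceil(ROI_MARGIN * sphere.r)) + 2
    ci, cj = int(round(sphere.cy)), int(round(sphere.cx))
    i0 = max(0, ci - half)
    j0 = max(0, cj - half)
    i1 = min(shape[0], ci + half + 1)
    j1 = min(shape[1], cj + half + 1)
    return i0, i1, j0, j1


def analyze_sequence(
    sequence: ImageSequence,
    template: Template | None = None,
    sphere: SphereModel | None = None,
    trajectory: Trajectory | None = None,
    hs_params: HSParams | None = None,
    sigma: float = DEFAULT_SIGMA,
    gap: int = 1,
    rng_seed: int = 0,
) -> list[RotationEstimate]:
    """Run the full measurement chain on an image sequence.

    Exactly one localisation source must be available: a precomputed
    ``trajectory``, a fixed ``sphere`` (static object), or a ``template``
    to track with. For a sequence of L frames and frame gap ``gap`` the
    result has L - gap estimates, one per frame pair (i, i + gap).

    Brightness is equalised across the whole sequence and every frame
    Gaussian-smoothed before flow; each pair is then cropped to the
    region of interest around the first frame's sphere position, dense
    Horn-Schunck flow computed, and the 3D rotation recovered by
    orthographic spherical back-projection.
    """
    if gap < 1:
        raise ValueError("gap must be >= 1")
    if len(sequence) <= gap:
        raise ValueError(
            f"sequence of length {len(sequence)} has no frame pairs at gap {gap}"
        )
    if trajectory is None:
        if sphere is not None:
            trajectory = static_trajectory(sequence, sphere)
        elif template is not None:
            trajectory = track_cell(sequence, template, rng_seed=rng_seed)
        else:
            raise ValueError("provide a trajectory, a sphere, or a template")
    if len(trajectory) != len(sequence):
        raise ValueError("trajectory length must match the sequence")

    hs_params = hs_params or HSParams()
    prepped = smooth_sequence(normalize_brightness(sequence), sigma)

    estimates: list[RotationEstimate] = []
    for i in range(len(sequence) - gap):
        sph = trajectory.spheres[i]
        i0, i1, j0, j1 = _crop_box(sph, prepped.frame_shape)
        f1 = prepped[i][i0:i1, j0:j1]
        f2 = prepped[i + gap][i0:i1, j0:j1]
        local = SphereModel(cx=sph.cx - j0, cy=sph.cy - i0, r=sph.r)
        field = horn_schunck(f1, f2, hs_params)
        est = estimate_rotation(field, local, frame_pair=f"{i}-{i + gap}")
        log.debug("pair %s: axis=%s deg/frame=%.4f", est.frame_pair,
                  np.round(est.axis, 3), est.deg_per_frame)
        estimates.append(est)
    return estimates
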
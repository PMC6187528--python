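"""Cell localisation by template matching with SSDA acceleration.

The cell is found in each frame by correlating a small template against
candidate windows. Normalised cross-correlation (NCC) gives the match
score; the sequential similarity detection algorithm (SSDA) accelerates
the search by comparing windowed pixel pairs in a random order and
aborting a candidate as soon as its accumulated absolute error (with the
window and template means removed) exceeds a threshold — the true match
accumulates error slowly, so it survives the most comparisons. Tracking
over a sequence restricts the search to a window around the previous
position, and the sphere radius is estimated once from the template.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ImageSequence
from .sphere import SphereModel

__all__ = [
    "Template",
    "Trajectory",
    "DetectionError",
    "ncc_score",
    "ncc_match",
    "ssda_match",
    "track_cell",
    "estimate_radius",
]

#: half-width of the search window around the previous frame's position
SEARCH_RADIUS = 15


class DetectionError(RuntimeError):
    """Template matching failed to localise the object."""


@dataclass
class Template:
    """A square M x M reference patch of the object."""

    patch: np.ndarray

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=np.float64)
        if self.patch.ndim != 2 or self.patch.shape[0] != self.patch.shape[1]:
            raise ValueError(f"template must be square 2D, got {self.patch.shape}")
        if self.patch.shape[0] < 8:
            raise ValueError("template side must be at least 8 pixels")
        if np.ptp(self.patch) == 0:
            raise ValueError("template must be nonconstant")

    @property
    def side(self) -> int:
        return self.patch.shape[0]

    @property
    def mean_intensity(self) -> float:
        return float(self.patch.mean())


@dataclass
class Trajectory:
    """Per-frame sphere models plus the match score for each frame."""

    spheres: list[SphereModel]
    scores: list[float]

    def __post_init__(self) -> None:
        if len(self.spheres) != len(self.scores):
            raise ValueError("one score per frame required")
        if not all(np.isfinite(self.scores)):
            raise ValueError("match scores must be finite")

    def __len__(self) -> int:
        return len(self.spheres)

    def centers(self) -> np.ndarray:
        return np.array([[s.cx, s.cy] for s in self.spheres])


def ncc_score(window: np.ndarray, template: Template) -> float:
    """Normalised cross-correlation between a window and the template:
    sum(S*T) / sqrt(sum(S^2) * sum(T^2)).

    For nonnegative images the score lies in (0, 1], reaching 1 exactly
    when the window is proportional to the template (the normalisation
    makes the score invariant to positive scaling of either input).
    """
    s = np.asarray(window, dtype=np.float64)
    t = template.patch
    if s.shape != t.shape:
        raise ValueError(f"window shape {s.shape} != template shape {t.shape}")
    ss = float(np.sum(s * s))
    tt = float(np.sum(t * t))
    if ss == 0 or tt == 0:
        raise ValueError("all-zero window or template: NCC undefined")
    return float(np.sum(s * t)) / np.sqrt(ss * tt)


def ncc_match(frame: np.ndarray, template: Template) -> tuple[tuple[int, int], float]:
    """Exhaustive NCC argmax over all top-left positions (row, col).

    The slow-but-sure fallback and the oracle SSDA is checked against.
    """
    frame = np.asarray(frame, dtype=np.float64)
    m = template.side
    h, w = frame.shape
    if h < m or w < m:
        raise ValueError("frame smaller than template")
    best, best_score = (0, 0), -np.inf
    t = template.patch
    tt = np.sqrt(float(np.sum(t * t)))
    for i in range(h - m + 1):
        for j in range(w - m + 1):
            s = frame[i:i + m, j:j + m]
            ss = np.sqrt(float(np.sum(s * s)))
            if ss == 0:
                continue
            score = float(np.sum(s * t)) / (ss * tt)
            if score > best_score:
                best_score, best = score, (i, j)
    return best, best_score


def ssda_match(frame: np.ndarray, template: Template,
               threshold: float | None = None, rng_seed: int = 0,
               search_box: tuple[int, int, int, int] | None = None,
               ) -> tuple[tuple[int, int], float]:
    """SSDA template search.

    At each candidate top-left position (i, j) the mean-removed windowed
    pairs ``|(S(n,m) - Sbar) - (T(n,m) - Tbar)|`` are accumulated in a
    seeded random pixel order; accumulation aborts once it exceeds the
    threshold. The winner is the candidate surviving the most comparisons
    (ties: lowest final accumulated error, then smallest (i, j) row-major).

    ``threshold=None`` uses the adaptive bound 2 * k * MAD(template) after
    k comparisons, where MAD is the mean absolute deviation of the
    template about its mean. ``search_box`` restricts candidates to
    (i0, i1, j0, j1) half-open row/col ranges.

    Returns ``((i, j), accumulated_error)``.
    Raises :class:`DetectionError` if no candidate completes a single
    comparison.
    """
    frame = np.asarray(frame, dtype=np.float64)
    m = template.side
    h, w = frame.shape
    if h <= m or w <= m:
        raise ValueError("frame must be strictly larger than the template")
    t_centered = (template.patch - template.mean_intensity).ravel()
    n_px = t_centered.size

    if threshold is None:
        mad = float(np.mean(np.abs(t_centered)))
        bound = 2.0 * mad * np.arange(1, n_px + 1)
    else:
        bound = np.full(n_px, float(threshold))

    i0, i1, j0, j1 = (0, h - m + 1, 0, w - m + 1)
    if search_box is not None:
        bi0, bi1, bj0, bj1 = search_box
        i0, i1 = max(i0, bi0), min(i1, bi1)
        j0, j1 = max(j0, bj0), min(j1, bj1)
    if i0 >= i1 or j0 >= j1:
        raise ValueError("empty search box")

    rng = np.random.default_rng(rng_seed)
    best = None  # (n_compared, final_error, (i, j))
    for i in range(i0, i1):
        for j in range(j0, j1):
            s = frame[i:i + m, j:j + m]
            diffs = np.abs((s - s.mean()).ravel() - t_centered)
            perm = rng.permutation(n_px)
            acc = np.cumsum(diffs[perm])
            over = np.nonzero(acc > bound)[0]
            if over.size:
                n_compared = int(over[0])  # comparisons completed before abort
                err = float(acc[over[0]])
            else:
                n_compared = n_px
                err = float(acc[-1])
            key = (-n_compared, err, i, j)
            if best is None or key < best[0]:
                best = (key, (i, j), err, n_compared)
    assert best is not None
    if best[3] == 0:
        raise DetectionError(
            "no candidate completed any comparison; increase the threshold"
        )
    return best[1], best[2]


def _subpixel_peak(frame: np.ndarray, template: Template,
                   pos: tuple[int, int]) -> tuple[float, float, float]:
    """Parabolic refinement of the NCC peak over its 3x3 neighbourhood.

    Returns (i, j, score) with subpixel (i, j); positions at the search
    border fall back to the integer peak.
    """
    m = template.side
    h, w = frame.shape
    i, j = pos
    scores = np.full((3, 3), np.nan)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            ii, jj = i + di, j + dj
            if 0 <= ii <= h - m and 0 <= jj <= w - m:
                scores[di + 1, dj + 1] = ncc_score(
                    frame[ii:ii + m, jj:jj + m], template)
    c = scores[1, 1]
    if np.isnan(scores).any():
        return float(i), float(j), float(c)

    def _offset(lo: float, hi: float) -> float:
        den = lo - 2 * c + hi
        return 0.0 if den >= 0 else float(np.clip(0.5 * (lo - hi) / den, -0.5, 0.5))

    return i + _offset(scores[0, 1], scores[2, 1]), \
        j + _offset(scores[1, 0], scores[1, 2]), float(c)


def estimate_radius(template: Template, fallback: bool = True) -> float:
    """Sphere radius (pixels) from the template's intensity-gradient ring.

    The object boundary is the circle where the radial profile of the
    gradient magnitude about the template centre peaks; the peak is
    refined parabolically. If no ring stands out (peak less than twice
    the median annulus response), returns the fallback ``(M - 2) / 2``
    or raises ``ValueError`` when the fallback is disabled.
    """
    patch = template.patch
    m = template.side
    gy, gx = np.gradient(patch)
    gmag = np.hypot(gx, gy)
    c = (m - 1) / 2.0
    rows, cols = np.mgrid[0:m, 0:m]
    rho = np.hypot(rows - c, cols - c)
    r_max = int(np.floor(m / 2)) - 1
    radii = np.arange(2, r_max + 1)
    profile = np.array([
        gmag[(rho >= r - 0.5) & (rho < r + 0.5)].mean() for r in radii
    ])
    med = float(np.median(profile)) if profile.size else 0.0
    if profile.size == 0 or profile.max() <= max(2.0 * med, 1e-12):
        if fallback:
            return (m - 2) / 2.0
        raise ValueError("no detectable intensity-gradient ring in template")
    k = int(np.argmax(profile))
    r = float(radii[k])
    if 0 < k < profile.size - 1:
        lo, c0, hi = profile[k - 1], profile[k], profile[k + 1]
        den = lo - 2 * c0 + hi
        if den < 0:
            r += float(np.clip(0.5 * (lo - hi) / den, -0.5, 0.5))
    return r


def track_cell(sequence: ImageSequence, template: Template,
               threshold: float | None = None, rng_seed: int = 0,
               search_radius: int = SEARCH_RADIUS,
               radius: float | None = None) -> Trajectory:
    """Localise the object in every frame.

    Frame 0 is searched exhaustively; each later frame only within
    ``search_radius`` pixels of the previous position (cells translate
    slowly relative to their rotation). The sphere centre is the subpixel
    NCC peak plus the template half-side; the radius is estimated once
    from the template and held constant.
    """
    if len(sequence) < 1:
        raise ValueError("sequence must contain at least one frame")
    r = float(radius) if radius is not None else estimate_radius(template)
    m = template.side
    half = (m - 1) / 2.0
    spheres: list[SphereModel] = []
    scores: list[float] = []
    prev: tuple[int, int] | None = None
    for k, frame in enumerate(sequence.frames):
        box = None
        if prev is not None:
            box = (prev[0] - search_radius, prev[0] + search_radius + 1,
                   prev[1] - search_radius, prev[1] + search_radius + 1)
        try:
            pos, _ = ssda_match(frame, template, threshold=threshold,
                                rng_seed=rng_seed, search_box=box)
        except (DetectionError, ValueError) as exc:
            raise DetectionError(f"detection failed in frame {k}: {exc}") from exc
        i_sub, j_sub, score = _subpixel_peak(frame, template, pos)
        spheres.append(SphereModel(cx=j_sub + half, cy=i_sub + half, r=r))
        scores.append(score)
        prev = pos
    return Trajectory(spheres, scores)
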
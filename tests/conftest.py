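import numpy as np
import pytest
from scipy import ndimage

from cellspin.pipeline import analyze_sequence
from cellspin.synthetic import GlobeSpec, render_globe_sequence


@pytest.fixture(scope="session")
def globe20():
    """The standard validation sequence: 207 x 207 semi-transparent globe
    rotating 2 degrees/frame about an oblique axis for 20 frames."""
    spec = GlobeSpec(n_frames=20)
    seq, axis, deg = render_globe_sequence(spec)
    return spec, seq, axis, deg


@pytest.fixture(scope="session")
def globe20_estimates(globe20):
    spec, seq, _, _ = globe20
    return analyze_sequence(seq, sphere=spec.sphere)


def smooth_random_image(shape, seed, blur=2.0):
    """Band-limited random texture in [0, 1] (enough structure for flow)."""
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.random(shape), blur)
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo)
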
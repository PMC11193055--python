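import numpy as np
import pytest

from cytoscreen import generate_scene, render_channels


@pytest.fixture
def small_scene():
    """A clean, well-separated scene small enough for exact detection."""
    return generate_scene(60, dead_fraction=0.25, field_size=(360, 360),
                          min_separation_px=14, noise_sd=0.0, seed=42)


@pytest.fixture
def small_channels(small_scene):
    return render_channels(small_scene)


def gaussian_spot(shape, y0, x0, sd, peak, background=0.0):
    """Render a single isotropic Gaussian spot (test helper)."""
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    return background + peak * np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * sd ** 2))
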
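import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import acetograd as ag
from acetograd.segmentation import Polyline
from acetograd.simulate import _splat_polyline


@pytest.fixture(scope="session")
def mini_preset():
    """Scaled-down control-like preset for fast unit tests."""
    return ag.preset("control").replace(
        name="mini",
        cell_radius_um=8.0,
        nucleus_radius_um=2.5,
        n_filaments=16,
        image_size_px=288,
        # segment scale reduced with the cell so several segments fit per filament
        ac_segment_mean_um=1.2,
        ac_segment_sd_um=0.3,
    )


@pytest.fixture(scope="session")
def mini_cell(mini_preset):
    return ag.generate_cell(mini_preset, 7)


def render_line(points_um, shape=(160, 160), pixel_size_um=0.065,
                brightness=200.0, psf_sigma_px=2.0, bg=0.0):
    """Noiseless render of one polyline: splat + Gaussian blur."""
    canvas = np.zeros(shape)
    _splat_polyline(canvas, Polyline(np.asarray(points_um, float)), pixel_size_um, brightness)
    img = canvas + bg
    if psf_sigma_px > 0:
        img = gaussian_filter(img, psf_sigma_px)
    return img


@pytest.fixture(scope="session")
def straight_filament_image():
    """A single straight 8-µm horizontal filament, noiseless."""
    y = 80 * 0.065
    pts = [(1.0, y), (9.0, y)]
    return render_line(pts), pts
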
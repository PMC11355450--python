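import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sim2sr.lifting import GaborBank
from sim2sr.synthetic import CurveSpec, calibrate_sigma_offset, corrupt_with_disc, make_curve_image

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240731)


@pytest.fixture(scope="session")
def default_bank():
    """The default 16-orientation / 8-scale bank, sigma-calibrated."""
    bank = GaborBank.default()
    return calibrate_sigma_offset(bank, width_ref=1.0, pixel_size=0.25, shape=(120, 120))


@pytest.fixture(scope="session")
def completion_bank():
    """Finer bank used by the inpainting workflow (0.1 log-scale step)."""
    bank = GaborBank(
        theta_grid=np.arange(24) * math.pi / 24,
        sigma_grid=np.linspace(-0.6, 1.4, 21),
    )
    return calibrate_sigma_offset(bank, width_ref=2.0, pixel_size=0.125, shape=(96, 96))


@pytest.fixture(scope="session")
def bar_fixture():
    """Straight horizontal bar, width 2, on a 12x12-unit canvas."""
    spec = CurveSpec(waypoints=((-6.0, 0.0), (6.0, 0.0)), width_profile=(2.0, 2.0))
    img, truth = make_curve_image(spec, shape=(96, 96), pixel_size=0.125)
    return img, truth


@pytest.fixture(scope="session")
def corrupted_bar(bar_fixture):
    img, _ = bar_fixture
    corrupted, mask = corrupt_with_disc(img, (0.0, 0.0), 1.2)
    return img, corrupted, mask
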
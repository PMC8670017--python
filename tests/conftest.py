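import numpy as np
import pytest

import ctrecon as cr


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def disk_image():
    """Factory for a centered (or offset) disk image rendered by membership."""

    def _make(n=64, r=14.0, intensity=1.0, center=(0.0, 0.0), supersample=False):
        spec = cr.PhantomSpec(
            grid_size=n,
            pixel_size=1.0,
            ellipses=[cr.EllipseSpec(center, (r, r), 0.0, intensity)],
        )
        return cr.render_phantom(spec, supersample=supersample)

    return _make


@pytest.fixture
def shepp_logan_half():
    """128-grid Shepp-Logan phantom rescaled to [0, 1]."""
    img = cr.make_shepp_logan(128)
    img.pixels /= 2.0
    return img


@pytest.fixture(autouse=True)
def _quiet_truncation():
    """Default D = N geometries never span the full diagonal; that warning is
    expected throughout the suite, so keep it out of the reports."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", cr.TruncationWarning)
        yield
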
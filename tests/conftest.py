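import numpy as np
import pytest

from maflim.core import BANDS, InstrumentResponse, MaflimImage, PixelMask
from maflim.fitting import BiExpFit, _tau_avg
from maflim.simulate import make_irf


@pytest.fixture
def irf160():
    """Gaussian IRF (FWHM 1 ns, peak 5 ns) on a 160-sample, 0.25 ns grid."""
    return make_irf(dt=0.25, fwhm_ns=1.0, n_time=160, peak_ns=5.0)


@pytest.fixture
def small_image():
    """Deterministic 4x4x64 image with positive decays in all bands."""
    rng = np.random.default_rng(42)
    t = np.arange(64) * 0.25
    decay = {}
    for i, b in enumerate(BANDS):
        base = (1.0 + 0.2 * i) * np.exp(-t / (2.0 + i))
        decay[b] = base[None, None, :] * (1 + 0.1 * rng.random((4, 4, 1)))
    return MaflimImage(decay=decay, dt=0.25, meta={"label": "unknown"}, full_scale=4.0)


@pytest.fixture
def small_irf():
    """IRF matching the small_image grid (64 samples, dt 0.25)."""
    return make_irf(dt=0.25, fwhm_ns=1.0, n_time=64, peak_ns=3.0)


def biexp(af, tf, ts):
    """Construct a valid BiExpFit from (alpha_fast, tau_fast, tau_slow)."""
    return BiExpFit(
        alpha_fast=af, tau_fast=tf, alpha_slow=1 - af, tau_slow=ts,
        tau_avg=_tau_avg(af, tf, 1 - af, ts), mse=0.0,
    )
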
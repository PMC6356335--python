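import numpy as np
import pytest

from scaffoldscope import profiles, synthgen
from scaffoldscope.mhat_cwt import cwt


@pytest.fixture(scope="session")
def three_tone_profile():
    """Detrended section-like profile with banding at 10, 80 and 420 µm."""
    prof, truth = synthgen.make_stripe_profile(synthgen.histology_stripe_spec(), seed=1)
    return profiles.detrend(prof, "linear"), truth


@pytest.fixture(scope="session")
def three_tone_waveletgram(three_tone_profile):
    prof, _ = three_tone_profile
    return cwt(prof)


@pytest.fixture(scope="session")
def pore_image():
    image, truth = synthgen.make_pore_image(synthgen.scaffold_pore_spec(), seed=3)
    return image, truth


def pure_tone(period_um: float, length_um: float | None = None,
              sampling_um: float | None = None, phase: float = 0.0,
              noise_sigma: float = 0.0, seed: int = 0):
    """Single-sinusoid profile sized sensibly for its period."""
    length = length_um if length_um is not None else max(10 * period_um, 400.0)
    dx = sampling_um if sampling_um is not None else min(period_um / 20.0, 2.0)
    spec = synthgen.StripeSpec(
        length, dx, ((period_um, 1.0, phase),), noise_sigma=noise_sigma
    )
    prof, _ = synthgen.make_stripe_profile(spec, seed)
    return prof


def random_profile(n: int, seed: int, sampling_um: float = 1.0):
    rng = np.random.default_rng(seed)
    pos = np.arange(n) * sampling_um
    return profiles.IntensityProfile(pos, rng.normal(size=n), sampling_um)
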
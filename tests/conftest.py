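import numpy as np
import pytest

import luxfit as lf


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def preset_a():
    return lf.STRAIN_PRESETS["A"]


@pytest.fixture
def noiseless_plate_a(preset_a):
    """One noiseless plate simulated from the LuxR^A preset."""
    return lf.simulate_plate(preset_a.params, preset_a.scale, noise=lf.NoiseModel(cv=0.0))


def random_params(rng, n, m_range=(0.05, 4.0)):
    """Kinetic parameter draws spanning the default search box."""
    lo, hi = lf.DEFAULT_BOUNDS.as_arrays()
    lo, hi = lo.copy(), hi.copy()
    lo[[1, 3]], hi[[1, 3]] = m_range[0], m_range[1]
    return [lf.KineticParams.from_array(rng.uniform(lo, hi)) for _ in range(n)]
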
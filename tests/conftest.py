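import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    from aifdetect import SamplingGrid

    return SamplingGrid()


@pytest.fixture(scope="session")
def small_phantom():
    """A reduced phantom (all six classes, quarter-size tissue pools)."""
    from aifdetect import PhantomSpec, build_phantom

    spec = PhantomSpec(
        composition=dict(arterial=6, false_arterial=16, gm=60, gm_path=60,
                         wm=80, pve=60),
        noise_subset=55, seed=123)
    return build_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Separable phantom: no noise, no false arterials, no PVE mixtures."""
    from aifdetect import PhantomSpec, build_phantom

    spec = PhantomSpec(
        composition=dict(arterial=6, false_arterial=0, gm=20, gm_path=20,
                         wm=20, pve=0),
        snr=None, seed=7)
    return build_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
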
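import numpy as np
import pytest
from hypothesis import settings

import crpkin as ck

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def worked_fixture():
    """The deterministic eight-patient infection cohort."""
    return ck.generate_worked_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient synthetic cohort with elevated prevalence for tests."""
    spec = ck.SyntheticCohortSpec(n_patients=60, infection_prevalence=0.2)
    return ck.generate_cohort(spec, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def model_points(xs, span=0.7235, k=0.2883, plateau=0.2683, noise_sd=0.0, rng=None):
    """Aligned points generated straight from the decay model."""
    xs = np.asarray(xs, dtype=float)
    ys = span * np.exp(-k * xs) + plateau
    if noise_sd > 0:
        ys = np.clip(ys + rng.normal(0.0, noise_sd, size=ys.shape), 0.0, None)
    return [ck.AlignedPoint(float(x), float(y)) for x, y in zip(xs, ys)]
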
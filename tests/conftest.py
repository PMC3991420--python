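import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import synthmap as sm

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def as_table() -> sm.TrialTable:
    return sm.load_as_trials()


@pytest.fixture(scope="session")
def easiqol() -> sm.CorrelationMatrix:
    return sm.load_easiqol_correlations()


@pytest.fixture(scope="session")
def signs(easiqol) -> dict:
    return sm.derive_signs(easiqol, "PAIN-VAS")


@pytest.fixture(scope="session")
def blocks(as_table, easiqol):
    return sm.assemble_blocks(as_table, easiqol)


#: reduced-but-honest settings for unit tests on the bundled dataset
FAST = sm.McmcSettings(chains=2, walkers=96, steps=2500, thin=16)


@pytest.fixture(scope="session")
def random_fit(blocks, signs) -> sm.PosteriorResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.fit_random_mapping(
            blocks, signs, settings=FAST, reference="PAIN-VAS", seed=11
        )


@pytest.fixture(scope="session")
def fixed_fit(blocks, signs) -> sm.PosteriorResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.fit_fixed_mapping(
            blocks,
            signs,
            settings=sm.McmcSettings(chains=2, walkers=64, steps=2500, thin=16),
            reference="PAIN-VAS",
            seed=12,
        )


@pytest.fixture(scope="session")
def small_study() -> sm.SyntheticStudy:
    return sm.make_study(sm.small_scenario(n_trials=6), seed=42)


def fit_quietly(fit_fn, *args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_fn(*args, **kwargs)
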
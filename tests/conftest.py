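import numpy as np
import pytest

import rdgee


@pytest.fixture(scope="session")
def beitler() -> "rdgee.TrialData":
    """The eight-center infection trial, expanded to subject level."""
    return rdgee.load_beitler_landis()


@pytest.fixture(scope="session")
def beitler_counts() -> "rdgee.CenterCountTable":
    return rdgee.load_beitler_landis_counts()


@pytest.fixture(scope="session")
def covariate_trial() -> "rdgee.TrialData":
    """A simulated trial with a baseline covariate, for covariate-model fits."""
    spec = rdgee.ScenarioSpec(
        true_link="identity", pi_c=0.25, true_rd=0.10, icc=0.05,
        n_per_center=50, covariate_effect="fifty_percent", seed=42,
    )
    return rdgee.simulate_trial(spec, np.random.default_rng(42))
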
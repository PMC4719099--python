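import warnings

import pytest
from hypothesis import settings

import pwibayes as pw

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_trials():
    """One paper-like synthetic experiment (13 controls, 6 patients)."""
    trials, truth = pw.simulate_dataset(pw.paper_like_config(seed=11))
    return trials, truth


@pytest.fixture(scope="session")
def paper_medians(paper_trials):
    trials, _ = paper_trials
    retained, _ = pw.exclude_trials(trials)
    return pw.condition_medians(retained)


@pytest.fixture(scope="session")
def small_mcmc():
    """Reduced draw counts for test-time fits (tolerances widened to match)."""
    return pw.McmcConfig(n_samples=6000, thin=1, burn_in=500, n_chains=2, seed=17)


@pytest.fixture(scope="session")
def paper_posterior(paper_medians, small_mcmc):
    return pw.fit_model(paper_medians, mcmc=small_mcmc)
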
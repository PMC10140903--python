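import numpy as np
import pytest

from switchddm import ddm_fit, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """Eight synthetic subjects with full ground truth (shared across
    the estimation tests to amortize simulation cost)."""
    spec = synthetic.PopulationSpec(n_subjects=8, rng_seed=5)
    latents, cell_params, trunc = synthetic.sample_population(spec)
    trial_list = synthetic.make_trial_list(11)
    trials = synthetic.simulate_switch_task(cell_params, trial_list, seed=7)
    return dict(spec=spec, latents=latents, cell_params=cell_params,
                trial_list=trial_list, trials=trials, truncation=trunc)


@pytest.fixture(scope="session")
def fitted_m2(small_cohort):
    """A well-mixed two-chain M2 fit of the small cohort."""
    mcmc = ddm_fit.McmcSettings(chains=2, draws=500, burn=500, thin=5, seed=1)
    return ddm_fit.fit_hierarchical(small_cohort["trials"], "M2", mcmc)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
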
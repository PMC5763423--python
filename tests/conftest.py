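import numpy as np
import pytest

from ivcea import ScenarioConfig, simulate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(20250914)


@pytest.fixture
def base_config():
    return ScenarioConfig(n=100, p_noncomp=0.3, cost_dist="normal", rho=0.4, seed=1)


@pytest.fixture
def trial_small(base_config):
    """One n=100 trial from the base scenario."""
    return simulate_trial(base_config)


@pytest.fixture
def trial_large():
    """n=20000 normal-cost trial for asymptotic checks."""
    return simulate_trial(ScenarioConfig(n=20000, seed=11))


@pytest.fixture
def full_compliance_trial():
    """A trial where everyone follows allocation (d == z)."""
    cfg = ScenarioConfig(n=800, p_noncomp=0.3, seed=21)
    trial = simulate_trial(cfg)
    trial.s = np.zeros(trial.n)
    trial.d = trial.z.copy()
    # re-draw outcomes consistent with d == z so the DGP stays coherent
    from ivcea.simulate import draw_outcomes, outcome_means

    mu1, mu2 = outcome_means(trial.d, trial.u, cfg.mu_coefs)
    trial.y1, trial.y2 = draw_outcomes(mu1, mu2, cfg, np.random.default_rng(22))
    return trial
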
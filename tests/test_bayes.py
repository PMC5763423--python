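"""Bayesian model checks: convergence machinery, transform identities,
model-collapse against least squares, prior sensitivity, input guards."""

import numpy as np
import pytest

from ivcea import (
    BayesGammaNormalIV,
    BayesNormalIV,
    FullLikelihoodIV,
    McmcProtocol,
    ScenarioConfig,
    SURSystem,
    geweke_z,
    run_convergence_loop,
    simulate_trial,
)


def short_protocol(seed=0, **over):
    kwargs = dict(
        n_chains=2, init_iters=400, burn_in=150, extension_block=150,
        final_block=600, target_kept=1200, max_extensions=3, seed=seed,
    )
    kwargs.update(over)
    return McmcProtocol(**kwargs)


class TestProtocol:
    def test_defaults_are_consistent(self):
        p = McmcProtocol()
        assert p.n_chains * p.final_block == p.target_kept

    @pytest.mark.parametrize(
        "bad",
        [
            {"burn_in": 5000},                      # >= init_iters
            {"target_kept": 9999},                  # inconsistent with chains
            {"geweke_first": 0.6, "geweke_last": 0.6},  # overlapping windows
            {"init_iters": 0},
        ],
    )
    def test_validation(self, bad):
        with pytest.raises(ValueError):
            McmcProtocol(**bad)


class TestGeweke:
    def test_stationary_chain_passes(self, rng):
        """|z| < 2.5 for nearly all i.i.d. chains (null is ~N(0,1))."""
        zs = [geweke_z(rng.standard_normal(2000)) for _ in range(60)]
        assert np.mean(np.abs(zs) < 2.5) >= 0.9
        # and the scores themselves look standard normal, not degenerate
        assert 0.5 < np.std(zs) < 2.0

    def test_trending_chain_fails(self, rng):
        chain = np.linspace(0.0, 3.0, 2000) + 0.5 * rng.standard_normal(2000)
        assert abs(geweke_z(chain)) > 2.5

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke_z(np.arange(10.0))


class _TrendingSampler:
    """Deterministic pseudo-sampler that never stops trending."""

    geweke_params = ("a",)

    def __init__(self):
        self.t = 0

    def run(self, n, adapt=False):
        out = 0.01 * (self.t + np.arange(n))
        self.t += n
        return {"a": out}


class _WhiteNoiseSampler:
    geweke_params = ("a",)

    def __init__(self, seed):
        self.rng = np.random.default_rng(seed)

    def run(self, n, adapt=False):
        return {"a": self.rng.standard_normal(n)}


class TestConvergenceLoop:
    def test_failure_is_flagged_after_cap(self):
        proto = short_protocol()
        with pytest.warns(UserWarning, match="Geweke"):
            kept, diag = run_convergence_loop(
                [_TrendingSampler(), _TrendingSampler()], proto
            )
        assert diag["converged"] is False
        assert all(c["extensions"] == proto.max_extensions for c in diag["chains"])
        assert len(kept["a"]) == proto.target_kept

    def test_stationary_chain_needs_no_extension(self):
        proto = short_protocol()
        kept, diag = run_convergence_loop(
            [_WhiteNoiseSampler(1), _WhiteNoiseSampler(2)], proto
        )
        assert diag["converged"] is True
        assert len(kept["a"]) == proto.target_kept


@pytest.fixture(scope="module")
def fc_trial():
    cfg = ScenarioConfig(n=800, p_noncomp=0.3, seed=21)
    trial = simulate_trial(cfg)
    trial.s = np.zeros(trial.n)
    trial.d = trial.z.copy()
    from ivcea.simulate import draw_outcomes, outcome_means

    mu1, mu2 = outcome_means(trial.d, trial.u, cfg.mu_coefs)
    trial.y1, trial.y2 = draw_outcomes(mu1, mu2, cfg, np.random.default_rng(22))
    return trial


class TestModelCollapse:
    """With full compliance the IV structure is inert: every Bayesian model
    should agree with the SUR/OLS effects within posterior uncertainty."""

    @pytest.mark.parametrize("model_cls", [BayesNormalIV, FullLikelihoodIV])
    def test_normal_models(self, model_cls, fc_trial):
        post = model_cls(fc_trial).fit(short_protocol(seed=5))
        ols = SURSystem(fc_trial).fit()
        for name, target in (("beta_cost", ols.beta_cost), ("beta_qaly", ols.beta_qaly)):
            assert abs(post.median(name) - target) < 2 * post.sd(name)

    def test_gamma_model(self):
        cfg = ScenarioConfig(n=600, cost_dist="gamma", seed=33)
        trial = simulate_trial(cfg)
        trial.s = np.zeros(trial.n)
        trial.d = trial.z.copy()
        from ivcea.simulate import draw_outcomes, outcome_means

        mu1, mu2 = outcome_means(trial.d, trial.u, cfg.mu_coefs)
        trial.y1, trial.y2 = draw_outcomes(mu1, mu2, cfg, np.random.default_rng(34))
        post = BayesGammaNormalIV(trial).fit(short_protocol(seed=7))
        ols = SURSystem(trial).fit()
        for name, target in (("beta_cost", ols.beta_cost), ("beta_qaly", ols.beta_qaly)):
            assert abs(post.median(name) - target) < 3 * post.sd(name)


class TestPosterior:
    def test_kept_count_and_summaries(self, fc_trial):
        proto = short_protocol(seed=9)
        post = BayesNormalIV(fc_trial).fit(proto)
        assert post.n_kept == proto.target_kept
        lo, hi = post.interval("beta_cost")
        assert lo < post.median("beta_cost") < hi
        assert "beta_cost" in post.summary()

    def test_fisher_z_transform_identity(self, fc_trial):
        post = BayesNormalIV(fc_trial).fit(short_protocol(seed=13))
        np.testing.assert_allclose(
            post.draws["rho"], np.tanh(post.draws["z_rho"]), atol=1e-12
        )

    def test_inb_icer_are_drawwise(self, fc_trial):
        post = BayesNormalIV(fc_trial).fit(short_protocol(seed=15))
        bc = 1000.0 * post.draws["beta_cost"]
        bq = 0.1 * post.draws["beta_qaly"]
        np.testing.assert_allclose(post.draws["inb"], 30000.0 * bq - bc)
        np.testing.assert_allclose(post.draws["icer"], bc / bq)


class TestPriorSensitivity:
    def test_wishart_df_variant_changes_little(self):
        trial = simulate_trial(ScenarioConfig(n=600, seed=44))
        a = FullLikelihoodIV(trial, wishart_df=4).fit(short_protocol(seed=1))
        b = FullLikelihoodIV(trial, wishart_df=6).fit(short_protocol(seed=2))
        for name in ("beta_cost", "beta_qaly"):
            assert abs(a.median(name) - b.median(name)) < a.sd(name)


class TestCovariateAdjustment:
    @pytest.mark.parametrize(
        "model_cls", [BayesNormalIV, BayesGammaNormalIV, FullLikelihoodIV]
    )
    def test_adjusted_fit_agrees_with_system_ls(self, model_cls):
        """Baseline-covariate adjustment runs through every sampler and
        lands near the covariate-adjusted 3SLS estimate."""
        import pandas as pd

        from ivcea import ThreeStageLS

        cfg = ScenarioConfig(n=500, cost_dist="gamma", seed=8)
        trial = simulate_trial(cfg)
        rng = np.random.default_rng(2)
        trial.x = pd.DataFrame(
            {"eq5d0": 0.5 * trial.u + rng.normal(0, 0.1, trial.n)}
        )
        post = model_cls(trial, covariates=["eq5d0"]).fit(short_protocol(seed=4))
        ls = ThreeStageLS(trial, covariates=["eq5d0"]).fit()
        for name, target in (("beta_cost", ls.beta_cost), ("beta_qaly", ls.beta_qaly)):
            assert abs(post.median(name) - target) < 4 * post.sd(name)


class TestInputGuards:
    def test_gamma_model_rejects_nonpositive_costs(self, trial_small):
        trial_small.y1[3] = 0.0
        with pytest.raises(ValueError, match="strictly positive"):
            BayesGammaNormalIV(trial_small).fit(short_protocol())

    def test_missing_outcomes_are_imputed(self):
        trial = simulate_trial(ScenarioConfig(n=600, seed=55))
        trial.y1[:30] = np.nan
        trial.y2[20:60] = np.nan
        post = BayesNormalIV(trial).fit(short_protocol(seed=3))
        assert np.isfinite(post.median("beta_cost"))
        assert abs(post.median("beta_cost") - 0.4) < 6 * post.sd("beta_cost")

    def test_missing_allocation_rejected(self, trial_small):
        trial_small.z[0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            BayesNormalIV(trial_small).fit(short_protocol())
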
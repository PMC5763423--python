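"""Net-benefit arithmetic, variance propagation and Rubin's-rules pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivcea import SystemResults, icer_from_system, inb_from_system, rubin_pool


def _est(effects, cov, method="threesls"):
    return SystemResults(
        method=method, effects=np.asarray(effects, float),
        cov_effects=np.asarray(cov, float), n_used=100,
    )


class TestINB:
    def test_published_cace_increments(self):
        """INB is the exact linear combination of the increments: for the
        surgery-vs-medicine CACE increments £1899 and 0.516 QALYs at
        lambda = £30,000 the identity gives 30000*0.516 - 1899 = 13581,
        matching the published 13587 up to rounding of the inputs."""
        est = _est([1899.0, 0.516], [[1.0, 0.0], [0.0, 1e-6]])
        cea = inb_from_system(est, 30000.0, cost_scale=1.0, qaly_scale=1.0)
        assert cea.inb == pytest.approx(30000 * 0.516 - 1899)
        # half-unit input rounding moves INB by up to ~15.5 + 0.5
        assert cea.inb == pytest.approx(13587, abs=17)

    def test_lambda_zero_reduction(self):
        est = _est([3.0, 1.0], [[0.25, 0.0], [0.0, 0.04]])
        cea = inb_from_system(est, 0.0, cost_scale=1.0, qaly_scale=1.0)
        assert cea.inb == pytest.approx(-3.0)
        assert cea.inb_se == pytest.approx(0.5)

    def test_variance_matches_monte_carlo(self, rng):
        """SE formula against brute-force propagation of 10^6 normal draws."""
        cov = np.array([[0.30, -0.08], [-0.08, 0.05]])
        est = _est([1.5, 0.4], cov)
        lam = 30000.0
        cea = inb_from_system(est, lam)
        draws = rng.multivariate_normal([1.5, 0.4], cov, size=1_000_000)
        inb_draws = lam * 0.1 * draws[:, 1] - 1000.0 * draws[:, 0]
        assert cea.inb_se == pytest.approx(inb_draws.std(), rel=0.01)
        assert cea.inb == pytest.approx(inb_draws.mean(), abs=3 * cea.inb_se / 1000)

    def test_tsls_requires_explicit_independence(self):
        est = _est([1.0, 0.5], [[0.1, 0.02], [0.02, 0.05]], method="tsls")
        with pytest.raises(ValueError, match="independence"):
            inb_from_system(est, 30000.0)
        cea = inb_from_system(est, 30000.0, independence=True)
        indep = np.sqrt((30000 * 0.1) ** 2 * 0.05 + 1000.0**2 * 0.1)
        assert cea.inb_se == pytest.approx(indep)

    def test_diagonal_covariance_equals_independence(self):
        cov = [[0.1, 0.0], [0.0, 0.05]]
        a = inb_from_system(_est([1.0, 0.5], cov), 30000.0)
        b = inb_from_system(_est([1.0, 0.5], cov), 30000.0, independence=True)
        assert a.inb_se == pytest.approx(b.inb_se)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        c=st.floats(-5, 5), q=st.floats(-5, 5), lam=st.floats(0, 1e5),
    )
    def test_sign_flip_identity(self, c, q, lam):
        """Negating costs with lambda = 0 negates INB exactly."""
        cov = [[0.1, 0.0], [0.0, 0.1]]
        plus = inb_from_system(_est([c, q], cov), 0.0)
        minus = inb_from_system(_est([-c, q], cov), 0.0)
        assert plus.inb == pytest.approx(-minus.inb, abs=1e-9)


class TestICER:
    def test_itt_increments_ratio(self):
        est = _est([1103.0, 0.295], np.eye(2))
        assert icer_from_system(est, 1.0, 1.0) == pytest.approx(1103 / 0.295)
        assert icer_from_system(est, 1.0, 1.0) == pytest.approx(3739, abs=1)

    def test_constructed_ratio(self):
        est = _est([4.2, 4.2 / 7.0], np.eye(2))
        assert icer_from_system(est, 1.0, 1.0) == pytest.approx(7.0)

    def test_zero_qaly_undefined(self):
        with pytest.raises(ZeroDivisionError):
            icer_from_system(_est([1.0, 0.0], np.eye(2)), 1.0, 1.0)

    def test_opposite_sign_warning(self):
        with pytest.warns(UserWarning, match="opposite signs"):
            icer_from_system(_est([1.0, -0.5], np.eye(2)), 1.0, 1.0)


class TestRubinPooling:
    def test_degenerate_identical_estimates(self):
        est = _est([1.0, 0.5], [[0.1, 0.01], [0.01, 0.05]])
        pooled = rubin_pool([est, est, est])
        np.testing.assert_allclose(pooled.effects, est.effects)
        np.testing.assert_allclose(pooled.cov_effects, est.cov_effects)

    def test_two_imputation_hand_calculation(self):
        w = np.array([[0.2, 0.0], [0.0, 0.1]])
        e1, e2 = _est([1.0, 0.4], w), _est([2.0, 0.6], w)
        pooled = rubin_pool([e1, e2])
        np.testing.assert_allclose(pooled.effects, [1.5, 0.5])
        # deviations (+-0.5, +-0.1): B = [[0.5, 0.1], [0.1, 0.02]]; T = W + (3/2) B
        np.testing.assert_allclose(
            pooled.cov_effects,
            [[0.2 + 1.5 * 0.5, 1.5 * 0.1], [1.5 * 0.1, 0.1 + 1.5 * 0.02]],
        )

    def test_order_invariance(self):
        ests = [
            _est([1.0, 0.4], [[0.2, 0.01], [0.01, 0.1]]),
            _est([2.0, 0.6], [[0.3, 0.02], [0.02, 0.2]]),
            _est([1.5, 0.9], [[0.25, 0.03], [0.03, 0.15]]),
        ]
        a = rubin_pool(ests)
        b = rubin_pool(ests[::-1])
        np.testing.assert_allclose(a.effects, b.effects)
        np.testing.assert_allclose(a.cov_effects, b.cov_effects)

    def test_pooled_inb_equals_inb_of_pooled(self):
        """Rubin's rules commute with the fixed-lambda linear map, provided
        the matrix form keeps the cross-covariance."""
        lam = 30000.0
        ests = [
            _est([1.0, 0.4], [[0.2, 0.01], [0.01, 0.1]]),
            _est([2.0, 0.6], [[0.3, 0.02], [0.02, 0.2]]),
        ]
        pooled = rubin_pool(ests)
        via_matrix = inb_from_system(pooled, lam)
        inbs = [inb_from_system(e, lam) for e in ests]
        m = 2
        qbar = np.mean([c.inb for c in inbs])
        wbar = np.mean([c.inb_se**2 for c in inbs])
        B = np.var([c.inb for c in inbs], ddof=1)
        assert via_matrix.inb == pytest.approx(qbar)
        assert via_matrix.inb_se**2 == pytest.approx(wbar + (1 + 1 / m) * B)

    def test_rejects_mixed_methods(self):
        a = _est([1.0, 0.4], np.eye(2), method="tsls")
        b = _est([1.0, 0.4], np.eye(2), method="threesls")
        with pytest.raises(ValueError, match="methods"):
            rubin_pool([a, b])

    def test_requires_two(self):
        with pytest.raises(ValueError):
            rubin_pool([_est([1.0, 0.4], np.eye(2))])
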
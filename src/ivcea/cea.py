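"""Cost-effectiveness summaries and multiple-imputation pooling.

The incremental net benefit at willingness to pay ``lam`` is
``INB(lam) = lam * dQALY - dCost`` on the natural (£, QALY) scale; its
variance follows the linear-combination rule, which is where the
cross-outcome covariance of the effect estimates enters.  The incremental
cost-effectiveness ratio is ``dCost / dQALY`` and is reported without an
interval.  Rubin's rules pool system estimates across multiply imputed
datasets in matrix form, so pooled net-benefit inference keeps the
cost–QALY cross-covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data import COST_SCALE, QALY_SCALE
from .least_squares import SystemResults

__all__ = ["CEAResult", "inb_from_system", "icer_from_system", "rubin_pool"]


@dataclass(frozen=True)
class CEAResult:
    """Net-benefit summary on the natural (£, QALY) scale."""

    lambda_wtp: float
    inb: float
    inb_se: float
    inb_ci: tuple[float, float]
    icer: float | None
    scale_note: str = "natural scale (£, QALY)"

    def summary(self) -> str:
        lo, hi = self.inb_ci
        lines = [
            f"INB(lambda={self.lambda_wtp:g}) = {self.inb:.1f} "
            f"(se {self.inb_se:.1f}, 95% CI {lo:.1f} to {hi:.1f})",
        ]
        if self.icer is not None:
            lines.append(f"ICER = {self.icer:.0f} per QALY")
        lines.append(self.scale_note)
        return "\n".join(lines)


def inb_from_system(
    est: SystemResults,
    lam: float,
    cost_scale: float = COST_SCALE,
    qaly_scale: float = QALY_SCALE,
    independence: bool = False,
    ci_level: float = 0.95,
) -> CEAResult:
    """Incremental net benefit with covariance-propagated uncertainty.

    ``cost_scale`` and ``qaly_scale`` map the estimate's analysis scale back
    to £ and QALYs (the simulator works in £1000s and 0.1-QALY units; pass 1
    for estimates already on the natural scale).  ``independence=True``
    zeroes the cost–QALY covariance term — the univariate-2SLS comparator.
    Var(INB) = lam^2 Var(dQ) + Var(dC) - 2 lam Cov(dC, dQ) after scaling.
    """
    theta = np.array([cost_scale * est.beta_cost, qaly_scale * est.beta_qaly])
    scale = np.diag([cost_scale, qaly_scale])
    cov = scale @ est.cov_effects @ scale
    if independence:
        cov = np.diag(np.diag(cov))
    elif est.method == "tsls" and not np.allclose(est.cov_effects[0, 1], 0.0):
        raise ValueError(
            "2SLS estimates carry no cross-outcome covariance; pass "
            "independence=True to build the independence interval explicitly"
        )
    w = np.array([-1.0, lam])
    inb = float(w @ theta)
    var = float(w @ cov @ w)
    if var < 0:
        raise ValueError("effect covariance is not positive semidefinite")
    se = np.sqrt(var)
    zq = stats.norm.ppf(0.5 + ci_level / 2.0)
    icer = None
    if theta[1] != 0.0:
        icer = icer_from_system(est, cost_scale, qaly_scale)
    return CEAResult(
        lambda_wtp=lam,
        inb=inb,
        inb_se=float(se),
        inb_ci=(inb - zq * se, inb + zq * se),
        icer=icer,
    )


def icer_from_system(
    est: SystemResults,
    cost_scale: float = COST_SCALE,
    qaly_scale: float = QALY_SCALE,
) -> float:
    """Incremental cost-effectiveness ratio (£ per QALY), no interval."""
    dc = cost_scale * est.beta_cost
    dq = qaly_scale * est.beta_qaly
    if dq == 0.0:
        raise ZeroDivisionError("ICER undefined: incremental QALYs are zero")
    if dc * dq < 0:
        warnings.warn(
            "incremental cost and QALYs have opposite signs; the ICER sign "
            "does not identify the dominating quadrant",
            stacklevel=2,
        )
    return float(dc / dq)


def rubin_pool(estimates: Sequence[SystemResults]) -> SystemResults:
    """Pool system estimates across m imputed datasets by Rubin's rules.

    Pooled point = mean of points; total covariance T = Wbar + (1 + 1/m) B
    with Wbar the mean within-imputation covariance and B the
    between-imputation covariance (matrix form).  Per-parameter small-sample
    degrees of freedom are stored under ``nuisance['rubin']``.
    """
    m = len(estimates)
    if m < 2:
        raise ValueError("Rubin pooling needs at least two imputations")
    methods = {e.method for e in estimates}
    if len(methods) != 1:
        raise ValueError(f"cannot pool across methods: {sorted(methods)}")
    points = np.stack([e.effects for e in estimates])
    wbar = np.mean([e.cov_effects for e in estimates], axis=0)
    qbar = points.mean(axis=0)
    dev = points - qbar
    B = dev.T @ dev / (m - 1)
    T = wbar + (1.0 + 1.0 / m) * B
    with np.errstate(divide="ignore"):
        rel = (1.0 + 1.0 / m) * np.diag(B) / np.diag(wbar)
        df = (m - 1) * (1.0 + 1.0 / rel) ** 2
    resid = [e.resid_cov for e in estimates if e.resid_cov is not None]
    return SystemResults(
        method=estimates[0].method,
        effects=qbar,
        cov_effects=T,
        resid_cov=np.mean(resid, axis=0) if resid else None,
        nuisance={
            "rubin": {
                "m": m,
                "df_cost": float(df[0]),
                "df_qaly": float(df[1]),
                "between_cov": B.tolist(),
                "within_cov": wbar.tolist(),
            }
        },
        ci_level=estimates[0].ci_level,
        n_used=estimates[0].n_used,
    )
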
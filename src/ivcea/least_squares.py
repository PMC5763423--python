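"""Least-squares estimators for the bivariate cost-effectiveness system.

Four fitting strategies share one results container:

* :class:`SURSystem` — intention-to-treat SUR of (cost, QALY) on allocation,
  estimated by two-step feasible GLS.
* :class:`TwoStageLS` — per-outcome two-stage least squares with random
  allocation instrumenting treatment received.  The cross-outcome covariance
  of the effects is deliberately set to zero: this is the "univariate IV"
  comparator whose net-benefit intervals ignore the cost–QALY correlation.
* :class:`ThreeStageLS` — the same first two stages, then a third FGLS stage
  across the two outcome equations using the estimated residual covariance;
  its 2x2 effect covariance feeds covariance-aware net-benefit inference.
* :class:`NaiveSystem` — per-protocol (drop switchers) and as-treated
  (regress on treatment received, ignoring allocation) comparators, which are
  confounded by design.

Point estimates from 2SLS and 3SLS coincide in this just-identified,
identical-instrument setting; they differ only in the effect covariance.
Residual covariances use divisor n, FGLS is two-step (not iterated), and
confidence intervals are normal-theory Wald intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .data import TrialData

__all__ = [
    "WeakInstrumentError",
    "SystemResults",
    "wald_estimate",
    "tsls_fit",
    "TwoStageLS",
    "ThreeStageLS",
    "SURSystem",
    "NaiveSystem",
]

_OUTCOMES = ("cost", "qaly")


class WeakInstrumentError(ValueError):
    """Raised when allocation does not shift treatment received."""


@dataclass
class SystemResults:
    """Joint point estimates and covariances from a frequentist system fit.

    ``effects`` holds the treatment-effect coefficients (cost, QALY) on the
    rescaled analysis scale; ``cov_effects`` their model-based 2x2 covariance;
    ``resid_cov`` the estimated residual covariance of the two outcome
    equations (where applicable).
    """

    method: str
    effects: np.ndarray
    cov_effects: np.ndarray
    resid_cov: np.ndarray | None = None
    nuisance: dict = field(default_factory=dict)
    ci_level: float = 0.95
    n_used: int = 0

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        self.cov_effects = np.asarray(self.cov_effects, dtype=float)
        if self.effects.shape != (2,) or self.cov_effects.shape != (2, 2):
            raise ValueError("effects must be length 2 with a 2x2 covariance")
        if self.resid_cov is not None:
            self.resid_cov = np.asarray(self.resid_cov, dtype=float)

    # ------------------------------------------------------------- accessors
    @property
    def beta_cost(self) -> float:
        return float(self.effects[0])

    @property
    def beta_qaly(self) -> float:
        return float(self.effects[1])

    @property
    def se_cost(self) -> float:
        return float(np.sqrt(self.cov_effects[0, 0]))

    @property
    def se_qaly(self) -> float:
        return float(np.sqrt(self.cov_effects[1, 1]))

    def conf_int(self, level: float | None = None) -> np.ndarray:
        """Normal-theory Wald intervals for (cost, QALY), rows = outcomes."""
        level = self.ci_level if level is None else level
        zq = stats.norm.ppf(0.5 + level / 2.0)
        se = np.sqrt(np.diag(self.cov_effects))
        return np.column_stack([self.effects - zq * se, self.effects + zq * se])

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"System estimate ({self.method}), n used = {self.n_used}",
            f"{'outcome':<10}{'effect':>10}{'se':>10}"
            f"{'[' + format(self.ci_level, '.0%'):>10}{'CI]':>10}",
        ]
        for i, name in enumerate(_OUTCOMES):
            se = float(np.sqrt(self.cov_effects[i, i]))
            lines.append(
                f"{name:<10}{self.effects[i]:>10.4f}{se:>10.4f}"
                f"{ci[i, 0]:>10.4f}{ci[i, 1]:>10.4f}"
            )
        if self.resid_cov is not None:
            r = self.resid_cov
            corr = r[0, 1] / np.sqrt(r[0, 0] * r[1, 1])
            lines.append(
                f"residual cov: s11={r[0, 0]:.4g} s22={r[1, 1]:.4g} "
                f"s12={r[0, 1]:.4g} (corr {corr:.3f})"
            )
        lines.append(
            f"effect cov: cov(cost, qaly) = {self.cov_effects[0, 1]:.4g}"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "effects": self.effects.tolist(),
            "cov_effects": self.cov_effects.tolist(),
            "resid_cov": None if self.resid_cov is None else self.resid_cov.tolist(),
            "nuisance": self.nuisance,
            "ci_level": self.ci_level,
            "n_used": self.n_used,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "SystemResults":
        return cls(
            method=raw["method"],
            effects=np.asarray(raw["effects"], dtype=float),
            cov_effects=np.asarray(raw["cov_effects"], dtype=float),
            resid_cov=(
                None
                if raw.get("resid_cov") is None
                else np.asarray(raw["resid_cov"], dtype=float)
            ),
            nuisance=raw.get("nuisance", {}),
            ci_level=raw.get("ci_level", 0.95),
            n_used=raw.get("n_used", 0),
        )


# --------------------------------------------------------------------- helpers
def _complete_rows(trial: TrialData, xmat: np.ndarray | None) -> np.ndarray:
    keep = ~(
        np.isnan(trial.z) | np.isnan(trial.d) | np.isnan(trial.y1) | np.isnan(trial.y2)
    )
    if xmat is not None:
        keep &= ~np.isnan(xmat).any(axis=1)
    return keep


def _design(col: np.ndarray, xmat: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(col), col]
    if xmat is not None:
        cols.append(xmat)
    return np.column_stack(cols)


def _check_arms(z: np.ndarray) -> None:
    if not ((z == 1).any() and (z == 0).any()):
        raise ValueError("both allocation arms must be non-empty")


def _first_stage_check(z: np.ndarray, d: np.ndarray) -> None:
    diff = d[z == 1].mean() - d[z == 0].mean()
    if abs(diff) < 1e-12:
        raise WeakInstrumentError(
            "allocation does not predict treatment received (first-stage "
            "difference is zero); the IV estimand is not identified"
        )


def _projected(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Regressors with endogenous columns replaced by their fit on W."""
    coef, *_ = np.linalg.lstsq(W, X, rcond=None)
    return W @ coef


def _system_fgls(
    ys: list[np.ndarray], Xs: list[np.ndarray], Xhats: list[np.ndarray]
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Two-step FGLS for a 2-equation system with (possibly) instrumented
    regressors.  Returns per-equation coefficients, the joint coefficient
    covariance, and the stage-one residual covariance (divisor n)."""
    n = ys[0].shape[0]
    betas0 = []
    resid = np.empty((n, 2))
    for l in range(2):
        b = np.linalg.solve(Xhats[l].T @ Xs[l], Xhats[l].T @ ys[l])
        betas0.append(b)
        resid[:, l] = ys[l] - Xs[l] @ b
    sigma = resid.T @ resid / n
    try:
        A = np.linalg.inv(sigma)
    except np.linalg.LinAlgError as err:  # pragma: no cover - degenerate data
        raise ValueError("singular residual covariance in FGLS stage") from err

    ks = [X.shape[1] for X in Xs]
    K = np.zeros((sum(ks), sum(ks)))
    r = np.zeros(sum(ks))
    offs = np.concatenate([[0], np.cumsum(ks)])
    for l in range(2):
        sl = slice(offs[l], offs[l + 1])
        for m in range(2):
            sm = slice(offs[m], offs[m + 1])
            K[sl, sm] = A[l, m] * (Xhats[l].T @ Xhats[m])
            r[offs[l] : offs[l + 1]] += A[l, m] * (Xhats[l].T @ ys[m])
    cov = np.linalg.inv(K)
    beta = cov @ r
    betas = [beta[offs[l] : offs[l + 1]] for l in range(2)]
    return betas, cov, sigma


def _pack_system(
    method: str,
    betas: list[np.ndarray],
    cov: np.ndarray,
    sigma: np.ndarray | None,
    ks: list[int],
    n_used: int,
    ci_level: float,
    covariate_names: Sequence[str] | None,
) -> SystemResults:
    # effect coefficient sits in position 1 of each equation ([const, effect, x...])
    idx = [1, ks[0] + 1]
    effects = np.array([betas[0][1], betas[1][1]])
    cov_eff = cov[np.ix_(idx, idx)]
    names = ["const", "effect"] + list(covariate_names or [])
    nuisance = {
        out: {nm: float(v) for nm, v in zip(names, b) if nm != "effect"}
        for out, b in zip(_OUTCOMES, betas)
    }
    return SystemResults(
        method=method,
        effects=effects,
        cov_effects=cov_eff,
        resid_cov=sigma,
        nuisance=nuisance,
        ci_level=ci_level,
        n_used=n_used,
    )


# ------------------------------------------------------------------ estimators
def wald_estimate(trial: TrialData, outcome: str = "cost") -> tuple[float, float]:
    """Wald (ratio of arm-mean differences) CACE estimate and its SE.

    The standard error is the delta-method / 2SLS asymptotic one, so this is
    numerically identical to a no-covariate two-stage least squares fit.
    """
    if outcome not in _OUTCOMES:
        raise ValueError(f"outcome must be one of {_OUTCOMES}")
    keep = _complete_rows(trial, None)
    z, d = trial.z[keep], trial.d[keep]
    y = (trial.y1 if outcome == "cost" else trial.y2)[keep]
    _check_arms(z)
    _first_stage_check(z, d)
    num = y[z == 1].mean() - y[z == 0].mean()
    den = d[z == 1].mean() - d[z == 0].mean()
    theta = num / den
    # homoskedastic 2SLS asymptotic variance
    W = _design(z, None)
    X = _design(d, None)
    Xhat = _projected(X, W)
    beta = np.linalg.solve(Xhat.T @ X, Xhat.T @ y)
    e = y - X @ beta
    s2 = float(e @ e) / len(y)
    var = s2 * np.linalg.inv(Xhat.T @ Xhat)[1, 1]
    return float(theta), float(np.sqrt(var))


class _SystemModel:
    """Shared plumbing for the two-equation system fitters."""

    method = "base"

    def __init__(
        self,
        trial: TrialData,
        covariates: Sequence[str] | None = None,
        ci_level: float = 0.95,
    ) -> None:
        self.trial = trial
        self.covariates = list(covariates) if covariates else None
        self.ci_level = ci_level

    def _prepare(self) -> tuple[np.ndarray, ...]:
        xmat = self.trial.covariate_matrix(self.covariates)
        keep = _complete_rows(self.trial, xmat)
        z = self.trial.z[keep]
        d = self.trial.d[keep]
        y1 = self.trial.y1[keep]
        y2 = self.trial.y2[keep]
        x = xmat[keep] if xmat is not None else None
        _check_arms(z)
        return z, d, y1, y2, x


class SURSystem(_SystemModel):
    """Seemingly unrelated regressions of (cost, QALY) on an exogenous
    regressor (allocation by default): the ITT analysis."""

    method = "sur_itt"

    def __init__(self, trial, covariates=None, ci_level=0.95, regressor="z"):
        super().__init__(trial, covariates, ci_level)
        if regressor not in ("z", "d"):
            raise ValueError("regressor must be 'z' or 'd'")
        self.regressor = regressor

    def fit(self) -> SystemResults:
        z, d, y1, y2, x = self._prepare()
        reg = z if self.regressor == "z" else d
        X = _design(reg, x)
        betas, cov, sigma = _system_fgls([y1, y2], [X, X], [X, X])
        return _pack_system(
            self.method, betas, cov, sigma, [X.shape[1]] * 2,
            len(y1), self.ci_level, self.covariates,
        )


class TwoStageLS(_SystemModel):
    """Per-outcome 2SLS with allocation instrumenting treatment received.

    ``cov_effects`` is diagonal by construction: the comparator ignores the
    cost–QALY correlation when propagating uncertainty to the net benefit.
    """

    method = "tsls"

    def fit(self) -> SystemResults:
        z, d, y1, y2, x = self._prepare()
        _first_stage_check(z, d)
        W = _design(z, x)
        X = _design(d, x)
        Xhat = _projected(X, W)
        n = len(y1)
        betas, ses2, resid = [], [], np.empty((n, 2))
        XtX_inv = np.linalg.inv(Xhat.T @ Xhat)
        for l, y in enumerate((y1, y2)):
            b = np.linalg.solve(Xhat.T @ X, Xhat.T @ y)
            e = y - X @ b
            resid[:, l] = e
            betas.append(b)
            ses2.append(float(e @ e) / n * XtX_inv[1, 1])
        sigma = resid.T @ resid / n
        cov_eff = np.diag(ses2)
        effects = np.array([betas[0][1], betas[1][1]])
        names = ["const", "effect"] + list(self.covariates or [])
        nuisance = {
            out: {nm: float(v) for nm, v in zip(names, b) if nm != "effect"}
            for out, b in zip(_OUTCOMES, betas)
        }
        return SystemResults(
            method=self.method,
            effects=effects,
            cov_effects=cov_eff,
            resid_cov=sigma,
            nuisance=nuisance,
            ci_level=self.ci_level,
            n_used=n,
        )


class ThreeStageLS(_SystemModel):
    """Three-stage least squares for the bivariate system.

    Stages one and two are per-outcome 2SLS; the third stage re-estimates the
    system by FGLS with the residual covariance from stage two, yielding the
    full 2x2 covariance of the treatment effects used for INB inference.
    """

    method = "threesls"

    def fit(self) -> SystemResults:
        z, d, y1, y2, x = self._prepare()
        _first_stage_check(z, d)
        W = _design(z, x)
        X = _design(d, x)
        Xhat = _projected(X, W)
        betas, cov, sigma = _system_fgls([y1, y2], [X, X], [Xhat, Xhat])
        return _pack_system(
            self.method, betas, cov, sigma, [X.shape[1]] * 2,
            len(y1), self.ci_level, self.covariates,
        )


class NaiveSystem(_SystemModel):
    """Per-protocol / as-treated comparators (confounded by design).

    * per-protocol: drop switchers (``s == 1`` when available, else rows with
      ``d != z``) and run the ITT SUR on the remainder.
    * as-treated: SUR of the outcomes on treatment received, ignoring
      allocation.
    """

    def __init__(self, trial, kind="per_protocol", covariates=None, ci_level=0.95):
        super().__init__(trial, covariates, ci_level)
        if kind not in ("per_protocol", "as_treated"):
            raise ValueError("kind must be 'per_protocol' or 'as_treated'")
        self.kind = kind
        self.method = kind

    def fit(self) -> SystemResults:
        trial = self.trial
        if self.kind == "per_protocol":
            # protocol deviators are those whose received treatment differs
            # from allocation (one-sided designs: s=1 in the active arm)
            keep = ~(trial.d != trial.z)
            sub = TrialData(
                z=trial.z[keep],
                d=trial.d[keep],
                y1=trial.y1[keep],
                y2=trial.y2[keep],
                x=trial.x.loc[keep].reset_index(drop=True) if trial.x is not None else None,
            )
            if not ((sub.z == 1).any() and (sub.z == 0).any()):
                raise ValueError("an allocation arm is empty after excluding switchers")
            res = SURSystem(sub, self.covariates, self.ci_level, regressor="z").fit()
        else:
            if not ((trial.d == 1).any() and (trial.d == 0).any()):
                raise ValueError("both treatment-received groups must be non-empty")
            res = SURSystem(trial, self.covariates, self.ci_level, regressor="d").fit()
        res.method = self.kind
        return res


def tsls_fit(
    trial: TrialData,
    outcome: str = "both",
    covariates: Sequence[str] | None = None,
    ci_level: float = 0.95,
) -> SystemResults | tuple[float, float]:
    """Two-stage least squares; ``outcome='both'`` returns a
    :class:`SystemResults`, a single outcome returns ``(estimate, se)``."""
    res = TwoStageLS(trial, covariates, ci_level).fit()
    if outcome == "both":
        return res
    if outcome not in _OUTCOMES:
        raise ValueError(f"outcome must be 'both' or one of {_OUTCOMES}")
    i = _OUTCOMES.index(outcome)
    return float(res.effects[i]), float(np.sqrt(res.cov_effects[i, i]))
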
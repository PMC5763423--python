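"""Bayesian IV models for bivariate cost-effectiveness outcomes.

Three models share one fitting protocol and one results container:

* :class:`BayesNormalIV` (uBN) — normal first stage and normal outcomes whose
  means condition on the first-stage *linear predictor*; the error structures
  of treatment received and outcomes are assumed independent ("unadjusted").
* :class:`BayesGammaNormalIV` (uBGN) — logistic first stage with raw-residual
  inclusion, gamma costs, conditionally normal QALYs.
* :class:`FullLikelihoodIV` (BFL) — trivariate normal reduced form over
  (D, Y1, Y2) with an unstructured covariance and a Wishart prior on its
  inverse; the allocation coefficient enters the outcome means as the product
  ``beta_effect * beta_firststage``, so the causal effects are read off
  directly.

The sampling protocol mirrors common practice for these models: two chains
with an initial run and burn-in, extension blocks until the Geweke statistic
(first 10% vs last 50% of the retained window) is below threshold for every
monitored parameter, then a final run per chain pooled into the kept sample.
Posteriors are summarised by median, SD and equal-tailed 95% intervals, and
net benefit / ICER are computed draw by draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _samplers
from .data import COST_SCALE, QALY_SCALE, TrialData

__all__ = [
    "McmcProtocol",
    "PosteriorResults",
    "geweke_z",
    "run_convergence_loop",
    "BayesNormalIV",
    "BayesGammaNormalIV",
    "FullLikelihoodIV",
    "fit_ubn",
    "fit_ubgn",
    "fit_bfl",
]


@dataclass(frozen=True)
class McmcProtocol:
    """Chain-length and convergence-checking policy.

    The kept sample is ``n_chains * final_block`` draws (``target_kept`` is
    validated against this product).  ``geweke_first``/``geweke_last`` are the
    fractions of the retained window compared by the Geweke statistic.
    """

    n_chains: int = 2
    init_iters: int = 5000
    burn_in: int = 1000
    extension_block: int = 1000
    final_block: int = 5000
    target_kept: int = 10000
    geweke_first: float = 0.10
    geweke_last: float = 0.50
    geweke_threshold: float = 2.5
    max_extensions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chains",
            "init_iters",
            "burn_in",
            "extension_block",
            "final_block",
            "target_kept",
            "max_extensions",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.burn_in >= self.init_iters:
            raise ValueError("burn_in must be smaller than init_iters")
        for name in ("geweke_first", "geweke_last"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.geweke_first + self.geweke_last > 1.0:
            raise ValueError("geweke windows overlap")
        if self.n_chains * self.final_block != self.target_kept:
            raise ValueError(
                "target_kept must equal n_chains * final_block "
                f"({self.n_chains} * {self.final_block} != {self.target_kept})"
            )

    @classmethod
    def reduced(cls, seed: int = 0, **over) -> "McmcProtocol":
        """A shorter protocol for simulation studies (documented scale-down)."""
        kwargs = dict(
            init_iters=1200,
            burn_in=400,
            extension_block=400,
            final_block=1500,
            target_kept=3000,
            max_extensions=5,
            seed=seed,
        )
        kwargs.update(over)
        return cls(**kwargs)


# ------------------------------------------------------------------- diagnostics
def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density of a chain segment at frequency zero (Bartlett
    window), the long-run variance used by the Geweke statistic."""
    x = np.asarray(x, float)
    n = len(x)
    x = x - x.mean()
    var = float(x @ x) / n
    if n < 8 or var == 0.0:
        return max(var, 1e-300)
    lags = max(1, int(np.floor(4.0 * (n / 100.0) ** (2.0 / 9.0))))
    s = var
    for k in range(1, min(lags, n - 1) + 1):
        gamma_k = float(x[k:] @ x[:-k]) / n
        s += 2.0 * (1.0 - k / (lags + 1.0)) * gamma_k
    return max(s, 1e-300)


def geweke_z(chain: np.ndarray, first: float = 0.10, last: float = 0.50) -> float:
    """Geweke convergence z-score comparing the first ``first`` and last
    ``last`` fractions of a chain, with spectral-density variance estimates.

    Approximately N(0, 1) for a stationary chain.
    """
    chain = np.asarray(chain, float)
    n = len(chain)
    if n < 20:
        raise ValueError("chain too short for a Geweke diagnostic")
    a = chain[: max(int(np.floor(first * n)), 5)]
    b = chain[n - max(int(np.floor(last * n)), 5) :]
    var = _spectral_density_zero(a) / len(a) + _spectral_density_zero(b) / len(b)
    return float((a.mean() - b.mean()) / np.sqrt(var))


def run_convergence_loop(chains: Sequence, protocol: McmcProtocol):
    """Drive per-chain samplers through the initial/extend/final protocol.

    ``chains`` are sampler objects exposing ``run(n, adapt=...)`` and the
    class attribute ``geweke_params``.  Returns ``(kept, diagnostics)`` where
    ``kept`` maps parameter name -> pooled kept draws (chains concatenated)
    and ``diagnostics`` records Geweke scores, extensions used and a
    convergence flag.
    """
    kept: dict[str, list[np.ndarray]] = {}
    diag = {"chains": [], "converged": True}
    monitored = chains[0].geweke_params
    for ci, chain in enumerate(chains):
        hist = chain.run(protocol.init_iters, adapt=True)
        window = {k: v[protocol.burn_in :] for k, v in hist.items()}
        n_ext = 0
        z = {
            k: geweke_z(window[k], protocol.geweke_first, protocol.geweke_last)
            for k in monitored
        }
        while (
            max(abs(v) for v in z.values()) >= protocol.geweke_threshold
            and n_ext < protocol.max_extensions
        ):
            ext = chain.run(protocol.extension_block)
            window = {k: np.concatenate([window[k], ext[k]]) for k in window}
            n_ext += 1
            z = {
                k: geweke_z(window[k], protocol.geweke_first, protocol.geweke_last)
                for k in monitored
            }
        converged = max(abs(v) for v in z.values()) < protocol.geweke_threshold
        final = chain.run(protocol.final_block)
        for k, v in final.items():
            kept.setdefault(k, []).append(v)
        diag["chains"].append(
            {"geweke_z": z, "extensions": n_ext, "converged": converged}
        )
        if not converged:
            diag["converged"] = False
            warnings.warn(
                f"chain {ci} failed the Geweke check after "
                f"{protocol.max_extensions} extension blocks; results are "
                "flagged as non-converged",
                stacklevel=2,
            )
    pooled = {k: np.concatenate(v) for k, v in kept.items()}
    return pooled, diag


# ------------------------------------------------------------------------ results
@dataclass
class PosteriorResults:
    """Posterior draws and their summaries from a Bayesian IV fit.

    Summaries follow the median / posterior-SD / equal-tailed 95% convention.
    ``beta_cost`` and ``beta_qaly`` are the causal treatment effects on the
    analysis scale; ``inb`` and ``icer`` are derived draw by draw on the
    natural (£, QALY) scale.
    """

    model: str
    draws: dict[str, np.ndarray]
    diagnostics: dict
    lambda_wtp: float = 30000.0
    cost_scale: float = COST_SCALE
    qaly_scale: float = QALY_SCALE

    def __post_init__(self) -> None:
        bc = self.cost_scale * self.draws["beta_cost"]
        bq = self.qaly_scale * self.draws["beta_qaly"]
        self.draws = dict(self.draws)
        self.draws["inb"] = self.lambda_wtp * bq - bc
        with np.errstate(divide="ignore", invalid="ignore"):
            self.draws["icer"] = bc / bq

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", True))

    @property
    def n_kept(self) -> int:
        return len(self.draws["beta_cost"])

    def params(self) -> list[str]:
        return list(self.draws)

    def median(self, name: str) -> float:
        return float(np.median(self.draws[name]))

    def sd(self, name: str) -> float:
        return float(np.std(self.draws[name], ddof=1))

    def interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        lo, hi = np.quantile(self.draws[name], [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)

    @property
    def beta_cost(self) -> float:
        return self.median("beta_cost")

    @property
    def beta_qaly(self) -> float:
        return self.median("beta_qaly")

    def summary(self, params: Sequence[str] | None = None) -> str:
        params = list(params) if params is not None else self.params()
        lines = [
            f"Posterior summary ({self.model}), kept draws = {self.n_kept}, "
            f"converged = {self.converged}",
            f"{'parameter':<18}{'median':>12}{'sd':>12}{'2.5%':>12}{'97.5%':>12}",
        ]
        for p in params:
            lo, hi = self.interval(p)
            lines.append(
                f"{p:<18}{self.median(p):>12.4f}{self.sd(p):>12.4f}"
                f"{lo:>12.4f}{hi:>12.4f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {"model": self.model, "converged": self.converged, "params": {}}
        for p in self.params():
            lo, hi = self.interval(p)
            out["params"][p] = {
                "median": self.median(p),
                "sd": self.sd(p),
                "ci_2.5": lo,
                "ci_97.5": hi,
            }
        return out


# ------------------------------------------------------------------------- models
class _BayesModel:
    """Shared constructor/fit plumbing for the three Bayesian IV models."""

    sampler_cls: type
    model_name = "base"

    def __init__(
        self,
        trial: TrialData,
        covariates: Sequence[str] | None = None,
        lambda_wtp: float = 30000.0,
        cost_scale: float = COST_SCALE,
        qaly_scale: float = QALY_SCALE,
        **sampler_kwargs,
    ) -> None:
        self.trial = trial
        self.covariates = list(covariates) if covariates else None
        self.lambda_wtp = lambda_wtp
        self.cost_scale = cost_scale
        self.qaly_scale = qaly_scale
        self.sampler_kwargs = sampler_kwargs

    def _make_chains(self, protocol: McmcProtocol) -> list:
        trial = self.trial
        if np.isnan(trial.z).any() or np.isnan(trial.d).any():
            raise ValueError("allocation and treatment received must be complete")
        xcov = trial.covariate_matrix(self.covariates)
        if xcov is not None and np.isnan(xcov).any():
            raise ValueError(
                "covariates must be complete; impute them externally "
                "(e.g. MI + rubin_pool)"
            )
        ss = np.random.SeedSequence(protocol.seed)
        return [
            self.sampler_cls(
                trial.z,
                trial.d,
                trial.y1,
                trial.y2,
                xcov,
                np.random.default_rng(child),
                **self.sampler_kwargs,
            )
            for child in ss.spawn(protocol.n_chains)
        ]

    def fit(self, protocol: McmcProtocol | None = None) -> PosteriorResults:
        protocol = protocol or McmcProtocol()
        chains = self._make_chains(protocol)
        pooled, diag = run_convergence_loop(chains, protocol)
        return PosteriorResults(
            model=self.model_name,
            draws=pooled,
            diagnostics=diag,
            lambda_wtp=self.lambda_wtp,
            cost_scale=self.cost_scale,
            qaly_scale=self.qaly_scale,
        )


class BayesNormalIV(_BayesModel):
    """uBN: normal first stage, normal outcomes conditioned on the
    first-stage linear predictor; independent error structures."""

    sampler_cls = _samplers.UBNSampler
    model_name = "ubn"


class BayesGammaNormalIV(_BayesModel):
    """uBGN: logistic first stage with residual inclusion, gamma costs,
    conditionally normal QALYs.  Requires strictly positive costs."""

    sampler_cls = _samplers.UBGNSampler
    model_name = "ubgn"


class FullLikelihoodIV(_BayesModel):
    """BFL: trivariate normal over (D, Y1, Y2) with unstructured covariance.

    ``wishart_df`` selects the prior on the inverse covariance: 4 (dimension
    + 1, the default) or the sensitivity variant 6, both with identity scale.
    """

    sampler_cls = _samplers.BFLSampler
    model_name = "bfl"

    def __init__(self, trial, covariates=None, wishart_df: int = 4, **kw):
        super().__init__(trial, covariates, wishart_df=wishart_df, **kw)


# thin functional wrappers matching the operation-style API
def fit_ubn(trial, protocol=None, **kw) -> PosteriorResults:
    return BayesNormalIV(trial, **kw).fit(protocol)


def fit_ubgn(trial, protocol=None, **kw) -> PosteriorResults:
    return BayesGammaNormalIV(trial, **kw).fit(protocol)


def fit_bfl(trial, protocol=None, **kw) -> PosteriorResults:
    return FullLikelihoodIV(trial, **kw).fit(protocol)
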
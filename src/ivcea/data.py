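"""Core data containers: trial datasets and simulation scenario configurations.

The trial container mirrors what a CEA-with-non-compliance analysis needs:
random allocation ``z``, treatment received ``d``, a cost outcome ``y1``
(rescaled to thousands of pounds) and an effectiveness outcome ``y2``
(rescaled 0.1-QALY units), optional baseline covariates, and — for simulated
data only — the latent confounder ``u`` and switching indicator ``s`` that the
generator used. The latent columns are retained purely for oracle checks and
are never consumed by any estimator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "COST_SCALE",
    "QALY_SCALE",
    "ScenarioConfig",
    "TrialData",
    "read_trial_csv",
    "load_scenario",
    "dump_scenario",
]

#: Costs are modelled in units of £1000; multiply by this to return to £.
COST_SCALE = 1000.0
#: Effectiveness is modelled in units of 0.1 QALYs; multiply by this for QALYs.
QALY_SCALE = 0.1

_COST_DISTS = ("normal", "gamma", "inverse_gaussian")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterisation of one simulated-trial scenario.

    Defaults reproduce the base data-generating process of the simulation
    study: a confounder U ~ N(0.50, 0.25^2) drives one-sided non-compliance
    and shifts both outcome means; outcomes are linked by a Gaussian copula
    with latent correlation ``rho``; the cost marginal is normal, gamma
    (shape ``eta``) or inverse-Gaussian (shape ``eta``).

    Parameters
    ----------
    n : sample size (the study uses 100 or 1000).
    p_noncomp : average one-sided non-compliance probability p; switching
        probability is p + 0.1 when u > 0.5 and p - 0.1 otherwise.
    cost_dist : "normal", "gamma" or "inverse_gaussian".
    rho : Gaussian-copula (latent normal) correlation between outcomes.
    mu_coefs : (intercept, D-effect, U-slope) per outcome; the defaults give
        true incremental cost 0.4 (= £400) and incremental QALY 0.2 (= 0.02).
    sigma1, sigma2 : conditional SDs used by the normal marginals.
    eta : shape parameter shared by the gamma and inverse-Gaussian costs.
    lambda_wtp : willingness to pay per QALY, in £ (natural scale).
    """

    n: int = 100
    p_noncomp: float = 0.3
    cost_dist: str = "normal"
    rho: float = 0.4
    mu_coefs: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (1.2, 0.4, 0.16),
        (0.5, 0.2, 0.04),
    )
    sigma1: float = 0.2
    sigma2: float = 0.1
    eta: float = 4.0
    u_mean: float = 0.50
    u_sd: float = 0.25
    alloc_ratio: float = 0.5
    lambda_wtp: float = 30000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"sample size must be >= 1, got {self.n}")
        if not 0.0 < self.p_noncomp < 1.0:
            raise ValueError(f"p_noncomp must lie in (0, 1), got {self.p_noncomp}")
        if self.p_noncomp + 0.1 > 1.0 or self.p_noncomp - 0.1 < 0.0:
            raise ValueError(
                "p_noncomp +/- 0.1 must stay inside [0, 1]; "
                f"got p_noncomp={self.p_noncomp}"
            )
        if self.cost_dist not in _COST_DISTS:
            raise ValueError(
                f"cost_dist must be one of {_COST_DISTS}, got {self.cost_dist!r}"
            )
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"rho must lie in (-1, 1), got {self.rho}")
        if self.eta <= 0:
            raise ValueError(f"eta must be positive, got {self.eta}")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigma1 and sigma2 must be positive")
        if self.u_sd <= 0:
            raise ValueError(f"u_sd must be positive, got {self.u_sd}")
        if not 0.0 < self.alloc_ratio < 1.0:
            raise ValueError(f"alloc_ratio must lie in (0, 1), got {self.alloc_ratio}")
        coefs = np.asarray(self.mu_coefs, dtype=float)
        if coefs.shape != (2, 3):
            raise ValueError("mu_coefs must be two triples (one per outcome)")
        object.__setattr__(
            self, "mu_coefs", tuple(tuple(row) for row in coefs.tolist())
        )

    # ------------------------------------------------------------------ truths
    @property
    def true_cost_effect(self) -> float:
        """True incremental cost on the rescaled (£1000) scale."""
        return float(self.mu_coefs[0][1])

    @property
    def true_qaly_effect(self) -> float:
        """True incremental effectiveness on the rescaled (0.1-QALY) scale."""
        return float(self.mu_coefs[1][1])

    @property
    def true_inb(self) -> float:
        """True incremental net benefit in £ at ``lambda_wtp``."""
        return (
            self.lambda_wtp * QALY_SCALE * self.true_qaly_effect
            - COST_SCALE * self.true_cost_effect
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mu_coefs"] = [list(row) for row in self.mu_coefs]
        return d

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
        kwargs = dict(raw)
        if "mu_coefs" in kwargs:
            kwargs["mu_coefs"] = tuple(tuple(r) for r in kwargs["mu_coefs"])
        return cls(**kwargs)

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class TrialData:
    """One (simulated or imported) randomized trial.

    Missing values are represented as NaN in the float columns; ``mask``
    exposes per-column boolean missingness (True = missing).
    """

    z: np.ndarray
    d: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    u: np.ndarray | None = None
    s: np.ndarray | None = None
    x: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.y1 = np.asarray(self.y1, dtype=float)
        self.y2 = np.asarray(self.y2, dtype=float)
        n = self.z.shape[0]
        for name in ("d", "y1", "y2"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"column {name!r} has wrong length")
        for name in ("u", "s"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.shape != (n,):
                    raise ValueError(f"column {name!r} has wrong length")
                setattr(self, name, val)
        if self.x is not None:
            self.x = pd.DataFrame(self.x)
            if len(self.x) != n:
                raise ValueError("covariate frame has wrong length")
        for name in ("z", "d"):
            col = getattr(self, name)
            ok = np.isnan(col) | (col == 0.0) | (col == 1.0)
            if not ok.all():
                bad = int(np.flatnonzero(~ok)[0])
                raise ValueError(
                    f"column {name!r} must be binary (0/1/missing); "
                    f"row {bad} has value {col[bad]!r}"
                )

    # ---------------------------------------------------------------- basics
    @property
    def n(self) -> int:
        return int(self.z.shape[0])

    @property
    def mask(self) -> dict[str, np.ndarray]:
        """Per-column missingness mask (True where the value is missing)."""
        out = {name: np.isnan(getattr(self, name)) for name in ("z", "d", "y1", "y2")}
        if self.x is not None:
            for col in self.x.columns:
                out[str(col)] = self.x[col].isna().to_numpy()
        return out

    def covariate_matrix(self, names: Sequence[str] | None) -> np.ndarray | None:
        if not names:
            return None
        if self.x is None:
            raise ValueError("trial has no covariates")
        missing = [c for c in names if c not in self.x.columns]
        if missing:
            raise ValueError(f"unknown covariates: {missing}")
        return self.x.loc[:, list(names)].to_numpy(dtype=float)

    # ------------------------------------------------------------------- io
    def to_frame(self) -> pd.DataFrame:
        cols = {"z": self.z, "d": self.d, "y1": self.y1, "y2": self.y2}
        if self.u is not None:
            cols["u"] = self.u
        if self.s is not None:
            cols["s"] = self.s
        frame = pd.DataFrame(cols)
        if self.x is not None:
            frame = pd.concat([frame, self.x.reset_index(drop=True)], axis=1)
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialData":
        required = ("z", "d", "y1", "y2")
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"missing mandatory columns: {missing}")
        extras = [c for c in frame.columns if c not in ("z", "d", "y1", "y2", "u", "s")]
        return cls(
            z=frame["z"].to_numpy(dtype=float),
            d=frame["d"].to_numpy(dtype=float),
            y1=frame["y1"].to_numpy(dtype=float),
            y2=frame["y2"].to_numpy(dtype=float),
            u=frame["u"].to_numpy(dtype=float) if "u" in frame.columns else None,
            s=frame["s"].to_numpy(dtype=float) if "s" in frame.columns else None,
            x=frame[extras].copy() if extras else None,
        )


def read_trial_csv(path: str | Path) -> TrialData:
    """Read a trial dataset from CSV (header required, empty cells = missing)."""
    frame = pd.read_csv(path)
    return TrialData.from_frame(frame)


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load a :class:`ScenarioConfig` from JSON or YAML, filling defaults.

    An empty file yields the base scenario (n=100, p=0.3, normal costs,
    rho=0.4).
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"scenario file {path} must contain a mapping")
    return ScenarioConfig.from_dict(raw)


def dump_scenario(config: ScenarioConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
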
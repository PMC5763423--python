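"""MCMC kernels for the three Bayesian IV models.

Each sampler exposes ``run(n_iter, adapt=False)`` which advances the chain and
returns the recorded draws as ``{name: array}``; repeated calls continue the
same chain, which is what the convergence loop needs.

For the two jointly-normal models (uBN, BFL) every full conditional — and the
log-likelihood needed by the Metropolis block — depends on the data only
through the Gram matrix of ``[1, covariates, Z, D, Y1, Y2]``, so a sweep costs
O(1) in the sample size once that matrix is accumulated (it is re-accumulated
per sweep only when missing outcomes are being imputed).  The gamma–normal
model (uBGN) has non-conjugate blocks and uses vectorised O(n) likelihood
evaluations with random-walk Metropolis steps, adapted during burn-in only.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

_COEF_PREC = 0.01  # N(0, 10^2) prior on regression coefficients
_Z_PREC = 0.01  # N(0, 10^2) prior on Fisher's z of rho
_SIGMA_MAX = 10.0  # Uniform(0, 10) prior on standard deviations


def _draw_mvn(P: np.ndarray, rhs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(P^-1 rhs, P^-1) via Cholesky of the precision."""
    L = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, rhs)
    eps = rng.standard_normal(len(rhs))
    return mean + np.linalg.solve(L.T, eps)


def _draw_variance_trunc(ss: float, n: int, rng: np.random.Generator) -> float:
    """Sample sigma^2 under sigma ~ U(0, 10): inverse-gamma((n-1)/2, ss/2)
    truncated to sigma < 10."""
    shape = 0.5 * (n - 1)
    for _ in range(100):
        tau = rng.gamma(shape, 2.0 / ss)
        if tau > 1.0 / (_SIGMA_MAX**2):
            return 1.0 / tau
    return min(ss / max(n, 1), _SIGMA_MAX**2 * 0.99)  # pragma: no cover


class _AdaptiveMVN:
    """Adaptive random-walk proposal: scalar step-size tuning plus an
    empirical proposal covariance learned during burn-in (frozen after)."""

    def __init__(self, dim: int, init_scale: float = 0.1,
                 step_diag: np.ndarray | None = None) -> None:
        self.dim = dim
        self.scale = _AdaptiveScale(init_scale)
        self.step_diag = np.ones(dim) if step_diag is None else np.asarray(step_diag)
        self.count = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros((dim, dim))
        self._chol: np.ndarray | None = None

    def observe(self, draw: np.ndarray, adapt: bool) -> None:
        if not adapt:
            return
        self.count += 1
        delta = draw - self.mean
        self.mean += delta / self.count
        self.m2 += np.outer(delta, draw - self.mean)
        if self.count >= 80 and self.count % 40 == 0:
            cov = self.m2 / (self.count - 1) + 1e-10 * np.eye(self.dim)
            try:
                self._chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:  # pragma: no cover
                self._chol = None

    def propose(self, cur: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        eps = rng.standard_normal(self.dim)
        if self._chol is not None:
            step = (2.38 / np.sqrt(self.dim)) * (self._chol @ eps)
            return cur + self.scale.scale / 0.1 * step
        return cur + self.scale.scale * self.step_diag * eps

    def update(self, accepted: bool, adapt: bool) -> None:
        self.scale.update(accepted, adapt)


class _AdaptiveScale:
    """Robbins–Monro scalar step-size adaptation toward ~30% acceptance."""

    def __init__(self, init: float = 0.1) -> None:
        self.log_scale = np.log(init)
        self._acc = 0
        self._tries = 0

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))

    def update(self, accepted: bool, adapt: bool) -> None:
        if not adapt:
            return
        self._acc += accepted
        self._tries += 1
        if self._tries == 25:
            rate = self._acc / 25.0
            self.log_scale = float(
                np.clip(self.log_scale + 0.4 * (rate - 0.30), -10.0, 3.0)
            )
            self._acc = 0
            self._tries = 0


# ======================================================================== uBN
class UBNSampler:
    """Unadjusted Bayesian normal–normal IV model.

    D_i ~ N(mu0, sigma0^2),          mu0 = W a0 + b10 Z
    Y1_i ~ N(mu1, sigma1^2),         mu1 = W a1 + b11 mu0
    Y2_i | Y1_i ~ N(mu2, s2c),       mu2 = W a2 + b12 mu0 + b22 (y1 - mu1)
    with b22 = rho sigma2 / sigma1 and s2c = sigma2^2 (1 - rho^2): the
    outcome equations condition on the first-stage linear predictor, not on
    treatment received, and the error structures are assumed independent.
    """

    name = "ubn"
    effect_params = ("beta_cost", "beta_qaly")
    geweke_params = (
        "beta_cost",
        "beta_qaly",
        "rho",
        "sigma0",
        "sigma1",
        "sigma2",
    )

    def __init__(self, z, d, y1, y2, xcov, rng: np.random.Generator) -> None:
        self.rng = rng
        n = len(z)
        self.n = n
        self.W = np.column_stack([np.ones(n)] + ([xcov] if xcov is not None else []))
        self.p0 = self.W.shape[1]
        self.z = np.asarray(z, float)
        self.d = np.asarray(d, float)
        # centre outcomes to improve mixing; intercepts are shifted back on output
        self.m1 = float(np.nanmean(y1))
        self.m2 = float(np.nanmean(y2))
        self.y1 = np.asarray(y1, float) - self.m1
        self.y2 = np.asarray(y2, float) - self.m2
        self.miss1 = np.flatnonzero(np.isnan(self.y1))
        self.miss2 = np.flatnonzero(np.isnan(self.y2))
        self.y1[self.miss1] = 0.0
        self.y2[self.miss2] = 0.0
        self._has_missing = len(self.miss1) + len(self.miss2) > 0

        # basis T = [W, Z, D, y1, y2]; all conditionals use C = T'T
        self.pT = self.p0 + 4
        self.iZ, self.iD, self.i1, self.i2 = (
            self.p0,
            self.p0 + 1,
            self.p0 + 2,
            self.p0 + 3,
        )
        self._accum()
        self._init_state()
        self.mh = _AdaptiveScale(0.15)

    # ------------------------------------------------------------- plumbing
    def _accum(self) -> None:
        T = np.column_stack([self.W, self.z, self.d, self.y1, self.y2])
        self.T = T
        self.C = T.T @ T

    def _unit(self, idx: int) -> np.ndarray:
        e = np.zeros(self.pT)
        e[idx] = 1.0
        return e

    def _init_state(self) -> None:
        rng = self.rng
        z, d, y1, y2 = self.z, self.d, self.y1, self.y2
        p1 = d[z == 1].mean()
        p0c = d[z == 0].mean()
        a0 = np.zeros(self.p0)
        a0[0] = p0c
        b10 = max(p1 - p0c, 0.05)
        jitter = lambda s: rng.normal(0.0, s)
        self.a0 = a0 + jitter(0.05)
        self.b10 = b10 * np.exp(jitter(0.2))
        naive1 = (y1[z == 1].mean() - y1[z == 0].mean()) / max(b10, 0.05)
        naive2 = (y2[z == 1].mean() - y2[z == 0].mean()) / max(b10, 0.05)
        self.a1 = np.zeros(self.p0)
        self.b11 = naive1 + jitter(0.1)
        self.a2 = np.zeros(self.p0)
        self.b12 = naive2 + jitter(0.05)
        self.sig0sq = max(float(np.var(d)) * np.exp(jitter(0.3)), 1e-4)
        self.sig1 = float(np.std(y1)) * np.exp(jitter(0.2)) + 1e-3
        self.sig2 = float(np.std(y2)) * np.exp(jitter(0.2)) + 1e-3
        r = float(np.corrcoef(y1, y2)[0, 1]) if self.n > 2 else 0.0
        self.zr = np.arctanh(np.clip(r, -0.9, 0.9)) + jitter(0.1)

    # coefficient vectors of the current linear predictors in the T basis
    def _c0(self) -> np.ndarray:
        c = np.zeros(self.pT)
        c[: self.p0] = self.a0
        c[self.iZ] = self.b10
        return c

    def _c1(self, c0: np.ndarray) -> np.ndarray:
        c = self.b11 * c0
        c[: self.p0] += self.a1
        return c

    def _c2base(self, c0: np.ndarray) -> np.ndarray:
        c = self.b12 * c0
        c[: self.p0] += self.a2
        return c

    @property
    def rho(self) -> float:
        return float(np.tanh(self.zr))

    def _b22(self, sig1: float, sig2: float, rho: float) -> float:
        return rho * sig2 / sig1

    # ------------------------------------------------------------ MH target
    def _loglik_sig(self, sig1: float, sig2: float, zr: float) -> float:
        """Log-likelihood of (Y1, Y2 | D-stage params) as a function of the
        scale block, via Gram products."""
        rho = float(np.tanh(zr))
        b22 = self._b22(sig1, sig2, rho)
        s2c = sig2**2 * (1.0 - rho**2)
        C = self.C
        c0 = self._c0()
        c1 = self._c1(c0)
        e1 = self._unit(self.i1) - c1
        ss1 = float(e1 @ C @ e1)
        e2 = self._unit(self.i2) - self._c2base(c0) - b22 * (self._unit(self.i1) - c1)
        ss2 = float(e2 @ C @ e2)
        n = self.n
        return (
            -n * np.log(sig1)
            - 0.5 * ss1 / sig1**2
            - 0.5 * n * np.log(s2c)
            - 0.5 * ss2 / s2c
        )

    def _logpost_sig(self, logs1: float, logs2: float, zr: float) -> float:
        sig1, sig2 = np.exp(logs1), np.exp(logs2)
        if sig1 >= _SIGMA_MAX or sig2 >= _SIGMA_MAX:
            return -np.inf
        # U(0,10) prior on sigma with log-scale proposal => + log sigma Jacobian
        return (
            self._loglik_sig(sig1, sig2, zr)
            + logs1
            + logs2
            - 0.5 * _Z_PREC * zr**2
        )

    # -------------------------------------------------------------- updates
    def _impute(self) -> None:
        rho = self.rho
        b22 = self._b22(self.sig1, self.sig2, rho)
        s2c = self.sig2**2 * (1.0 - rho**2)
        mu0 = self.W @ self.a0 + self.b10 * self.z
        mu1 = self.W @ self.a1 + self.b11 * mu0
        mu2b = self.W @ self.a2 + self.b12 * mu0
        if len(self.miss1):
            i = self.miss1
            prec = 1.0 / self.sig1**2 + b22**2 / s2c
            mean = (
                mu1[i] / self.sig1**2
                + b22 * (self.y2[i] - mu2b[i] + b22 * mu1[i]) / s2c
            ) / prec
            self.y1[i] = mean + self.rng.standard_normal(len(i)) / np.sqrt(prec)
        if len(self.miss2):
            i = self.miss2
            mean = mu2b[i] + b22 * (self.y1[i] - mu1[i])
            self.y2[i] = mean + self.rng.standard_normal(len(i)) * np.sqrt(s2c)
        self._accum()

    def _sweep(self, adapt: bool) -> None:
        rng = self.rng
        C = self.C
        p0, pT = self.p0, self.pT
        if self._has_missing:
            self._impute()
            C = self.C
        rho = self.rho
        b22 = self._b22(self.sig1, self.sig2, rho)
        s2c = self.sig2**2 * (1.0 - rho**2)

        # --- (a1, b11) block: observed through Y1 and the (y1 - mu1) term
        c0 = self._c0()
        Gb = np.zeros((pT, p0 + 1))  # basis coords of [W, mu0]
        Gb[:p0, :p0] = np.eye(p0)
        Gb[:, p0] = c0
        GtG = Gb.T @ C @ Gb
        u1 = self._unit(self.i1)
        u2 = self._unit(self.i2)
        c2b = self._c2base(c0)
        Gy1 = Gb.T @ (C @ u1)
        # c2 = y2 - mu2base - b22*y1 (coefficients in T basis)
        c2 = u2 - c2b - b22 * u1
        Gc2 = Gb.T @ (C @ c2)
        P = _COEF_PREC * np.eye(p0 + 1) + (1.0 / self.sig1**2 + b22**2 / s2c) * GtG
        rhs = Gy1 / self.sig1**2 - b22 * Gc2 / s2c
        th1 = _draw_mvn(P, rhs, rng)
        self.a1, self.b11 = th1[:p0], float(th1[p0])

        # --- (a2, b12) block: target y2 - b22 (y1 - mu1)
        c1 = self._c1(c0)
        tgt = u2 - b22 * (u1 - c1)
        Gt = Gb.T @ (C @ tgt)
        P = _COEF_PREC * np.eye(p0 + 1) + GtG / s2c
        th2 = _draw_mvn(P, Gt / s2c, rng)
        self.a2, self.b12 = th2[:p0], float(th2[p0])

        # --- (a0, b10) block: enters all three equations through mu0
        Fb = np.zeros((pT, p0 + 1))
        Fb[:p0, :p0] = np.eye(p0)
        Fb[self.iZ, p0] = 1.0
        FtF = Fb.T @ C @ Fb
        cc = self.b12 - b22 * self.b11
        uD = self._unit(self.iD)
        a1c = np.zeros(pT)
        a1c[:p0] = self.a1
        a2c = np.zeros(pT)
        a2c[:p0] = self.a2
        t1 = u1 - a1c
        t2 = u2 - a2c - b22 * t1
        P = (
            _COEF_PREC * np.eye(p0 + 1)
            + (1.0 / self.sig0sq + self.b11**2 / self.sig1**2 + cc**2 / s2c) * FtF
        )
        rhs = (
            Fb.T @ (C @ uD) / self.sig0sq
            + self.b11 * (Fb.T @ (C @ t1)) / self.sig1**2
            + cc * (Fb.T @ (C @ t2)) / s2c
        )
        th0 = _draw_mvn(P, rhs, rng)
        self.a0, self.b10 = th0[:p0], float(th0[p0])

        # --- sigma0^2 (conjugate, truncated by the uniform prior)
        eD = uD - self._c0()
        ss0 = float(eD @ C @ eD)
        self.sig0sq = _draw_variance_trunc(max(ss0, 1e-12), self.n, rng)

        # --- (log sigma1, log sigma2, z) joint random-walk Metropolis
        cur = np.array([np.log(self.sig1), np.log(self.sig2), self.zr])
        lp_cur = self._logpost_sig(*cur)
        prop = cur + self.mh.scale * rng.standard_normal(3)
        lp_prop = self._logpost_sig(*prop)
        accept = np.log(rng.random()) < lp_prop - lp_cur
        if accept:
            self.sig1, self.sig2 = float(np.exp(prop[0])), float(np.exp(prop[1]))
            self.zr = float(prop[2])
        self.mh.update(bool(accept), adapt)

    def _record(self) -> dict[str, float]:
        return {
            "beta_cost": self.b11,
            "beta_qaly": self.b12,
            "rho": self.rho,
            "z_rho": float(self.zr),
            "sigma0": float(np.sqrt(self.sig0sq)),
            "sigma1": self.sig1,
            "sigma2": self.sig2,
            "beta00": float(self.a0[0]),
            "beta10": self.b10,
            "beta01": float(self.a1[0] + self.m1),
            "beta02": float(self.a2[0] + self.m2),
        }

    def run(self, n_iter: int, adapt: bool = False) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {}
        for _ in range(n_iter):
            self._sweep(adapt)
            for k, v in self._record().items():
                out.setdefault(k, []).append(v)
        return {k: np.asarray(v) for k, v in out.items()}


# ======================================================================== BFL
class BFLSampler:
    """Bayesian full-likelihood (trivariate reduced-form) IV model.

    (D, Y1, Y2) ~ N((mu0, mu1, mu2), Sigma) with unstructured Sigma;
    mu0 = W a0 + b10 Z, mu1 = W a1 + b11 b10 Z, mu2 = W a2 + b12 b10 Z.
    The product parameterisation makes b11/b12 the causal effects; the
    Wishart prior on Sigma^-1 (df ``wishart_df``, identity scale) follows the
    usual weakly-informative choice df = dim + 1.
    """

    name = "bfl"
    effect_params = ("beta_cost", "beta_qaly")
    geweke_params = (
        "beta_cost",
        "beta_qaly",
        "rho",
        "s00",
        "s11",
        "s22",
        "s12",
    )

    def __init__(self, z, d, y1, y2, xcov, rng, wishart_df: int = 4) -> None:
        self.rng = rng
        n = len(z)
        self.n = n
        self.W = np.column_stack([np.ones(n)] + ([xcov] if xcov is not None else []))
        self.p0 = self.W.shape[1]
        self.z = np.asarray(z, float)
        self.d = np.asarray(d, float)
        self.m1 = float(np.nanmean(y1))
        self.m2 = float(np.nanmean(y2))
        self.y1 = np.asarray(y1, float) - self.m1
        self.y2 = np.asarray(y2, float) - self.m2
        self.miss1 = np.flatnonzero(np.isnan(self.y1))
        self.miss2 = np.flatnonzero(np.isnan(self.y2))
        self.y1[self.miss1] = 0.0
        self.y2[self.miss2] = 0.0
        self._has_missing = len(self.miss1) + len(self.miss2) > 0
        self.wishart_df = wishart_df
        self.prior_scale = np.eye(3)

        self.pT = self.p0 + 4
        self.iZ = self.p0
        self._accum()
        self._init_state()

    def _accum(self) -> None:
        # basis [W, Z, D, y1, y2]; Y block occupies the last three columns
        T = np.column_stack([self.W, self.z, self.d, self.y1, self.y2])
        self.T = T
        self.C = T.T @ T

    def _init_state(self) -> None:
        rng = self.rng
        z, d = self.z, self.d
        b10 = d[z == 1].mean() - d[z == 0].mean()
        self.b10 = float(b10 * np.exp(rng.normal(0, 0.2))) or 0.05
        den = self.b10 if abs(self.b10) > 0.05 else 0.05
        self.a0 = np.zeros(self.p0)
        self.a0[0] = d[z == 0].mean()
        self.a1 = np.zeros(self.p0)
        self.a2 = np.zeros(self.p0)
        self.b11 = float(
            (self.y1[z == 1].mean() - self.y1[z == 0].mean()) / den
            + rng.normal(0, 0.1)
        )
        self.b12 = float(
            (self.y2[z == 1].mean() - self.y2[z == 0].mean()) / den
            + rng.normal(0, 0.05)
        )
        Y = np.column_stack([d, self.y1, self.y2])
        S = np.cov(Y.T) + 1e-3 * np.eye(3)
        self.Omega = np.linalg.inv(S)

    # mean coefficients in the T basis (3 columns of mu as T @ Cmu)
    def _cmu(self) -> np.ndarray:
        Cmu = np.zeros((self.pT, 3))
        Cmu[: self.p0, 0] = self.a0
        Cmu[: self.p0, 1] = self.a1
        Cmu[: self.p0, 2] = self.a2
        Cmu[self.iZ, 0] = self.b10
        Cmu[self.iZ, 1] = self.b11 * self.b10
        Cmu[self.iZ, 2] = self.b12 * self.b10
        return Cmu

    def _impute(self) -> None:
        Cmu = self._cmu()
        MU = self.T @ Cmu  # n x 3 means (uses current y columns only via coefs=0)
        Sigma = np.linalg.inv(self.Omega)
        Y = np.column_stack([self.d, self.y1, self.y2])
        both = np.intersect1d(self.miss1, self.miss2)
        only1 = np.setdiff1d(self.miss1, both)
        only2 = np.setdiff1d(self.miss2, both)
        for idx, mdims in ((only1, [1]), (only2, [2]), (both, [1, 2])):
            if len(idx) == 0:
                continue
            odims = [k for k in range(3) if k not in mdims]
            Soo = Sigma[np.ix_(odims, odims)]
            Smo = Sigma[np.ix_(mdims, odims)]
            Smm = Sigma[np.ix_(mdims, mdims)]
            K = Smo @ np.linalg.inv(Soo)
            cond_cov = Smm - K @ Sigma[np.ix_(odims, mdims)]
            L = np.linalg.cholesky(cond_cov)
            resid_o = Y[np.ix_(idx, odims)] - MU[np.ix_(idx, odims)]
            mean = MU[np.ix_(idx, mdims)] + resid_o @ K.T
            draws = mean + self.rng.standard_normal(mean.shape) @ L.T
            for j, dm in enumerate(mdims):
                if dm == 1:
                    self.y1[idx] = draws[:, j]
                else:
                    self.y2[idx] = draws[:, j]
        self._accum()

    def _sweep(self) -> None:
        rng = self.rng
        if self._has_missing:
            self._impute()
        C = self.C
        p0, pT = self.p0, self.pT
        Om = self.Omega
        iY = [p0 + 1, p0 + 2, p0 + 3]  # D, y1, y2 columns in the basis

        # --- block (a0, a1, a2, b11, b12) | b10, Omega
        # design per subject: eq0: W a0 ; eq1: W a1 + b11 w ; eq2: W a2 + b12 w
        # with w = b10 Z and offset (w, 0, 0)
        SWW = C[:p0, :p0]
        SWz = C[:p0, self.iZ]
        Szz = C[self.iZ, self.iZ]
        w2 = self.b10**2 * Szz
        Ww = self.b10 * SWz
        k = 3 * p0 + 2
        P = _COEF_PREC * np.eye(k)
        for j in range(3):
            for l in range(3):
                P[j * p0 : (j + 1) * p0, l * p0 : (l + 1) * p0] += Om[j, l] * SWW
        ib11, ib12 = 3 * p0, 3 * p0 + 1
        for j in range(3):
            P[j * p0 : (j + 1) * p0, ib11] += Om[j, 1] * Ww
            P[ib11, j * p0 : (j + 1) * p0] += Om[j, 1] * Ww
            P[j * p0 : (j + 1) * p0, ib12] += Om[j, 2] * Ww
            P[ib12, j * p0 : (j + 1) * p0] += Om[j, 2] * Ww
        P[ib11, ib11] += Om[1, 1] * w2
        P[ib12, ib12] += Om[2, 2] * w2
        P[ib11, ib12] += Om[1, 2] * w2
        P[ib12, ib11] += Om[1, 2] * w2
        # rhs uses ytilde = y - offset; offset only affects equation 0
        WtY = C[np.ix_(range(p0), iY)].copy()  # W'[D, y1, y2]
        WtY[:, 0] -= self.b10 * SWz
        ztY = C[self.iZ, iY].copy()
        ztY[0] -= self.b10 * Szz
        rhs = np.empty(k)
        for j in range(3):
            rhs[j * p0 : (j + 1) * p0] = WtY @ Om[:, j]
        rhs[ib11] = self.b10 * (ztY @ Om[:, 1])
        rhs[ib12] = self.b10 * (ztY @ Om[:, 2])
        th = _draw_mvn(P, rhs, rng)
        self.a0 = th[0:p0]
        self.a1 = th[p0 : 2 * p0]
        self.a2 = th[2 * p0 : 3 * p0]
        self.b11 = float(th[ib11])
        self.b12 = float(th[ib12])

        # --- b10 | rest: coefficient of Z with loading v = (1, b11, b12)
        v = np.array([1.0, self.b11, self.b12])
        A = np.column_stack([self.a0, self.a1, self.a2])  # p0 x 3
        ztY = C[self.iZ, iY]  # Z'[D, y1, y2]
        ztA = C[self.iZ, :p0] @ A  # Z'(W a_j)
        q = ztY - ztA
        prec = _COEF_PREC + Szz * float(v @ Om @ v)
        rhs10 = float(v @ Om @ q)
        self.b10 = float(rng.normal(rhs10 / prec, 1.0 / np.sqrt(prec)))

        # --- Omega | rest: conjugate Wishart update
        Cmu = self._cmu()
        uY = np.zeros((pT, 3))
        for j, col in enumerate(iY):
            uY[col, j] = 1.0
        E = uY - Cmu  # residual coefficients in the T basis
        EtE = E.T @ C @ E
        scale = np.linalg.inv(self.prior_scale + EtE)
        scale = 0.5 * (scale + scale.T)
        self.Omega = stats.wishart.rvs(
            df=self.wishart_df + self.n, scale=scale, random_state=rng
        )

    def _record(self) -> dict[str, float]:
        Sigma = np.linalg.inv(self.Omega)
        rho = float(Sigma[1, 2] / np.sqrt(Sigma[1, 1] * Sigma[2, 2]))
        return {
            "beta_cost": self.b11,
            "beta_qaly": self.b12,
            "beta10": self.b10,
            "beta00": float(self.a0[0]),
            "beta01": float(self.a1[0] + self.m1),
            "beta02": float(self.a2[0] + self.m2),
            "s00": float(Sigma[0, 0]),
            "s01": float(Sigma[0, 1]),
            "s02": float(Sigma[0, 2]),
            "s11": float(Sigma[1, 1]),
            "s12": float(Sigma[1, 2]),
            "s22": float(Sigma[2, 2]),
            "rho": rho,
        }

    def run(self, n_iter: int, adapt: bool = False) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {}
        for _ in range(n_iter):
            self._sweep()
            for kk, vv in self._record().items():
                out.setdefault(kk, []).append(vv)
        return {kk: np.asarray(vv) for kk, vv in out.items()}


# ======================================================================= uBGN
class UBGNSampler:
    """Unadjusted Bayesian gamma–normal IV model.

    logit(pi) = W alpha + alpha1 Z;  D ~ Bern(pi);  r = D - pi
    Y1 ~ gamma(shape nu~, rate nu~/mu1),  mu1 = b01 + X bc + b11 D + b1r r
    Y2 | Y1 ~ N(mu2, sigma2^2 (1 - rho^2)),
    mu2 = W a2 + b12 D + b2r r + b22_i (y1 - mu1)
    with nu~ = nu + 0.01 (shape offset guarding against near-zero shapes) and
    b22_i = rho sigma2 / sd1_i, sd1_i = mu1_i / sqrt(nu~) the per-subject
    gamma SD.  The raw first-stage residuals r enter both outcome equations
    (two-stage residual inclusion).
    """

    name = "ubgn"
    effect_params = ("beta_cost", "beta_qaly")
    geweke_params = ("beta_cost", "beta_qaly", "rho", "sigma2", "nu")

    def __init__(self, z, d, y1, y2, xcov, rng) -> None:
        self.rng = rng
        y1 = np.asarray(y1, float)
        if np.any(np.isnan(y1)):
            raise ValueError(
                "the gamma cost model requires complete cost data; impute "
                "missing costs externally (e.g. MI + rubin_pool)"
            )
        if np.any(y1 <= 0.0):
            raise ValueError(
                "the gamma cost model requires strictly positive costs; "
                "set zero costs to missing and impute, or use the normal or "
                "full-likelihood model"
            )
        n = len(z)
        self.n = n
        self.z = np.asarray(z, float)
        self.d = np.asarray(d, float)
        self.y1 = y1
        self.xcov = xcov
        self.W = np.column_stack([np.ones(n)] + ([xcov] if xcov is not None else []))
        self.p0 = self.W.shape[1]
        self.m2 = float(np.nanmean(y2))
        self.y2 = np.asarray(y2, float) - self.m2
        self.miss2 = np.flatnonzero(np.isnan(self.y2))
        self.y2[self.miss2] = 0.0
        self.logy1_sum = float(np.sum(np.log(y1)))
        # without covariates every likelihood term depends on the data only
        # through per-(z, d)-cell sums, making Metropolis evaluations O(1)
        self._fast = self.p0 == 1
        if self._fast:
            self._cell_index()
            self._cell_refresh()
        self._init_state()
        self.mh_alpha = _AdaptiveMVN(self.p0 + 1, 0.3)
        step = np.ones(self.p0 + 2)
        step[0] = 0.5  # tighter steps for the positive intercept
        self.mh_cost = _AdaptiveMVN(self.p0 + 2, 0.1, step_diag=step)
        self.mh_nu = _AdaptiveScale(0.15)
        self.mh_sig = _AdaptiveScale(0.15)

    def _init_state(self) -> None:
        rng = self.rng
        z, d, y1, y2 = self.z, self.d, self.y1, self.y2
        eps = 0.5 / self.n
        p1 = np.clip(d[z == 1].mean(), eps, 1 - eps)
        p0c = np.clip(d[z == 0].mean(), eps, 1 - eps)
        self.alpha = np.zeros(self.p0 + 1)
        self.alpha[0] = special.logit(p0c) + rng.normal(0, 0.2)
        self.alpha[-1] = special.logit(p1) - special.logit(p0c) + rng.normal(0, 0.2)
        den = max(p1 - p0c, 0.05)
        naive1 = (y1[z == 1].mean() - y1[z == 0].mean()) / den
        # cost coefficients: [b01, covariates..., b11, b1r]
        self.bcost = np.zeros(self.p0 + 2)
        self.bcost[0] = max(y1[d == 0].mean(), 0.05) * np.exp(rng.normal(0, 0.1))
        self.bcost[-2] = naive1 + rng.normal(0, 0.1)
        mu1 = self._mu1(self.alpha, self.bcost)
        v = float(np.var(y1))
        self.nu = max(float(np.mean(mu1) ** 2 / v), 0.2) * np.exp(rng.normal(0, 0.2))
        naive2 = (y2[z == 1].mean() - y2[z == 0].mean()) / den
        self.bq = np.zeros(self.p0 + 2)  # [a2 (incl. intercept), b12, b2r]
        self.bq[-2] = naive2 + rng.normal(0, 0.05)
        self.sig2 = float(np.std(y2)) * np.exp(rng.normal(0, 0.2)) + 1e-3
        r = float(np.corrcoef(y1, y2)[0, 1]) if self.n > 2 else 0.0
        self.zr = float(np.arctanh(np.clip(r, -0.9, 0.9)) + rng.normal(0, 0.1))

    # -------------------------------------------------- cell sufficient stats
    def _cell_index(self) -> None:
        cells = []
        for zv in (0.0, 1.0):
            for dv in (0.0, 1.0):
                idx = np.flatnonzero((self.z == zv) & (self.d == dv))
                if len(idx):
                    cells.append((zv, dv, idx))
        self._cells = cells
        self.cz = np.array([c[0] for c in cells])
        self.cd = np.array([c[1] for c in cells])
        # arm-level counts for the Bernoulli term
        self.n_arm = np.array([(self.z == 0).sum(), (self.z == 1).sum()], float)
        self.d_arm = np.array(
            [self.d[self.z == 0].sum(), self.d[self.z == 1].sum()], float
        )

    def _cell_refresh(self) -> None:
        """Per-cell sums of y1, y2 and their products (y2 can change under
        imputation; y1 is fixed)."""
        g = lambda f: np.array([f(c[2]) for c in self._cells])
        y1, y2 = self.y1, self.y2
        self.c_n = g(lambda i: float(len(i)))
        self.c_s1 = g(lambda i: y1[i].sum())
        self.c_s11 = g(lambda i: (y1[i] ** 2).sum())
        self.c_s2 = g(lambda i: y2[i].sum())
        self.c_s22 = g(lambda i: (y2[i] ** 2).sum())
        self.c_s12 = g(lambda i: (y1[i] * y2[i]).sum())

    def _cell_mu1_r(
        self, alpha: np.ndarray, bcost: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        pi = special.expit(alpha[0] + alpha[-1] * self.cz)
        r = self.cd - pi
        mu1 = bcost[0] + bcost[-2] * self.cd + bcost[-1] * r
        return mu1, r

    # ---------------------------------------------------------- likelihoods
    def _pi_r(self, alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lin = self.W @ alpha[:-1] + alpha[-1] * self.z
        pi = special.expit(lin)
        return pi, self.d - pi

    def _mu1(self, alpha: np.ndarray, bcost: np.ndarray) -> np.ndarray:
        _, r = self._pi_r(alpha)
        mu1 = bcost[0] + self.d * bcost[-2] + r * bcost[-1]
        if self.p0 > 1:
            mu1 = mu1 + self.xcov @ bcost[1:-2]
        return mu1

    def _ll_bern(self, alpha: np.ndarray) -> float:
        lin = self.W @ alpha[:-1] + alpha[-1] * self.z
        # log Bernoulli(pi) with logit link, numerically stable
        return float(np.sum(self.d * lin - np.logaddexp(0.0, lin)))

    def _ll_gamma(self, mu1: np.ndarray, nu: float) -> float:
        nut = nu + 0.01
        if np.any(mu1 <= 0.0) or nut <= 0.0:
            return -np.inf
        rate = nut / mu1
        return float(
            nut * np.sum(np.log(rate))
            - self.n * special.gammaln(nut)
            + (nut - 1.0) * self.logy1_sum
            - np.sum(rate * self.y1)
        )

    def _ll_norm2(
        self,
        mu1: np.ndarray,
        r: np.ndarray,
        bq: np.ndarray,
        nu: float,
        sig2: float,
        zr: float,
    ) -> float:
        rho = float(np.tanh(zr))
        s2c = sig2**2 * (1.0 - rho**2)
        sd1 = mu1 / np.sqrt(nu + 0.01)
        b22 = rho * sig2 / sd1
        mu2 = bq[0] + self.d * bq[-2] + r * bq[-1] + b22 * (self.y1 - mu1)
        if self.p0 > 1:
            mu2 = mu2 + self.xcov @ bq[1:-2]
        resid = self.y2 - mu2
        return float(-0.5 * self.n * np.log(s2c) - 0.5 * np.sum(resid**2) / s2c)

    def _loglik_fast(
        self,
        alpha: np.ndarray,
        bcost: np.ndarray,
        bq: np.ndarray,
        nu: float,
        sig2: float,
        zr: float,
    ) -> float:
        mu1, r = self._cell_mu1_r(alpha, bcost)
        if np.any(mu1 <= 0.0):
            return -np.inf
        nut = nu + 0.01
        lin = alpha[0] + alpha[-1] * np.array([0.0, 1.0])
        ll = float(self.d_arm @ lin - self.n_arm @ np.logaddexp(0.0, lin))
        ll += float(
            nut * np.sum(self.c_n * (np.log(nut) - np.log(mu1)))
            - nut * np.sum(self.c_s1 / mu1)
            + (nut - 1.0) * self.logy1_sum
            - self.n * special.gammaln(nut)
        )
        rho = float(np.tanh(zr))
        s2c = sig2**2 * (1.0 - rho**2)
        B = rho * sig2 * np.sqrt(nut) / mu1
        A = bq[0] + bq[-2] * self.cd + bq[-1] * r - B * mu1
        ssr = float(
            np.sum(
                self.c_s22
                - 2.0 * A * self.c_s2
                - 2.0 * B * self.c_s12
                + A * A * self.c_n
                + 2.0 * A * B * self.c_s1
                + B * B * self.c_s11
            )
        )
        return ll - 0.5 * self.n * np.log(s2c) - 0.5 * ssr / s2c

    def _logpost(
        self,
        alpha: np.ndarray,
        bcost: np.ndarray,
        bq: np.ndarray,
        lognu: float,
        logsig2: float,
        zr: float,
    ) -> float:
        nu = float(np.exp(lognu))
        sig2 = float(np.exp(logsig2))
        if sig2 >= _SIGMA_MAX:
            return -np.inf
        b01 = bcost[0]
        if b01 <= 0.0:
            return -np.inf
        if self._fast:
            lp = self._loglik_fast(alpha, bcost, bq, nu, sig2, zr)
        else:
            mu1 = self._mu1(alpha, bcost)
            if np.any(mu1 <= 0.0):
                return -np.inf
            _, r = self._pi_r(alpha)
            lp = (
                self._ll_bern(alpha)
                + self._ll_gamma(mu1, nu)
                + self._ll_norm2(mu1, r, bq, nu, sig2, zr)
            )
        if not np.isfinite(lp):
            return -np.inf
        # priors
        lp += -0.5 * _COEF_PREC * float(alpha @ alpha)
        lp += (0.01 - 1.0) * np.log(b01) - 0.01 * b01  # gamma(0.01, 0.01) on b01
        rest = np.concatenate([bcost[1:], bq])
        lp += -0.5 * _COEF_PREC * float(rest @ rest)
        lp += 0.01 * lognu - 0.01 * nu  # gamma(0.01, 0.01) on nu, log-scale Jacobian
        lp += logsig2  # U(0,10) on sigma2, log-scale Jacobian
        lp += -0.5 * _Z_PREC * zr**2
        return lp

    # -------------------------------------------------------------- updates
    def _sweep(self, adapt: bool) -> None:
        rng = self.rng
        if len(self.miss2):
            # impute missing QALYs from their conditional normal
            _, r = self._pi_r(self.alpha)
            mu1 = self._mu1(self.alpha, self.bcost)
            rho = float(np.tanh(self.zr))
            s2c = self.sig2**2 * (1.0 - rho**2)
            sd1 = mu1 / np.sqrt(self.nu + 0.01)
            b22 = rho * self.sig2 / sd1
            mu2 = (
                self.bq[0]
                + self.d * self.bq[-2]
                + r * self.bq[-1]
                + b22 * (self.y1 - mu1)
            )
            if self.p0 > 1:
                mu2 = mu2 + self.xcov @ self.bq[1:-2]
            i = self.miss2
            self.y2[i] = mu2[i] + rng.standard_normal(len(i)) * np.sqrt(s2c)
            if self._fast:
                self._cell_refresh()

        lognu, logsig2 = float(np.log(self.nu)), float(np.log(self.sig2))
        lp = self._logpost(self.alpha, self.bcost, self.bq, lognu, logsig2, self.zr)

        # --- first-stage block
        prop = self.mh_alpha.propose(self.alpha, rng)
        lp_p = self._logpost(prop, self.bcost, self.bq, lognu, logsig2, self.zr)
        acc = np.log(rng.random()) < lp_p - lp
        if acc:
            self.alpha, lp = prop, lp_p
        self.mh_alpha.update(bool(acc), adapt)
        self.mh_alpha.observe(self.alpha, adapt)

        # --- cost-equation block (intercept kept positive by the prior)
        prop = self.mh_cost.propose(self.bcost, rng)
        lp_p = self._logpost(self.alpha, prop, self.bq, lognu, logsig2, self.zr)
        acc = np.log(rng.random()) < lp_p - lp
        if acc:
            self.bcost, lp = prop, lp_p
        self.mh_cost.update(bool(acc), adapt)
        self.mh_cost.observe(self.bcost, adapt)

        # --- shape parameter on the log scale
        prop_lognu = lognu + self.mh_nu.scale * rng.standard_normal()
        lp_p = self._logpost(
            self.alpha, self.bcost, self.bq, prop_lognu, logsig2, self.zr
        )
        acc = np.log(rng.random()) < lp_p - lp
        if acc:
            lognu, lp = float(prop_lognu), lp_p
            self.nu = float(np.exp(lognu))
        self.mh_nu.update(bool(acc), adapt)

        # --- QALY-equation block: conjugate given everything else
        rho = float(np.tanh(self.zr))
        s2c = self.sig2**2 * (1.0 - rho**2)
        nut = self.nu + 0.01
        if self._fast:
            mu1c, rc = self._cell_mu1_r(self.alpha, self.bcost)
            B = rho * self.sig2 * np.sqrt(nut) / mu1c
            hc = np.column_stack([np.ones(len(mu1c)), self.cd, rc])
            HtH = (hc * self.c_n[:, None]).T @ hc
            tsum = self.c_s2 - B * self.c_s1 + B * mu1c * self.c_n
            P = _COEF_PREC * np.eye(3) + HtH / s2c
            self.bq = _draw_mvn(P, hc.T @ tsum / s2c, rng)
        else:
            _, r = self._pi_r(self.alpha)
            mu1 = self._mu1(self.alpha, self.bcost)
            sd1 = mu1 / np.sqrt(nut)
            offset = rho * self.sig2 / sd1 * (self.y1 - mu1)
            cols = [np.ones(self.n)]
            if self.p0 > 1:
                cols.append(self.xcov)
            cols += [self.d, r]
            H = np.column_stack(cols)
            t = self.y2 - offset
            P = _COEF_PREC * np.eye(H.shape[1]) + H.T @ H / s2c
            self.bq = _draw_mvn(P, H.T @ t / s2c, rng)
        lp = self._logpost(self.alpha, self.bcost, self.bq, lognu, logsig2, self.zr)

        # --- (z, log sigma2) block
        prop = np.array([self.zr, logsig2]) + self.mh_sig.scale * rng.standard_normal(2)
        lp_p = self._logpost(
            self.alpha, self.bcost, self.bq, lognu, prop[1], prop[0]
        )
        acc = np.log(rng.random()) < lp_p - lp
        if acc:
            self.zr, logsig2 = float(prop[0]), float(prop[1])
            self.sig2 = float(np.exp(logsig2))
        self.mh_sig.update(bool(acc), adapt)

    def _record(self) -> dict[str, float]:
        return {
            "beta_cost": float(self.bcost[-2]),
            "beta_qaly": float(self.bq[-2]),
            "beta_cost_resid": float(self.bcost[-1]),
            "beta_qaly_resid": float(self.bq[-1]),
            "alpha0": float(self.alpha[0]),
            "alpha1": float(self.alpha[-1]),
            "beta01": float(self.bcost[0]),
            "beta02": float(self.bq[0] + self.m2),
            "rho": float(np.tanh(self.zr)),
            "z_rho": float(self.zr),
            "sigma2": self.sig2,
            "nu": self.nu,
        }

    def run(self, n_iter: int, adapt: bool = False) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {}
        for _ in range(n_iter):
            self._sweep(adapt)
            for k, v in self._record().items():
                out.setdefault(k, []).append(v)
        return {k: np.asarray(v) for k, v in out.items()}
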
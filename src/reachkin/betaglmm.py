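"""Beta mixed-effects regression with a logit link.

The response is a continuous proportion on (0, 1) (rescaled TPV%), modelled
as Beta(mu·phi, (1-mu)·phi) with logit(mu) = X·beta + b, where b is a
participant-level random intercept, b ~ N(0, sigma_b²).  The marginal
likelihood integrates b out per participant with *adaptive* Gauss–Hermite
quadrature: the integrand's mode and curvature are found by Newton iteration
and the Hermite nodes are centred and scaled there, which keeps a modest
node count accurate even for small per-participant trial counts.

The model ladder mirrors the candidate set of the analysis this package
reproduces:

===== =======================================================
name  fixed effects (random intercept by participant always)
===== =======================================================
mb0   intercept only
mb1   condition
mb2   condition + StimulusRandomTime
mb3   condition × StimulusRandomTime (main effects + interaction)
===== =======================================================

The reported parameter count k = #fixed coefficients + 1 (random-intercept
SD) + 1 (dispersion), i.e. 3, 4, 5, 6 across the ladder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import betaln, digamma, expit, logit, polygamma
from scipy.special import logsumexp

MODEL_NAMES = ("mb0", "mb1", "mb2", "mb3")

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """One rung of the nested fixed-effect ladder."""

    name: str

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")

    @property
    def terms(self) -> tuple:
        return {
            "mb0": ("intercept",),
            "mb1": ("intercept", "condition"),
            "mb2": ("intercept", "condition", "srt_z"),
            "mb3": ("intercept", "condition", "srt_z", "condition:srt_z"),
        }[self.name]

    @property
    def k(self) -> int:
        # fixed coefficients + random-intercept SD + dispersion
        return len(self.terms) + 2


def model_ladder() -> list[ModelSpec]:
    return [ModelSpec(n) for n in MODEL_NAMES]


@dataclass
class ModelFit:
    """A fitted beta mixed model and its information-criterion bookkeeping."""

    spec: ModelSpec
    beta: np.ndarray
    beta_names: tuple
    sigma_b: float
    phi: float
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    beta_se: np.ndarray | None = None
    srt_center: float = 0.0
    srt_scale: float = 1.0

    @property
    def name(self) -> str:
        return self.spec.name

    def wald_table(self) -> pd.DataFrame:
        """Wald z statistics and two-sided p-values for the fixed effects."""
        from scipy.stats import norm

        se = self.beta_se if self.beta_se is not None else np.full_like(self.beta, np.nan)
        z = self.beta / se
        return pd.DataFrame(dict(term=self.beta_names, estimate=self.beta,
                                 se=se, z=z, p=2 * norm.sf(np.abs(z))))


class _FitData:
    """Rows sorted by participant, with reduceat indices for group sums."""

    def __init__(self, table: pd.DataFrame, spec: ModelSpec,
                 srt_center: float | None = None, srt_scale: float | None = None):
        required = {"participant", "condition", "srt_ms", "tpv"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"trial table missing columns {sorted(missing)}")
        t = table.sort_values("participant", kind="stable").reset_index(drop=True)
        y = t["tpv"].to_numpy(dtype=float)
        if np.any((y <= 0) | (y >= 1)):
            bad = t.index[(y <= 0) | (y >= 1)].tolist()[:5]
            raise ValueError(f"TPV values outside (0,1) at rows {bad}")
        codes, uniques = pd.factorize(t["participant"], sort=True)
        if len(uniques) < 2:
            raise ValueError("need at least two participants")
        self.y = y
        self.logit_y = logit(y)
        self.group_idx = codes
        self.n_groups = len(uniques)
        self.groups = list(uniques)
        self.starts = np.searchsorted(codes, np.arange(self.n_groups))
        srt = t["srt_ms"].to_numpy(dtype=float)
        self.srt_center = float(np.mean(srt)) if srt_center is None else srt_center
        sd = float(np.std(srt, ddof=1)) if srt_scale is None else srt_scale
        self.srt_scale = sd if sd > 0 else 1.0
        z = (srt - self.srt_center) / self.srt_scale
        nd = (t["condition"].to_numpy() == "non-dominant").astype(float)
        cols = {"intercept": np.ones_like(y), "condition": nd,
                "srt_z": z, "condition:srt_z": nd * z}
        self.X = np.column_stack([cols[term] for term in spec.terms])
        self.spec = spec


def _beta_logpdf(y, mu, phi):
    a = mu * phi
    b = (1.0 - mu) * phi
    return (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y) - betaln(a, b)


def _find_modes(eta0, data: _FitData, sigma: float, phi: float,
                b0: np.ndarray | None = None, tol: float = 1e-11,
                max_iter: int = 60):
    """Per-participant mode and curvature of the joint log-density in b."""
    b = np.zeros(data.n_groups) if b0 is None else b0.copy()
    inv_s2 = 1.0 / sigma**2
    h = None
    for _ in range(max_iter):
        eta = eta0 + b[data.group_idx]
        mu = expit(eta)
        w = mu * (1.0 - mu)
        a1 = mu * phi
        a2 = (1.0 - mu) * phi
        d = data.logit_y - digamma(a1) + digamma(a2)
        g_obs = phi * d * w
        h_obs = (-(phi**2) * (polygamma(1, a1) + polygamma(1, a2)) * w**2
                 + phi * d * w * (1.0 - 2.0 * mu))
        g = np.add.reduceat(g_obs, data.starts) - b * inv_s2
        h = np.add.reduceat(h_obs, data.starts) - inv_s2
        h = np.minimum(h, -1e-10)
        step = np.clip(g / h, -1.0, 1.0)
        b = b - step
        if np.max(np.abs(step)) < tol:
            break
    # recompute curvature at the final iterate
    eta = eta0 + b[data.group_idx]
    mu = expit(eta)
    w = mu * (1.0 - mu)
    a1 = mu * phi
    a2 = (1.0 - mu) * phi
    d = data.logit_y - digamma(a1) + digamma(a2)
    h_obs = (-(phi**2) * (polygamma(1, a1) + polygamma(1, a2)) * w**2
             + phi * d * w * (1.0 - 2.0 * mu))
    h = np.add.reduceat(h_obs, data.starts) - inv_s2
    h = np.minimum(h, -1e-10)
    return b, -h


def _marginal_loglik(beta, sigma, phi, data: _FitData, order: int = 15,
                     b_start: np.ndarray | None = None):
    """Total marginal log-likelihood; also returns the modes for warm starts."""
    eta0 = data.X @ beta
    if sigma < 1e-8:
        mu = expit(eta0)
        return float(np.sum(_beta_logpdf(data.y, mu, phi))), None
    b_hat, curv = _find_modes(eta0, data, sigma, phi, b0=b_start)
    s = 1.0 / np.sqrt(curv)
    x, wq = hermgauss(order)
    bk = b_hat[:, None] + math.sqrt(2.0) * s[:, None] * x[None, :]
    eta = eta0[:, None] + bk[data.group_idx, :]
    mu = expit(eta)
    a1 = mu * phi
    a2 = (1.0 - mu) * phi
    ll_obs = ((a1 - 1.0) * np.log(data.y)[:, None]
              + (a2 - 1.0) * np.log1p(-data.y)[:, None]
              - betaln(a1, a2))
    ll_grp = np.add.reduceat(ll_obs, data.starts, axis=0)
    log_prior = -0.5 * (bk / sigma) ** 2 - math.log(sigma) - _LOG_SQRT_2PI
    log_joint = ll_grp + log_prior
    log_int = logsumexp(np.log(wq)[None, :] + x[None, :] ** 2 + log_joint, axis=1)
    log_int = log_int + np.log(math.sqrt(2.0) * s)
    return float(np.sum(log_int)), b_hat


def beta_glmm_loglik(beta, sigma_b: float, phi: float, table: pd.DataFrame,
                     spec: ModelSpec | str = "mb1", order: int = 15,
                     srt_center: float | None = None,
                     srt_scale: float | None = None) -> float:
    """Marginal log-likelihood of a parameter triple on a trial table."""
    if phi <= 0:
        raise ValueError("phi must be positive")
    if sigma_b < 0:
        raise ValueError("sigma_b must be non-negative")
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    data = _FitData(table, spec, srt_center, srt_scale)
    beta = np.asarray(beta, dtype=float)
    if beta.size != data.X.shape[1]:
        raise ValueError(f"{spec.name} expects {data.X.shape[1]} coefficients")
    ll, _ = _marginal_loglik(beta, sigma_b, phi, data, order)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite marginal log-likelihood")
    return ll


def _starting_values(data: _FitData):
    z = np.clip(data.logit_y, -6, 6)
    beta0, *_ = np.linalg.lstsq(data.X, z, rcond=None)
    resid = z - data.X @ beta0
    group_means = np.array([resid[data.group_idx == g].mean()
                            for g in range(data.n_groups)])
    sigma0 = float(np.clip(np.std(group_means, ddof=1), 0.02, 2.0))
    mu0 = expit(data.X @ beta0)
    var_y = float(np.var(data.y - mu0))
    phi0 = float(np.clip(np.mean(mu0 * (1 - mu0)) / max(var_y, 1e-6) - 1.0, 2.0, 300.0))
    return beta0, sigma0, phi0


def fit_model(spec: ModelSpec | str, table: pd.DataFrame, order: int = 15,
              compute_cov: bool = True, extra_starts: bool = True) -> ModelFit:
    """Maximize the marginal likelihood of one model on a trial table.

    Optimizes (beta, log sigma_b, log phi) with L-BFGS-B from a
    moment-matched start and, optionally, a near-zero sigma_b start; the
    participant modes are cached between objective evaluations so the inner
    Newton iteration warms up quickly.
    """
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    data = _FitData(table, spec)
    p = data.X.shape[1]
    n = data.y.size
    beta0, sigma0, phi0 = _starting_values(data)

    cache = {"b": None}

    def nll(theta):
        beta = theta[:p]
        sigma = math.exp(theta[p])
        phi = math.exp(theta[p + 1])
        ll, b_hat = _marginal_loglik(beta, sigma, phi, data, order,
                                     b_start=cache["b"])
        if b_hat is not None:
            cache["b"] = b_hat
        if not np.isfinite(ll):
            return 1e12
        return -ll

    bounds = [(None, None)] * p + [(math.log(1e-3), math.log(3.0)),
                                   (math.log(0.5), math.log(5e4))]
    starts = [np.concatenate([beta0, [math.log(sigma0), math.log(phi0)]])]
    if extra_starts:
        starts.append(np.concatenate([beta0, [math.log(0.02), math.log(phi0)]]))

    best = None
    for th0 in starts:
        cache["b"] = None
        res = minimize(nll, th0, method="L-BFGS-B", bounds=bounds,
                       options=dict(maxiter=300, ftol=1e-11, gtol=1e-8))
        if best is None or res.fun < best.fun:
            best = res

    theta = best.x
    beta = theta[:p]
    sigma = math.exp(theta[p])
    phi = math.exp(theta[p + 1])
    loglik = -best.fun

    beta_se = None
    if compute_cov:
        H = _numeric_hessian(nll, theta)
        try:
            cov = np.linalg.inv(H)
            se2 = np.diag(cov)[:p]
            beta_se = np.sqrt(np.where(se2 > 0, se2, np.nan))
        except np.linalg.LinAlgError:
            beta_se = np.full(p, np.nan)

    k = spec.k
    aicc_val = -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    return ModelFit(spec=spec, beta=beta, beta_names=spec.terms,
                    sigma_b=sigma, phi=phi, loglik=loglik, k=k, n=n,
                    aicc=aicc_val, converged=bool(best.success),
                    beta_se=beta_se,
                    srt_center=data.srt_center, srt_scale=data.srt_scale)


def fit_ladder(table: pd.DataFrame, order: int = 15, compute_cov: bool = False,
               extra_starts: bool = True) -> list[ModelFit]:
    """Fit mb0 → mb3 on the same table."""
    return [fit_model(s, table, order=order, compute_cov=compute_cov,
                      extra_starts=extra_starts) for s in model_ladder()]


def _numeric_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
    return H
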
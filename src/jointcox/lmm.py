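"""Maximum-likelihood linear mixed model with random intercept and slope.

The longitudinal submodel is ``y_ij = beta0 + beta1 * t_ij + b0_i + b1_i *
t_ij + eps_ij`` with (b0, b1) ~ N(0, D) and eps ~ N(0, sigma2).  The
marginal Gaussian likelihood is maximized directly (ML, not REML) over a
log-Cholesky parameterization of D, with the fixed effects profiled out in
closed form.  Because both design matrices are (1, t) the per-subject
likelihood depends on the data only through six sufficient statistics, so
evaluation is O(n_subjects) regardless of visit counts.

Time enters the optimizer in units of 100 days so that intercept- and
slope-type parameters are comparably scaled; all reported values are on the
day scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["LmmFit", "fit_lmm", "eb_modes", "lmm_loglik_direct"]

TSCALE = 100.0  # days per internal time unit


@dataclass
class SubjectStats:
    """Sufficient statistics of one subject's visits on the internal scale."""

    n: int
    St: float
    Stt: float
    Sy: float
    Sty: float
    Syy: float

    @classmethod
    def from_visits(cls, days: np.ndarray, values: np.ndarray) -> "SubjectStats":
        t = np.asarray(days, dtype=float) / TSCALE
        y = np.asarray(values, dtype=float)
        return cls(
            n=len(t),
            St=float(t.sum()),
            Stt=float((t * t).sum()),
            Sy=float(y.sum()),
            Sty=float((t * y).sum()),
            Syy=float((y * y).sum()),
        )


@dataclass
class LmmFit:
    """ML fit of the random intercept/slope model, on the day scale."""

    beta: np.ndarray  # (intercept, slope per day)
    D_hat: np.ndarray  # 2x2, day scale
    sigma2_hat: float
    loglik: float
    converged: bool
    n_subjects: int
    subject_ids: list
    eb_modes_: np.ndarray  # (n, 2) posterior modes of (b0, b1), day scale
    eb_covs_: np.ndarray  # (n, 2, 2) conditional covariances, day scale


def _stack_stats(stats: list[SubjectStats]):
    n = np.array([s.n for s in stats], dtype=float)
    G = np.empty((len(stats), 2, 2))
    G[:, 0, 0] = n
    G[:, 0, 1] = G[:, 1, 0] = [s.St for s in stats]
    G[:, 1, 1] = [s.Stt for s in stats]
    q = np.column_stack([[s.Sy for s in stats], [s.Sty for s in stats]])
    syy = np.array([s.Syy for s in stats])
    return n, G, q, syy


def _inv2(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse and log-determinant of a stack of 2x2 matrices."""
    det = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    inv = np.empty_like(A)
    inv[..., 0, 0] = A[..., 1, 1]
    inv[..., 1, 1] = A[..., 0, 0]
    inv[..., 0, 1] = -A[..., 0, 1]
    inv[..., 1, 0] = -A[..., 1, 0]
    return inv / det[..., None, None], np.log(det)


def _theta_to_D(theta: np.ndarray) -> np.ndarray:
    L = np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])
    return L @ L.T


def _profiled_negloglik(theta, n, G, q, syy, return_beta=False):
    # extreme parameter values explored by the optimizer can overflow the
    # 2x2 determinants; the resulting non-finite objective is guarded below
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        return _profiled_negloglik_inner(theta, n, G, q, syy, return_beta)


def _profiled_negloglik_inner(theta, n, G, q, syy, return_beta):
    D = _theta_to_D(theta[:3])
    sigma2 = np.exp(theta[3])
    Dinv, logdetD = _inv2(D[None])
    Dinv = Dinv[0]
    K = Dinv[None] + G / sigma2
    M, logdetK = _inv2(K)
    # log|V| = log|I + G D / sigma2| + n log sigma2 = log|K| + log|D| + n log s2
    logdetV = logdetK + logdetD + n * np.log(sigma2)

    GM = G @ M
    # X'V^-1 X and X'V^-1 y via Woodbury (X = Z here)
    XtVX = (G - GM @ G / sigma2) / sigma2
    XtVy = (q[:, None, :] @ np.swapaxes(G / sigma2 @ M, 1, 2)).squeeze(1)
    XtVy = (q - XtVy) / sigma2
    ytVy = (syy - np.einsum("ni,nij,nj->n", q, M, q) / sigma2) / sigma2

    A = XtVX.sum(axis=0)
    c = XtVy.sum(axis=0)
    try:
        beta = np.linalg.solve(A, c)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(A, c, rcond=None)
    if not np.all(np.isfinite(beta)):
        return (1e12, np.zeros(2), M) if return_beta else 1e12
    quad = ytVy.sum() - 2 * c @ beta + beta @ A @ beta
    nll = 0.5 * (n.sum() * np.log(2 * np.pi) + logdetV.sum() + quad)
    if not np.isfinite(nll):
        nll = 1e12
    if return_beta:
        return nll, beta, M
    return nll


def fit_lmm(data: pd.DataFrame, *, subject_col: str = "subject_id",
            day_col: str = "day", value_col: str = "value") -> LmmFit:
    """Fit the random intercept/slope LMM by maximum likelihood.

    ``data`` is a long-format table with one row per visit.  When no subject
    has two or more visits the random slope is unidentified and the fit
    falls back to (numerically) random-intercept-only with a warning.
    """
    groups = data.groupby(subject_col, sort=True)
    subject_ids = list(groups.groups)
    stats = [
        SubjectStats.from_visits(g[day_col].to_numpy(), g[value_col].to_numpy())
        for _, g in groups
    ]
    n, G, q, syy = _stack_stats(stats)

    slope_identified = max(s.n for s in stats) >= 2
    if not slope_identified:
        warnings.warn(
            "no subject has repeated visits: random slope unidentified, "
            "fitting random-intercept-only",
            stacklevel=2,
        )

    # moment starts: spread of per-subject OLS lines approximates D, their
    # residual variance approximates sigma2, pooled OLS gives beta
    t_all = data[day_col].to_numpy() / TSCALE
    y_all = data[value_col].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(t_all), t_all])
    beta_start, *_ = np.linalg.lstsq(X, y_all, rcond=None)
    resid_var = max(np.var(y_all - X @ beta_start), 1e-8)
    lines, ssrs = [], []
    for s in stats:
        Gi = np.array([[s.n, s.St], [s.St, s.Stt]])
        if s.n >= 3 and np.linalg.det(Gi) > 1e-10:
            coef = np.linalg.solve(Gi, [s.Sy, s.Sty])
            lines.append(coef)
            ssrs.append(max(s.Syy - coef @ [s.Sy, s.Sty], 0.0) / (s.n - 2))
    if len(lines) >= 10:
        sig0 = float(np.clip(np.mean(ssrs), 1e-6, None))
        Dm = np.cov(np.array(lines).T)
        v0 = float(np.clip(Dm[0, 0] - 0.5 * sig0, 1e-4, None))
        v1 = float(np.clip(Dm[1, 1], 1e-6, None))
        x0 = np.array([0.5 * np.log(v0), 0.0, 0.5 * np.log(v1), np.log(sig0)])
    else:
        x0 = np.array([
            0.5 * np.log(resid_var / 2), 0.0,
            0.5 * np.log(resid_var / 8) if slope_identified else np.log(1e-4),
            np.log(resid_var / 2)])

    if slope_identified:
        obj = lambda th: _profiled_negloglik(th, n, G, q, syy)
        free = np.arange(4)
    else:
        # freeze slope variance and covariance near zero
        def obj(th_free):
            th = np.array([th_free[0], 0.0, np.log(1e-6), th_free[1]])
            return _profiled_negloglik(th, n, G, q, syy)
        free = np.array([0, 3])
        x0 = x0[free]

    # bounds keep exp() parameters inside floating range; they are far
    # wider than any plausible variance on the day scale
    bounds = ([(-18.0, 18.0), (-1e4, 1e4), (-18.0, 18.0), (-18.0, 18.0)]
              if slope_identified else [(-18.0, 18.0), (-18.0, 18.0)])
    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    theta = res.x if slope_identified else np.array(
        [res.x[0], 0.0, np.log(1e-6), res.x[1]])

    nll, beta_s, M = _profiled_negloglik(theta, n, G, q, syy, return_beta=True)
    D_s = _theta_to_D(theta[:3])
    sigma2 = float(np.exp(theta[3]))

    # empirical Bayes modes: mu_i = M_i Z'(y - X beta)/sigma2
    r0 = q - G @ beta_s
    modes_s = np.einsum("nij,nj->ni", M, r0) / sigma2

    # convert internal (per-100-days) scale to day scale
    S = np.diag([1.0, 1.0 / TSCALE])
    beta = S @ beta_s
    D = S @ D_s @ S.T
    modes = modes_s @ S.T
    covs = S[None] @ M @ S.T[None]

    return LmmFit(
        beta=beta,
        D_hat=D,
        sigma2_hat=sigma2,
        loglik=float(-nll),
        converged=bool(res.success),
        n_subjects=len(stats),
        subject_ids=subject_ids,
        eb_modes_=modes,
        eb_covs_=covs,
    )


def eb_modes(fit: LmmFit, days: np.ndarray, values: np.ndarray,
             beta: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and covariance of (b0, b1) for one subject's data.

    The LMM posterior of the random effects given the subject's visits is
    Gaussian, so the mode is the conditional mean ``(D^-1 + Z'Z/s2)^-1
    Z'(y - X beta)/s2`` and the curvature is ``(D^-1 + Z'Z/s2)^-1``; both are
    returned on the day scale.  An empty visit vector returns the prior.
    """
    beta = fit.beta if beta is None else np.asarray(beta, dtype=float)
    t = np.asarray(days, dtype=float)
    y = np.asarray(values, dtype=float)
    Z = np.column_stack([np.ones_like(t), t])
    Dinv = np.linalg.inv(fit.D_hat)
    K = Dinv + Z.T @ Z / fit.sigma2_hat
    cov = np.linalg.inv(K)
    mode = cov @ (Z.T @ (y - Z @ beta)) / fit.sigma2_hat
    return mode, cov


def lmm_loglik_direct(data: pd.DataFrame, beta, D, sigma2, *,
                      subject_col: str = "subject_id", day_col: str = "day",
                      value_col: str = "value") -> float:
    """Marginal Gaussian log-likelihood by direct MVN evaluation.

    Builds each subject's full marginal covariance Z D Z' + sigma2 I and
    sums multivariate-normal log-densities; O(sum n_i^3), intended for
    cross-checks and small problems.
    """
    from scipy.stats import multivariate_normal

    beta = np.asarray(beta, dtype=float)
    D = np.asarray(D, dtype=float)
    total = 0.0
    for _, g in data.groupby(subject_col):
        t = g[day_col].to_numpy(dtype=float)
        y = g[value_col].to_numpy(dtype=float)
        Z = np.column_stack([np.ones_like(t), t])
        V = Z @ D @ Z.T + sigma2 * np.eye(len(t))
        total += multivariate_normal.logpdf(y, mean=Z @ beta, cov=V)
    return float(total)
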
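"""Shared-random-effects joint model for longitudinal + time-to-event data.

The hazard for subject i is ``h_i(t) = h0(t) exp(gamma*u_i + alpha*m_i(t))``
where ``m_i(t) = beta0 + beta1*t + b0_i + b1_i*t`` is the latent value of
the longitudinal predictor (current-value association) and u_i a binary
group covariate.  The longitudinal observations are ``y_ij = m_i(t_ij) +
eps_ij`` with eps ~ N(0, sigma2) and (b0, b1) ~ N(0, D).  The marginal
likelihood integrates the product of the two conditional likelihoods over
the bivariate random effects with 2-D Gauss-Hermite quadrature; by default
the rule is pseudo-adaptive: nodes are shifted and scaled per subject by
the empirical Bayes mode and curvature of a preliminary linear-mixed-model
fit, which makes a modest node count accurate.

The baseline hazard h0 is either Weibull, ``h0(t) = exp(eta)*k*t^(k-1)``
(cumulative hazard integrated by fixed-order Gauss-Legendre panels because
the product with exp(alpha*m(t)) has no closed form), or piecewise constant
on intervals delimited by event-time quantiles, whose cumulative hazard has
a closed form since m is linear in t.

The quadrature-approximated log-likelihood is maximized by quasi-Newton
(L-BFGS-B) with an analytic gradient: since the nodes are fixed, the exact
gradient of the approximation is the posterior-node-weighted average of the
complete-data score.  Standard errors come from a central-difference
observed-information matrix at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp, roots_hermite, roots_legendre

from .lmm import TSCALE, LmmFit, fit_lmm

__all__ = [
    "JointSpec",
    "JointParams",
    "JointFit",
    "WeibullBaseline",
    "PiecewiseBaseline",
    "conditional_survival_loglik",
    "subject_marginal_loglik",
    "fit_joint",
]

ASCALE = 10.0  # internal rescaling of the association coefficient
_EXP_CAP = 700.0


@dataclass(frozen=True)
class JointSpec:
    """Estimation settings for the joint model."""

    baseline: Literal["weibull", "piecewise_constant"] = "weibull"
    n_intervals: int = 6
    gh_points: int = 9
    pseudo_adaptive: bool = True
    max_iter: int = 200
    tol: float = 1e-8
    gl_panels: int = 15
    gl_points: int = 5

    def __post_init__(self) -> None:
        if self.gh_points < 3:
            raise ValueError("gh_points must be >= 3")
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")


@dataclass(frozen=True)
class WeibullBaseline:
    """h0(t) = exp(log_scale) * shape * t^(shape-1); H0(t) = exp(log_scale)*t^shape."""

    shape: float
    log_scale: float


@dataclass(frozen=True)
class PiecewiseBaseline:
    """Piecewise-constant h0 with interior knots; last interval is unbounded."""

    knots: np.ndarray  # interior knots, increasing, first interval starts at 0
    log_hazards: np.ndarray  # one per interval, len(knots) + 1

    def interval_of(self, t) -> np.ndarray:
        return np.searchsorted(self.knots, np.asarray(t, dtype=float), side="left")


@dataclass
class JointParams:
    """Joint-model parameters on the natural (day) scale."""

    beta: np.ndarray  # (intercept, slope per day)
    sigma2: float
    D: np.ndarray  # 2x2 random-effects covariance, day scale
    alpha: float  # association of the hazard with m(t)
    gamma: float  # group log-hazard ratio
    baseline: WeibullBaseline | PiecewiseBaseline


@dataclass
class JointFit:
    """Result of a maximum-likelihood joint-model fit."""

    params: JointParams
    se_alpha: float
    se_gamma: float
    loglik: float
    converged: bool
    n_iter: int
    spec: JointSpec

    @property
    def alpha(self) -> float:
        return self.params.alpha

    @property
    def gamma(self) -> float:
        return self.params.gamma

    def ci_alpha(self, z: float = 1.959963984540054) -> tuple[float, float]:
        return (self.alpha - z * self.se_alpha, self.alpha + z * self.se_alpha)

    def ci_gamma(self, z: float = 1.959963984540054) -> tuple[float, float]:
        return (self.gamma - z * self.se_gamma, self.gamma + z * self.se_gamma)


# ---------------------------------------------------------------------------
# small numerical helpers


def _phi(x: np.ndarray) -> np.ndarray:
    """expm1(x)/x with the x -> 0 limit; equals int_0^1 exp(x*u) du."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-8
    xs = np.where(small, 1.0, x)
    return np.where(small, 1.0 + x / 2.0, np.expm1(xs) / xs)


def _psi(x: np.ndarray) -> np.ndarray:
    """int_0^1 u*exp(x*u) du = (exp(x)*(x-1)+1)/x^2 with the x -> 0 limit."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    exact = (np.exp(xs) * (xs - 1.0) + 1.0) / xs**2
    series = 0.5 + x / 3.0 + x**2 / 8.0
    return np.where(small, series, exact)


def _gl_rule(panels: int, points: int) -> tuple[np.ndarray, np.ndarray]:
    """Composite Gauss-Legendre nodes/weights on [0, 1].

    The rule is applied after the cubic substitution s = v^3, which removes
    the algebraic endpoint singularity of the Weibull hazard t^(shape-1)
    for every shape > 1/3 while keeping the nodes fixed (so quadrature
    points never move during optimization).
    """
    x, w = roots_legendre(points)
    edges = np.linspace(0.0, 1.0, panels + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    half = 0.5 * np.diff(edges)
    v = (mid[:, None] + half[:, None] * x[None, :]).ravel()
    wv = (half[:, None] * w[None, :]).ravel()
    return v**3, 3.0 * v**2 * wv


def _gh_grid(points: int) -> tuple[np.ndarray, np.ndarray]:
    """2-D tensor Gauss-Hermite grid: z nodes (Q, 2) and log-weights (Q,)."""
    z, w = roots_hermite(points)
    z1, z2 = np.meshgrid(z, z, indexing="ij")
    Z = np.column_stack([z1.ravel(), z2.ravel()])
    logW = np.add.outer(np.log(w), np.log(w)).ravel()
    return Z, logW


# ---------------------------------------------------------------------------
# single-subject reference computations (used by tests and small fixtures)


def _m_of(params: JointParams, b: tuple[float, float], t):
    t = np.asarray(t, dtype=float)
    return params.beta[0] + params.beta[1] * t + b[0] + b[1] * t


def conditional_survival_loglik(
    params: JointParams,
    T: float,
    delta: int,
    u: int,
    b: tuple[float, float],
    *,
    gl_panels: int = 15,
    gl_points: int = 5,
) -> float:
    """Survival log-likelihood of one subject given its random effects.

    Returns ``delta*log h(T|b) - int_0^T h(s|b) ds``.  The cumulative hazard
    is closed-form for a piecewise-constant baseline (the integrand is
    c*exp(d*s) on each interval) and composite Gauss-Legendre for Weibull.
    """
    base = params.baseline
    c0 = params.gamma * u + params.alpha * (params.beta[0] + b[0])
    d = params.alpha * (params.beta[1] + b[1])
    if isinstance(base, PiecewiseBaseline):
        knots = np.concatenate([[0.0], np.asarray(base.knots, dtype=float), [np.inf]])
        a = np.minimum(knots[:-1], T)
        c = np.minimum(knots[1:], T)
        dl = np.maximum(c - a, 0.0)
        cum = np.sum(
            np.exp(np.asarray(base.log_hazards) + c0 + d * a) * dl * _phi(d * dl)
        )
        logh = base.log_hazards[int(base.interval_of(T))] + c0 + d * T
    elif isinstance(base, WeibullBaseline):
        x, w = _gl_rule(gl_panels, gl_points)
        s = T * x
        logh_s = (
            base.log_scale
            + np.log(base.shape)
            + (base.shape - 1.0) * np.log(s)
            + c0
            + d * s
        )
        cum = float(T * np.sum(w * np.exp(logh_s)))
        logh = (
            base.log_scale + np.log(base.shape) + (base.shape - 1.0) * np.log(T)
            + c0 + d * T
        )
    else:  # pragma: no cover
        raise TypeError(f"unknown baseline {base!r}")
    if not np.isfinite(cum):
        warnings.warn("cumulative hazard overflow; clipping", stacklevel=2)
        cum = np.finfo(float).max / 1e10
    return float(delta * logh - cum)


def _conditional_long_loglik(params: JointParams, days, values, b) -> float:
    t = np.asarray(days, dtype=float)
    y = np.asarray(values, dtype=float)
    r = y - _m_of(params, b, t)
    return float(
        -0.5 * len(t) * np.log(2 * np.pi * params.sigma2)
        - 0.5 * np.sum(r**2) / params.sigma2
    )


def subject_marginal_loglik(
    params: JointParams,
    days,
    values,
    T: float,
    delta: int,
    u: int,
    spec: JointSpec | None = None,
    *,
    center: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Gauss-Hermite approximation of one subject's marginal log-likelihood.

    ``log int exp{ll_surv(b) + ll_long(b)} N(b; 0, D) db`` on a 2-D grid.
    With the (default) pseudo-adaptive rule the grid is centered at the
    subject's empirical Bayes mode under the longitudinal submodel with
    matching curvature; ``center=(mode, cov)`` overrides it.  Log-sum-exp is
    used for stability; if every node underflows the result is -inf.
    """
    spec = spec or JointSpec()
    t = np.asarray(days, dtype=float)
    if center is not None:
        mode, cov = center
    elif spec.pseudo_adaptive:
        Z = np.column_stack([np.ones_like(t), t])
        K = np.linalg.inv(params.D) + Z.T @ Z / params.sigma2
        cov = np.linalg.inv(K)
        mode = cov @ (Z.T @ (np.asarray(values) - Z @ params.beta)) / params.sigma2
    else:
        mode, cov = np.zeros(2), params.D
    L = np.linalg.cholesky(cov)
    Zg, logW = _gh_grid(spec.gh_points)
    bs = mode[None, :] + np.sqrt(2.0) * Zg @ L.T
    Dinv = np.linalg.inv(params.D)
    _, logdetD = np.linalg.slogdet(params.D)
    terms = np.empty(len(bs))
    for q, b in enumerate(bs):
        lp = -np.log(2 * np.pi) - 0.5 * logdetD - 0.5 * b @ Dinv @ b
        terms[q] = (
            conditional_survival_loglik(
                params, T, delta, u, b, gl_panels=spec.gl_panels,
                gl_points=spec.gl_points,
            )
            + _conditional_long_loglik(params, t, values, b)
            + lp
        )
    logjac = np.log(2.0) + np.log(np.abs(np.prod(np.diag(L))))
    out = logsumexp(logW + np.sum(Zg**2, axis=1) + logjac + terms)
    return float(out)


# ---------------------------------------------------------------------------
# vectorized fitting machinery


class _Problem:
    """Precomputed arrays for fast likelihood/gradient evaluation.

    Everything the objective needs is reduced to per-subject sufficient
    statistics (longitudinal), per-subject outcome scalars and fixed
    quadrature grids, all on the internal scale where time is measured in
    units of 100 days and alpha is multiplied by ASCALE.
    """

    def __init__(self, long_df: pd.DataFrame, surv_df: pd.DataFrame,
                 spec: JointSpec, lmm: LmmFit):
        self.spec = spec
        surv = surv_df.sort_values("subject_id").reset_index(drop=True)
        self.ids = surv["subject_id"].to_numpy()
        self.T = surv["time"].to_numpy(dtype=float)
        self.delta = surv["status"].to_numpy(dtype=float)
        self.u = surv["group"].to_numpy(dtype=float)
        if self.delta.sum() < 1:
            raise ValueError("joint model requires at least one event")
        if np.any(self.T <= 0):
            # subjects censored at time 0 carry no survival exposure
            self.T = np.maximum(self.T, 1e-10)
        n = len(self.T)
        self.n = n
        self.tauT = self.T / TSCALE
        self.logT = np.log(self.T)

        # longitudinal sufficient stats on the internal time scale
        stats = {sid: np.zeros(6) for sid in self.ids}
        for sid, g in long_df.groupby("subject_id"):
            t = g["day"].to_numpy(dtype=float) / TSCALE
            y = g["value"].to_numpy(dtype=float)
            stats[sid] = np.array([
                len(t), t.sum(), (t * t).sum(), y.sum(), (t * y).sum(), (y * y).sum()
            ])
        S = np.array([stats[sid] for sid in self.ids])
        self.nvis, self.St, self.Stt, self.Sy, self.Sty, self.Syy = S.T

        # quadrature nodes (internal scale), fixed through the optimization
        Zg, logW = _gh_grid(spec.gh_points)
        self.Q = len(Zg)
        Sint = np.diag([1.0, TSCALE])  # day -> internal random-effect scale
        if spec.pseudo_adaptive:
            modes = lmm.eb_modes_ @ Sint.T
            covs = Sint[None] @ lmm.eb_covs_ @ Sint.T[None]
        else:
            D0 = Sint @ lmm.D_hat @ Sint.T
            modes = np.zeros((n, 2))
            covs = np.broadcast_to(D0, (n, 2, 2))
        L = np.linalg.cholesky(covs)
        bs = modes[:, None, :] + np.sqrt(2.0) * np.einsum("nij,qj->nqi", L, Zg)
        self.b0n = bs[:, :, 0]
        self.b1n = bs[:, :, 1]
        logdetL = np.log(L[:, 0, 0]) + np.log(L[:, 1, 1])
        self.const = (logW + np.sum(Zg**2, axis=1) + np.log(2.0))[None, :] \
            + logdetL[:, None]

        if spec.baseline == "weibull":
            x, w = _gl_rule(spec.gl_panels, spec.gl_points)
            self.s = self.T[:, None] * x[None, :]          # days, (n, K)
            self.w = self.T[:, None] * w[None, :]
            self.logs = np.log(self.s)
            self.taus = self.s / TSCALE
            # stacked weights for the (1, tau, log s) cumulative-hazard
            # moments, contracted against the integrand in one batched GEMM
            self.W3 = np.stack(
                [self.w, self.w * self.taus, self.w * self.logs], axis=1)
            self._buf = np.empty((n, self.s.shape[1], self.Q))
            self.knots = None
        else:
            ev = np.sort(self.T[self.delta == 1])
            qs = np.arange(1, spec.n_intervals) / spec.n_intervals
            knots = np.unique(np.quantile(ev, qs))
            self.knots = knots
            edges = np.concatenate([[0.0], knots, [np.inf]])
            self.a_seg = np.minimum(edges[:-1][None, :], self.T[:, None])
            c_seg = np.minimum(edges[1:][None, :], self.T[:, None])
            self.dl_seg = np.maximum(c_seg - self.a_seg, 0.0)
            self.intv_T = np.searchsorted(knots, self.T, side="left")
            self.n_base = len(edges) - 1

    # -- parameter packing ---------------------------------------------------

    def n_params(self) -> int:
        return 8 + (2 if self.spec.baseline == "weibull" else self.n_base)

    def pack(self, params: JointParams) -> np.ndarray:
        Sint = np.diag([1.0, TSCALE])
        Ds = Sint @ params.D @ Sint.T
        L = np.linalg.cholesky(Ds)
        th = [params.beta[0], params.beta[1] * TSCALE, np.log(params.sigma2),
              np.log(L[0, 0]), L[1, 0], np.log(L[1, 1]),
              params.alpha * ASCALE, params.gamma]
        if self.spec.baseline == "weibull":
            b = params.baseline
            th += [np.log(b.shape), b.log_scale]
        else:
            th += list(params.baseline.log_hazards)
        return np.array(th, dtype=float)

    def unpack(self, theta: np.ndarray) -> JointParams:
        L = np.array([[np.exp(theta[3]), 0.0], [theta[4], np.exp(theta[5])]])
        Ds = L @ L.T
        Sinv = np.diag([1.0, 1.0 / TSCALE])
        if self.spec.baseline == "weibull":
            base = WeibullBaseline(shape=float(np.exp(theta[8])),
                                   log_scale=float(theta[9]))
        else:
            base = PiecewiseBaseline(knots=self.knots,
                                     log_hazards=np.array(theta[8:]))
        return JointParams(
            beta=np.array([theta[0], theta[1] / TSCALE]),
            sigma2=float(np.exp(theta[2])),
            D=Sinv @ Ds @ Sinv.T,
            alpha=float(theta[6] / ASCALE),
            gamma=float(theta[7]),
            baseline=base,
        )

    # -- objective -----------------------------------------------------------

    def negloglik_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        b0v, b1v = self.b0n, self.b1n  # (n, Q), internal scale
        beta0, beta1s = theta[0], theta[1]
        sigma2 = np.exp(theta[2])
        p1, p2, p3 = theta[3], theta[4], theta[5]
        L11, L21, L22 = np.exp(p1), p2, np.exp(p3)
        alpha = theta[6] / ASCALE
        gamma = theta[7]
        delta, u, tauT = self.delta, self.u, self.tauT

        # longitudinal conditional log-likelihood from sufficient stats
        one_r0 = self.Sy - self.nvis * beta0 - beta1s * self.St
        t_r0 = self.Sty - beta0 * self.St - beta1s * self.Stt
        r0r0 = (self.Syy - 2 * beta0 * self.Sy - 2 * beta1s * self.Sty
                + beta0**2 * self.nvis + 2 * beta0 * beta1s * self.St
                + beta1s**2 * self.Stt)
        SSR = (r0r0[:, None]
               - 2 * (b0v * one_r0[:, None] + b1v * t_r0[:, None])
               + b0v**2 * self.nvis[:, None]
               + 2 * b0v * b1v * self.St[:, None]
               + b1v**2 * self.Stt[:, None])
        ll_long = (-0.5 * self.nvis[:, None] * np.log(2 * np.pi * sigma2)
                   - SSR / (2 * sigma2))

        # random-effects prior density at the nodes
        v0 = b0v / L11
        v1 = (b1v - L21 * v0) / L22
        log_prior = -np.log(2 * np.pi) - (p1 + p3) - 0.5 * (v0**2 + v1**2)

        # survival conditional log-likelihood
        m_T = beta0 + beta1s * tauT[:, None] + b0v + b1v * tauT[:, None]
        if self.spec.baseline == "weibull":
            k = np.exp(theta[8])
            eta = theta[9]
            A = (eta + np.log(k) + (k - 1.0) * self.logs
                 + gamma * u[:, None]
                 + alpha * (beta0 + beta1s * self.taus))            # (n, K)
            E = self._buf                                            # (n, K, Q)
            np.multiply(self.taus[:, :, None], b1v[:, None, :], out=E)
            E += b0v[:, None, :]
            E *= alpha
            E += A[:, :, None]
            np.minimum(E, _EXP_CAP, out=E)
            np.exp(E, out=E)
            H3 = self.W3 @ E                                         # (n, 3, Q)
            H, Htau, Hlogs = H3[:, 0, :], H3[:, 1, :], H3[:, 2, :]
            logh0T = eta + np.log(k) + (k - 1.0) * self.logT
        else:
            zeta = theta[8:]
            c0 = gamma * u[:, None] + alpha * (beta0 + b0v)          # (n, Q)
            dcoef = alpha * (beta1s + b1v) / TSCALE                  # per day
            x = dcoef[:, None, :] * self.dl_seg[:, :, None]          # (n, M, Q)
            eda = np.exp(np.minimum(
                dcoef[:, None, :] * self.a_seg[:, :, None], _EXP_CAP))
            pref = np.exp(np.minimum(
                zeta[None, :, None] + c0[:, None, :], _EXP_CAP)) * eda
            P = pref * self.dl_seg[:, :, None] * _phi(x)             # (n, M, Q)
            Hseg_s = pref * self.dl_seg[:, :, None] * (
                self.a_seg[:, :, None] * _phi(x)
                + self.dl_seg[:, :, None] * _psi(x))                 # int s*h ds
            H = P.sum(axis=1)
            Htau = Hseg_s.sum(axis=1) / TSCALE
            logh0T = zeta[self.intv_T]

        le = delta[:, None] * (logh0T[:, None] + gamma * u[:, None] + alpha * m_T)

        tot = self.const + ll_long + log_prior + le - H
        ll_i = logsumexp(tot, axis=1)
        nll = -float(ll_i.sum())
        post = np.exp(tot - ll_i[:, None])                           # (n, Q)

        # gradient by the posterior-weighted complete-data score
        dm = delta[:, None] - H
        grads = np.empty((self.n_params(), self.n, self.Q))
        one_r = one_r0[:, None] - self.nvis[:, None] * b0v - self.St[:, None] * b1v
        t_r = t_r0[:, None] - self.St[:, None] * b0v - self.Stt[:, None] * b1v
        grads[0] = one_r / sigma2 + alpha * dm
        grads[1] = t_r / sigma2 + alpha * (delta[:, None] * tauT[:, None] - Htau)
        grads[2] = -self.nvis[:, None] / 2.0 + SSR / (2 * sigma2)
        w1 = v1 / L22
        w0 = (v0 - L21 * w1) / L11
        grads[3] = -1.0 + L11 * w0 * v0
        grads[4] = w1 * v0
        grads[5] = -1.0 + L22 * w1 * v1
        grads[6] = (delta[:, None] * m_T
                    - ((beta0 + b0v) * H + (beta1s + b1v) * Htau)) / ASCALE
        grads[7] = u[:, None] * dm
        if self.spec.baseline == "weibull":
            grads[8] = (delta[:, None] * (1.0 + k * self.logT[:, None])
                        - (H + k * Hlogs))
            grads[9] = dm
        else:
            ind = (self.intv_T[:, None] == np.arange(self.n_base)[None, :])
            for mseg in range(self.n_base):
                grads[8 + mseg] = (delta[:, None] * ind[:, mseg][:, None]
                                   - P[:, mseg, :])
        grad = -np.einsum("iq,piq->p", post, grads)
        if not np.isfinite(nll):
            nll = 1e12
            grad = np.zeros_like(grad)
        return nll, grad

    def negloglik(self, theta: np.ndarray) -> float:
        return self.negloglik_grad(theta)[0]


def _initial_params(problem: _Problem, long_df: pd.DataFrame,
                    surv_df: pd.DataFrame, lmm: LmmFit,
                    spec: JointSpec) -> JointParams:
    """Starting values: LMM for the longitudinal block, alpha = 0, the Cox
    group coefficient for gamma, and an occurrence/exposure baseline."""
    from .cox import build_locf_table, fit_cox

    gamma0 = 0.0
    try:
        cox = fit_cox(build_locf_table(long_df=long_df, surv_df=surv_df))
        if cox.converged:
            gamma0 = float(np.clip(cox.coef[1], -3.0, 3.0))
    except Exception:
        pass
    n_events = problem.delta.sum()
    exposure = problem.T.sum()
    rate = max(n_events / exposure, 1e-10)
    if spec.baseline == "weibull":
        base = WeibullBaseline(shape=1.0, log_scale=float(np.log(rate)))
    else:
        edges = np.concatenate([[0.0], problem.knots, [problem.T.max()]])
        logh = np.empty(problem.n_base)
        for m in range(problem.n_base):
            expo = np.sum(np.clip(problem.T, edges[m], edges[m + 1]) - edges[m])
            ev = np.sum((problem.delta == 1) & (problem.intv_T == m))
            logh[m] = np.log(max(ev, 0.5) / max(expo, 1e-10))
        base = PiecewiseBaseline(knots=problem.knots, log_hazards=logh)
    return JointParams(
        beta=lmm.beta.copy(),
        sigma2=lmm.sigma2_hat,
        D=_nearest_spd(lmm.D_hat),
        alpha=0.0,
        gamma=gamma0,
        baseline=base,
    )


def _nearest_spd(D: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    vals, vecs = np.linalg.eigh(D)
    return (vecs * np.maximum(vals, floor)) @ vecs.T


def fit_joint(
    dataset=None,
    spec: JointSpec | None = None,
    *,
    long_df: pd.DataFrame | None = None,
    surv_df: pd.DataFrame | None = None,
    lmm: LmmFit | None = None,
) -> JointFit:
    """Maximum-likelihood fit of the joint model.

    Accepts either a simulated dataset (``SimDataset``) or explicit
    long-format longitudinal and survival tables.  Non-convergence is
    reported through ``converged=False`` rather than an exception, since a
    replicate that fails to converge is a legitimate study outcome.
    """
    spec = spec or JointSpec()
    if dataset is not None:
        long_df = dataset.to_longitudinal_frame()
        surv_df = dataset.to_survival_frame()
    if long_df is None or surv_df is None:
        raise ValueError("provide a dataset or both long_df and surv_df")
    if lmm is None:
        lmm = fit_lmm(long_df)

    problem = _Problem(long_df, surv_df, spec, lmm)
    start = _initial_params(problem, long_df, surv_df, lmm, spec)
    x0 = problem.pack(start)

    res = optimize.minimize(
        problem.negloglik_grad, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": spec.max_iter, "ftol": spec.tol, "gtol": 1e-6},
    )
    params = problem.unpack(res.x)
    converged = bool(res.success) and np.isfinite(res.fun)

    se_alpha = se_gamma = np.nan
    if converged:
        hess = _hessian_from_grad(problem, res.x)
        try:
            cov = np.linalg.inv(hess)
            var_a = cov[6, 6] / ASCALE**2
            var_g = cov[7, 7]
            if var_a > 0 and var_g > 0:
                se_alpha = float(np.sqrt(var_a))
                se_gamma = float(np.sqrt(var_g))
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False
    return JointFit(
        params=params,
        se_alpha=se_alpha,
        se_gamma=se_gamma,
        loglik=float(-res.fun),
        converged=converged,
        n_iter=int(res.nit),
        spec=spec,
    )


def _hessian_from_grad(problem: _Problem, theta: np.ndarray,
                       step: float = 1e-4) -> np.ndarray:
    """Observed information by central differences of the analytic gradient."""
    p = len(theta)
    H = np.empty((p, p))
    for j in range(p):
        tp = theta.copy()
        tp[j] += step
        _, gp = problem.negloglik_grad(tp)
        tm = theta.copy()
        tm[j] -= step
        _, gm = problem.negloglik_grad(tm)
        H[j] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)


def total_marginal_loglik(long_df: pd.DataFrame, surv_df: pd.DataFrame,
                          params: JointParams, spec: JointSpec | None = None,
                          lmm: LmmFit | None = None) -> float:
    """Quadrature log-likelihood of given parameters on a dataset.

    Uses the same vectorized machinery as :func:`fit_joint`; the
    pseudo-adaptive centering comes from ``lmm`` (fitted on the data when
    omitted).
    """
    spec = spec or JointSpec()
    if lmm is None:
        lmm = fit_lmm(long_df)
    problem = _Problem(long_df, surv_df, spec, lmm)
    return -problem.negloglik(problem.pack(params))
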
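"""Count-regression models for weighted spectral counts.

Three log-link model variants cover the analyses a hair-shaft profiling
study needs:

``fit_od_poisson_glm``
    overdispersed (quasi-)Poisson GLM — fixed effects only, e.g. treating
    subject as a fixed effect for within-ethnicity subject comparisons.
    Variance is phi times the mean; phi is the Pearson statistic over the
    residual degrees of freedom and scales the coefficient covariance.

``fit_od_poisson_glmm``
    overdispersed Poisson mixed model with a subject random intercept, e.g.
    for body-site comparisons with repeated measures per subject.  beta and
    sigma_subject come from Laplace-approximated maximum likelihood; the
    residual dispersion phi comes from conditional Pearson residuals and
    inflates the conditional part of the coefficient covariance.

``fit_lognormal_poisson_glmm``
    Poisson mixed model with a subject intercept plus an observation-level
    Gaussian intercept (lognormal-Poisson, behaving like a negative binomial)
    for total-hair vs cuticle comparisons of low-abundance proteins.  Both
    random-effect vectors are integrated by a joint Laplace approximation.

Weighted spectral counts are non-negative reals, not integers; the quasi
fits use the Poisson score equations, which are well defined for continuous
responses, while the lognormal-Poisson fit rounds to the nearest integer by
default (configurable) because its objective is a true likelihood.

Inference is Wald-type: a t reference with residual degrees of freedom for
the GLM, an asymptotic normal reference for the mixed models.  All pairwise
comparisons of one factor can be adjusted with the Tukey HSD studentized
range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln

from .evidence_io import SampleTable

__all__ = [
    "DesignSpec",
    "ModelFit",
    "ContrastResult",
    "make_design",
    "fit_od_poisson_glm",
    "fit_od_poisson_glmm",
    "fit_lognormal_poisson_glmm",
    "contrast_test",
    "pairwise_contrasts",
    "tukey_adjust",
]

MAX_ETA = 30.0  # linear-predictor clip guarding against separation blow-up
GRAD_TOL = 1e-6
MAX_ITER = 200
SIGMA_LOWER = 1e-4  # variance-component search floor
SIGMA_BOUNDARY = 1e-3  # below this an estimate is reported as at the boundary


class FitError(RuntimeError):
    """The requested model cannot be estimated from the supplied design."""


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class DesignSpec:
    """Fixed-effect design matrix plus optional subject grouping and offset.

    Factors use reference-level (treatment) coding with the alphabetically
    first level as reference; ``factor_cols`` maps each factor's level to its
    column index (``None`` for the reference level) so that arbitrary level
    contrasts can be formed regardless of the coding.
    """

    matrix: np.ndarray
    coef_names: list[str]
    factor_levels: dict[str, list[str]]
    factor_cols: dict[str, dict[str, int | None]]
    offset: np.ndarray
    groups: np.ndarray | None = None  # subject code per observation
    group_labels: list[str] | None = None

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_groups(self) -> int:
        return 0 if self.group_labels is None else len(self.group_labels)

    def between_subject_columns(self) -> np.ndarray:
        """Boolean mask of design columns constant within every subject."""
        if self.groups is None:
            return np.ones(self.n_params, dtype=bool)
        out = np.ones(self.n_params, dtype=bool)
        for j in range(self.n_params):
            col = self.matrix[:, j]
            for s in range(self.n_groups):
                vals = col[self.groups == s]
                if np.ptp(vals) > 1e-12:
                    out[j] = False
                    break
        return out

    def containment_df(self) -> tuple[float, float]:
        """(between-subject, within-subject) denominator degrees of freedom.

        Containment rule: effects constant within subject are tested against
        subject-to-subject variation (q − rank of the subject-level design);
        effects varying within subject against the residual level
        (n − q − #within-subject columns).
        """
        if self.groups is None:
            df = float(self.n_obs - self.n_params)
            return df, df
        between = self.between_subject_columns()
        subject_level = np.vstack(
            [self.matrix[self.groups == s].mean(axis=0) for s in range(self.n_groups)]
        )
        r_b = np.linalg.matrix_rank(subject_level)
        df_between = max(float(self.n_groups - r_b), 1.0)
        df_within = max(float(self.n_obs - self.n_groups - int((~between).sum())), 1.0)
        return df_between, df_within

    def contrast_vector(self, factor: str, level_a: str, level_b: str) -> np.ndarray:
        """Coefficient vector for the (log-scale) difference level_a − level_b."""
        cols = self.factor_cols[factor]
        c = np.zeros(self.n_params)
        for level, sign in ((level_a, 1.0), (level_b, -1.0)):
            j = cols[level]
            if j is not None:
                c[j] += sign
        return c


def make_design(
    metadata: SampleTable,
    sample_ids: Sequence[str],
    fixed: Sequence[str],
    random_subject: bool = False,
    offset: pd.Series | np.ndarray | None = None,
) -> DesignSpec:
    """Build a full-rank treatment-coded design for the given samples.

    ``fixed`` names metadata columns ("subject" is an alias for
    ``subject_id``).  With ``random_subject`` the subject column supplies the
    random-intercept grouping instead of fixed-effect columns.
    """
    sample_ids = list(sample_ids)
    metadata.require_samples(sample_ids)
    n = len(sample_ids)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["(Intercept)"]
    factor_levels: dict[str, list[str]] = {}
    factor_cols: dict[str, dict[str, int | None]] = {}
    for term in fixed:
        values = metadata.column(term).loc[sample_ids].to_numpy()
        levels = sorted(set(values))
        if len(levels) < 2:
            raise FitError(f"factor {term!r} has a single level among supplied samples")
        factor_levels[term] = levels
        colmap: dict[str, int | None] = {levels[0]: None}
        for lev in levels[1:]:
            colmap[lev] = len(names)
            names.append(f"{term}[{lev}]")
            cols.append((values == lev).astype(float))
        factor_cols[term] = colmap
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("design matrix is rank deficient after reference coding")

    groups = None
    group_labels = None
    if random_subject:
        subj = metadata.column("subject_id").loc[sample_ids].to_numpy()
        group_labels = sorted(set(subj))
        code = {s: i for i, s in enumerate(group_labels)}
        groups = np.array([code[s] for s in subj])

    if offset is None:
        off = np.zeros(n)
    elif isinstance(offset, pd.Series):
        off = offset.loc[sample_ids].to_numpy(dtype=float)
    else:
        off = np.asarray(offset, dtype=float)
        if off.shape != (n,):
            raise ValueError("offset length does not match sample list")
    return DesignSpec(X, names, factor_levels, factor_cols, off, groups, group_labels)


# ---------------------------------------------------------------------------
# fitted-model container and Wald machinery
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """State of a fitted count model on the log scale."""

    beta: np.ndarray
    coef_names: list[str]
    vcov_beta: np.ndarray
    phi: float = 1.0
    sigma_subject: float = 0.0
    sigma_obs: float = 0.0
    df_resid: float = np.inf
    df_between: float = np.inf
    df_within: float = np.inf
    loglik_approx: float = np.nan
    converged: bool = True
    boundary: bool = False
    model: str = ""
    design: DesignSpec | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "beta": dict(zip(self.coef_names, map(float, self.beta))),
            "phi": float(self.phi),
            "sigma_subject": float(self.sigma_subject),
            "sigma_obs": float(self.sigma_obs),
            "df_resid": float(self.df_resid),
            "loglik_approx": float(self.loglik_approx),
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
        }


@dataclass
class ContrastResult:
    """One Wald contrast: log-scale estimate, test and 95% interval."""

    label: str
    estimate: float
    se: float
    statistic: float
    p_raw: float
    ci_low: float
    ci_high: float
    p_adjusted: float | None = None
    df: float = np.inf


def _contrast_df(fit: ModelFit, c: np.ndarray) -> float:
    """Reference df for one contrast: containment rule for mixed models.

    A contrast supported only on between-subject columns is tested against
    subject-to-subject variation; anything touching a within-subject column
    uses the residual-level df.  GLMs use the usual n − p.
    """
    if fit.design is None:
        return fit.df_resid
    if fit.design.groups is None:
        return fit.df_resid
    between = fit.design.between_subject_columns()
    df_b = fit.df_between
    df_w = fit.df_within
    return df_b if np.all(between[np.abs(c) > 1e-12]) else df_w


def contrast_test(fit: ModelFit, contrast: np.ndarray, label: str = "", level: float = 0.95) -> ContrastResult:
    """Wald test of c'beta = 0 with a two-sided p and a CI at ``level``.

    The reference distribution is t with the fit's denominator degrees of
    freedom (residual df for the GLM, containment df for the mixed models);
    an infinite df falls back to the standard normal.
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != fit.beta.shape:
        raise ValueError("contrast length does not match coefficient vector")
    est = float(c @ fit.beta)
    var = float(c @ fit.vcov_beta @ c)
    if var <= 0:
        raise ValueError("zero-variance contrast (is the contrast the zero vector?)")
    se = np.sqrt(var)
    stat = est / se
    df = _contrast_df(fit, c)
    if np.isfinite(df):
        p = 2.0 * stats.t.sf(abs(stat), df)
        crit = stats.t.ppf(0.5 + level / 2.0, df)
    else:
        p = 2.0 * stats.norm.sf(abs(stat))
        crit = stats.norm.ppf(0.5 + level / 2.0)
    return ContrastResult(
        label=label,
        estimate=est,
        se=se,
        statistic=stat,
        p_raw=float(p),
        ci_low=est - crit * se,
        ci_high=est + crit * se,
        df=df,
    )


def pairwise_contrasts(fit: ModelFit, factor: str) -> list[ContrastResult]:
    """All k(k−1)/2 level-pair contrasts of one factor of the fit's design."""
    if fit.design is None or factor not in fit.design.factor_levels:
        raise KeyError(f"fit has no recorded factor {factor!r}")
    levels = fit.design.factor_levels[factor]
    return [
        contrast_test(fit, fit.design.contrast_vector(factor, b, a), label=f"{b} - {a}")
        for a, b in combinations(levels, 2)
    ]


def tukey_adjust(
    contrasts: Sequence[ContrastResult], k: int, df: float | None = None
) -> list[ContrastResult]:
    """Tukey HSD adjustment of a complete set of pairwise contrasts.

    p_adjusted = P(Q_{k,df} >= sqrt(2) |t|) under the studentized range
    distribution; for k = 2 this reduces to the unadjusted two-sided p.
    ``df`` overrides each contrast's own reference df.
    """
    if len(contrasts) != k * (k - 1) // 2:
        raise ValueError(
            f"expected {k * (k - 1) // 2} pairwise contrasts for k={k}, got {len(contrasts)}"
        )
    out = []
    for c in contrasts:
        c_df = df if df is not None else c.df
        q_df = c_df if np.isfinite(c_df) else 1e6  # studentized_range needs finite df
        p_adj = float(stats.studentized_range.sf(np.sqrt(2.0) * abs(c.statistic), k, q_df))
        out.append(replace(c, p_adjusted=max(min(p_adj, 1.0), c.p_raw)))
    return out


# ---------------------------------------------------------------------------
# quasi-Poisson GLM (IRLS)
# ---------------------------------------------------------------------------


def _check_response(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if (y < 0).any() or not np.isfinite(y).all():
        raise ValueError("response must be finite and non-negative")
    return y


def fit_od_poisson_glm(y: np.ndarray, design: DesignSpec) -> ModelFit:
    """Quasi-Poisson GLM via iteratively reweighted least squares.

    Accepts non-integer responses; the Poisson score equations and Pearson
    dispersion are well defined for any y >= 0.
    """
    y = _check_response(y)
    X, off = design.matrix, design.offset
    n, p = X.shape
    if n <= p:
        raise FitError(f"need more observations ({n}) than parameters ({p})")

    beta = np.zeros(p)
    beta[0] = np.log(max(np.mean(y / np.exp(np.clip(off, -MAX_ETA, MAX_ETA))), 1e-8))
    converged = False
    mu = np.exp(np.clip(X @ beta + off, -MAX_ETA, MAX_ETA))
    for _ in range(MAX_ITER):
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < GRAD_TOL * max(1.0, y.sum()):
            converged = True
            break
        XW = X * mu[:, None]
        H = X.T @ XW + 1e-10 * np.eye(p)
        step = np.linalg.solve(H, grad)
        # step-halving on the quasi log-likelihood
        q0 = _quasi_loglik(y, np.clip(X @ beta + off, -MAX_ETA, MAX_ETA))
        scale = 1.0
        for _ in range(30):
            trial = beta + scale * step
            eta = np.clip(X @ trial + off, -MAX_ETA, MAX_ETA)
            if _quasi_loglik(y, eta) >= q0 - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        mu = np.exp(np.clip(X @ beta + off, -MAX_ETA, MAX_ETA))

    boundary = bool(np.max(np.abs(beta)) > 10.0)
    if boundary:
        warnings.warn("coefficient at boundary (possible separation / all-zero cell)")
    df_resid = n - p
    phi = float(np.sum((y - mu) ** 2 / np.maximum(mu, 1e-12)) / df_resid)
    phi = max(phi, 1e-8)
    H = X.T @ (X * mu[:, None]) + 1e-10 * np.eye(p)
    vcov = phi * np.linalg.inv(H)
    return ModelFit(
        beta=beta,
        coef_names=design.coef_names,
        vcov_beta=vcov,
        phi=phi,
        df_resid=df_resid,
        df_between=float(df_resid),
        df_within=float(df_resid),
        loglik_approx=_poisson_loglik(y, np.log(np.maximum(mu, 1e-300))),
        converged=converged or boundary,
        boundary=boundary,
        model="od_glm",
        design=design,
    )


def _quasi_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.exp(eta)))


def _poisson_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))


# ---------------------------------------------------------------------------
# Poisson GLMM with subject random intercept (Laplace)
# ---------------------------------------------------------------------------


def _glmm_inner(y, X, off, g, q, sigma, beta, u):
    """Joint Newton for (beta, u) at fixed sigma; returns mode and curvature."""
    n, p = X.shape
    inv_s2 = 1.0 / sigma**2

    def penalized(beta, u):
        eta = np.clip(X @ beta + off + u[g], -MAX_ETA, MAX_ETA)
        return _quasi_loglik(y, eta) - 0.5 * inv_s2 * float(u @ u)

    obj = penalized(beta, u)
    for _ in range(MAX_ITER):
        eta = np.clip(X @ beta + off + u[g], -MAX_ETA, MAX_ETA)
        mu = np.exp(eta)
        r = y - mu
        grad_b = X.T @ r
        grad_u = np.bincount(g, weights=r, minlength=q) - inv_s2 * u
        gnorm = max(np.max(np.abs(grad_b)), np.max(np.abs(grad_u)))
        if gnorm < GRAD_TOL * max(1.0, y.sum()):
            break
        Wg = np.bincount(g, weights=mu, minlength=q)
        XW = X * mu[:, None]
        A = X.T @ XW + 1e-10 * np.eye(p)  # p×p
        B = np.zeros((p, q))  # X'WZ
        np.add.at(B.T, g, XW)
        Dg = Wg + inv_s2
        # Schur complement solve: (A - B D^{-1} B') d_b = grad_b - B D^{-1} grad_u
        BD = B / Dg
        S = A - BD @ B.T
        rhs = grad_b - BD @ grad_u
        try:
            d_b = np.linalg.solve(S, rhs)
        except np.linalg.LinAlgError:
            d_b = np.linalg.lstsq(S, rhs, rcond=None)[0]
        d_u = (grad_u - B.T @ d_b) / Dg
        scale = 1.0
        for _ in range(30):
            nb, nu = beta + scale * d_b, u + scale * d_u
            new = penalized(nb, nu)
            if new >= obj - 1e-12:
                break
            scale *= 0.5
        beta, u = beta + scale * d_b, u + scale * d_u
        obj = new
    eta = np.clip(X @ beta + off + u[g], -MAX_ETA, MAX_ETA)
    mu = np.exp(eta)
    Wg = np.bincount(g, weights=mu, minlength=q)
    return beta, u, mu, Wg


def fit_od_poisson_glmm(y: np.ndarray, design: DesignSpec) -> ModelFit:
    """Overdispersed Poisson GLMM: Laplace ML for (beta, sigma_subject).

    The subject random-intercept SD is profiled by a bounded 1-D search on
    the Laplace log-likelihood.  Residual dispersion phi comes from
    conditional Pearson residuals; the coefficient covariance is the
    generalized-least-squares covariance under working variance
    phi/mu + sigma_subject^2 within subject, so phi inflates the conditional
    part while the between-subject part enters through sigma_subject.
    """
    y = _check_response(y)
    if design.groups is None:
        raise FitError("fit_od_poisson_glmm requires a subject random effect")
    X, off, g = design.matrix, design.offset, design.groups
    n, p = X.shape
    q = design.n_groups
    if q < 3:
        raise FitError(f"need at least 3 subjects for a random intercept, got {q}")
    _check_random_identifiable(X, g, q)

    state = {"beta": None, "u": None}

    def neg_laplace(log_sigma: float) -> float:
        sigma = np.exp(log_sigma)
        beta0 = state["beta"] if state["beta"] is not None else np.zeros(p)
        u0 = state["u"] if state["u"] is not None else np.zeros(q)
        if state["beta"] is None:
            beta0 = beta0.copy()
            beta0[0] = np.log(max(np.mean(y) / np.mean(np.exp(np.clip(off, -30, 30))), 1e-8))
        beta, u, mu, Wg = _glmm_inner(y, X, off, g, q, sigma, beta0.copy(), u0.copy())
        state["beta"], state["u"] = beta, u
        eta = np.log(np.maximum(mu, 1e-300))
        lap = (
            _quasi_loglik(y, eta)
            - 0.5 * float(u @ u) / sigma**2
            - q * np.log(sigma)
            - 0.5 * float(np.sum(np.log(Wg + 1.0 / sigma**2)))
        )
        return -lap

    res = minimize_scalar(
        neg_laplace,
        bounds=(np.log(SIGMA_LOWER), np.log(5.0)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    sigma = float(np.exp(res.x))
    beta, u, mu, Wg = _glmm_inner(
        y, X, off, g, q, sigma, state["beta"].copy(), state["u"].copy()
    )
    boundary = sigma < SIGMA_BOUNDARY
    if np.max(np.abs(beta)) > 10.0:
        boundary = True
        warnings.warn("coefficient at boundary (possible separation / all-zero cell)")

    df_resid = n - p
    phi = float(np.sum((y - mu) ** 2 / np.maximum(mu, 1e-12)) / df_resid)
    phi = max(phi, 1e-8)

    # GLS covariance under Var = phi/mu + sigma^2 within subject (working scale)
    a = mu / phi  # inverse conditional variance of the working response
    Ag = np.bincount(g, weights=a, minlength=q)
    XA = X * a[:, None]
    XAX = X.T @ XA
    XAZ = np.zeros((p, q))
    np.add.at(XAZ.T, g, XA)
    M = Ag + 1.0 / sigma**2
    S = XAX - (XAZ / M) @ XAZ.T + 1e-12 * np.eye(p)
    vcov = np.linalg.inv(S)
    df_b, df_w = design.containment_df()
    return ModelFit(
        beta=beta,
        coef_names=design.coef_names,
        vcov_beta=vcov,
        phi=phi,
        sigma_subject=sigma,
        df_resid=df_w,
        df_between=df_b,
        df_within=df_w,
        loglik_approx=float(-res.fun),
        converged=bool(res.success),
        boundary=boundary,
        model="od_glmm",
        design=design,
    )


def _check_random_identifiable(X: np.ndarray, g: np.ndarray, q: int) -> None:
    """Reject designs where each fixed-effect cell holds a single subject."""
    pattern_of_subject: dict[int, tuple] = {}
    for i, s in enumerate(g):
        pattern_of_subject.setdefault(int(s), tuple(np.round(X[i], 10)))
    patterns = list(pattern_of_subject.values())
    if len(set(patterns)) == q:
        raise FitError(
            "each subject occupies its own fixed-effect cell; the subject random "
            "effect is confounded with the fixed effects (e.g., one subject per group)"
        )


# ---------------------------------------------------------------------------
# lognormal-Poisson GLMM (subject + observation-level intercepts)
# ---------------------------------------------------------------------------


def _lnp_inner(y, X, off, g, q, s_u, s_o, beta, u, e):
    """Joint Newton over (beta, u, e) at fixed SDs; dense solve."""
    n, p = X.shape
    iu, io = 1.0 / s_u**2, 1.0 / s_o**2

    def penalized(beta, u, e):
        eta = np.clip(X @ beta + off + u[g] + e, -MAX_ETA, MAX_ETA)
        return _quasi_loglik(y, eta) - 0.5 * iu * float(u @ u) - 0.5 * io * float(e @ e)

    obj = penalized(beta, u, e)
    for _ in range(MAX_ITER):
        eta = np.clip(X @ beta + off + u[g] + e, -MAX_ETA, MAX_ETA)
        mu = np.exp(eta)
        r = y - mu
        grad = np.concatenate(
            [X.T @ r, np.bincount(g, weights=r, minlength=q) - iu * u, r - io * e]
        )
        if np.max(np.abs(grad)) < GRAD_TOL * max(1.0, y.sum()):
            break
        # full Hessian of size p+q+n
        XW = X * mu[:, None]
        H = np.zeros((p + q + n, p + q + n))
        H[:p, :p] = X.T @ XW
        ZW = np.zeros((q, n))
        ZW[g, np.arange(n)] = mu
        H[:p, p : p + q] = (ZW @ X).T  # X'WZ
        H[p : p + q, :p] = H[:p, p : p + q].T
        H[p : p + q, p : p + q] = np.diag(np.bincount(g, weights=mu, minlength=q) + iu)
        H[:p, p + q :] = XW.T
        H[p + q :, :p] = XW
        H[p : p + q, p + q :] = ZW
        H[p + q :, p : p + q] = ZW.T
        H[p + q :, p + q :] = np.diag(mu + io)
        H[np.diag_indices_from(H)] += 1e-10
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        d_b, d_u, d_e = step[:p], step[p : p + q], step[p + q :]
        scale = 1.0
        for _ in range(30):
            new = penalized(beta + scale * d_b, u + scale * d_u, e + scale * d_e)
            if new >= obj - 1e-12:
                break
            scale *= 0.5
        beta, u, e = beta + scale * d_b, u + scale * d_u, e + scale * d_e
        obj = penalized(beta, u, e)
    eta = np.clip(X @ beta + off + u[g] + e, -MAX_ETA, MAX_ETA)
    return beta, u, e, np.exp(eta)


def _lnp_logdet_rand(mu, g, q, iu, io):
    """log det of the (u, e) curvature block via its Schur form.

    The block is [[Du + iu, ZW], [WZ', W + io]] with W = diag(mu); eliminating
    e gives det = det(W + io) * det(Du + iu - ZW (W+io)^{-1} WZ').
    """
    w_over = mu * mu / (mu + io)
    Du = np.bincount(g, weights=mu, minlength=q)
    corr = np.bincount(g, weights=w_over, minlength=q)
    return float(np.sum(np.log(mu + io)) + np.sum(np.log(Du + iu - corr)))


def fit_lognormal_poisson_glmm(
    y: np.ndarray,
    design: DesignSpec,
    round_counts: bool = True,
    fix_sigma_obs: float | None = None,
) -> ModelFit:
    """Lognormal-Poisson GLMM via joint Laplace over subject and observation
    random intercepts.

    The observation-level Gaussian intercept gives negative-binomial-like
    marginal overdispersion.  Because the objective is a true likelihood,
    non-integer weighted counts are rounded by default.  ``fix_sigma_obs=0``
    collapses the model to the Poisson GLMM likelihood (used for nested-model
    consistency checks).
    """
    y = _check_response(y)
    if round_counts:
        y = np.round(y)
    if design.groups is None:
        raise FitError("fit_lognormal_poisson_glmm requires a subject random effect")
    X, off, g = design.matrix, design.offset, design.groups
    n, p = X.shape
    q = design.n_groups
    if q < 3:
        raise FitError(f"need at least 3 subjects for a random intercept, got {q}")
    _check_random_identifiable(X, g, q)

    state: dict = {"beta": None, "u": None, "e": None}

    def mode_at(s_u: float, s_o: float):
        beta0 = state["beta"] if state["beta"] is not None else np.zeros(p)
        if state["beta"] is None:
            beta0 = beta0.copy()
            beta0[0] = np.log(max(np.mean(y) / np.mean(np.exp(np.clip(off, -30, 30))), 1e-8))
        u0 = state["u"] if state["u"] is not None else np.zeros(q)
        e0 = state["e"] if state["e"] is not None else np.zeros(n)
        beta, u, e, mu = _lnp_inner(
            y, X, off, g, q, s_u, s_o, beta0.copy(), u0.copy(), e0.copy()
        )
        state.update(beta=beta, u=u, e=e)
        return beta, u, e, mu

    def neg_laplace(params) -> float:
        s_u = float(np.exp(params[0]))
        s_o = float(np.exp(params[1])) if fix_sigma_obs is None else max(fix_sigma_obs, 0.0)
        beta, u, e, mu = mode_at(s_u, max(s_o, SIGMA_LOWER) if s_o > 0 else SIGMA_LOWER)
        iu = 1.0 / s_u**2
        io = 1.0 / max(s_o, SIGMA_LOWER) ** 2
        eta = np.log(np.maximum(mu, 1e-300))
        lap = (
            _poisson_loglik(y, eta)
            - 0.5 * iu * float(u @ u)
            - 0.5 * io * float(e @ e)
            - q * np.log(s_u)
            - n * np.log(max(s_o, SIGMA_LOWER))
            - 0.5 * _lnp_logdet_rand(mu, g, q, iu, io)
        )
        return -lap

    if fix_sigma_obs is not None and fix_sigma_obs <= SIGMA_LOWER:
        # collapses to the Poisson GLMM likelihood: profile sigma_subject only
        res = minimize_scalar(
            lambda ls: _glmm_neg_laplace_true(y, X, off, g, q, np.exp(ls), state),
            bounds=(np.log(SIGMA_LOWER), np.log(5.0)),
            method="bounded",
            options={"xatol": 1e-4},
        )
        s_u = float(np.exp(res.x))
        beta, u, mu, _ = _glmm_inner(y, X, off, g, q, s_u, state["beta"].copy(), state["u"].copy())
        s_o, loglik, success = 0.0, float(-res.fun), bool(res.success)
    else:
        x0 = np.log([0.3, 0.3])
        res = minimize(
            neg_laplace,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 300},
        )
        s_u = float(np.exp(res.x[0]))
        s_o = float(np.exp(res.x[1])) if fix_sigma_obs is None else float(fix_sigma_obs)
        beta, u, e, mu = mode_at(s_u, max(s_o, SIGMA_LOWER))
        loglik, success = float(-res.fun), bool(res.success)

    boundary = s_u < SIGMA_BOUNDARY or (fix_sigma_obs is None and s_o < SIGMA_BOUNDARY)
    if np.max(np.abs(beta)) > 10.0:
        boundary = True
        warnings.warn("coefficient at boundary (possible separation / all-zero cell)")
    vcov = _lnp_vcov_beta(mu, X, g, q, s_u, s_o)
    df_b, df_w = design.containment_df()
    return ModelFit(
        beta=beta,
        coef_names=design.coef_names,
        vcov_beta=vcov,
        phi=1.0,
        sigma_subject=s_u,
        sigma_obs=s_o,
        df_resid=df_w,
        df_between=df_b,
        df_within=df_w,
        loglik_approx=loglik,
        converged=success,
        boundary=boundary,
        model="lognormal_poisson",
        design=design,
    )


def _glmm_neg_laplace_true(y, X, off, g, q, sigma, state):
    """Negative true-likelihood Laplace objective for the Poisson GLMM."""
    p = X.shape[1]
    beta0 = state["beta"] if state["beta"] is not None else np.zeros(p)
    if state["beta"] is None:
        beta0 = beta0.copy()
        beta0[0] = np.log(max(np.mean(y) / np.mean(np.exp(np.clip(off, -30, 30))), 1e-8))
    u0 = state["u"] if state["u"] is not None else np.zeros(q)
    beta, u, mu, Wg = _glmm_inner(y, X, off, g, q, sigma, beta0.copy(), u0.copy())
    state["beta"], state["u"] = beta, u
    eta = np.log(np.maximum(mu, 1e-300))
    lap = (
        _poisson_loglik(y, eta)
        - 0.5 * float(u @ u) / sigma**2
        - q * np.log(sigma)
        - 0.5 * float(np.sum(np.log(Wg + 1.0 / sigma**2)))
    )
    return -lap


def _lnp_vcov_beta(mu, X, g, q, s_u, s_o):
    """GLS covariance of beta under working variance 1/mu + s_o^2 + s_u^2 (subject)."""
    n, p = X.shape
    d = 1.0 / np.maximum(mu, 1e-12) + s_o**2  # independent part, working scale
    a = 1.0 / d
    Ag = np.bincount(g, weights=a, minlength=q)
    XA = X * a[:, None]
    XAX = X.T @ XA
    XAZ = np.zeros((p, q))
    np.add.at(XAZ.T, g, XA)
    M = Ag + 1.0 / max(s_u, SIGMA_LOWER) ** 2
    S = XAX - (XAZ / M) @ XAZ.T + 1e-12 * np.eye(p)
    return np.linalg.inv(S)
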
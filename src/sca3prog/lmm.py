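"""Maximum-likelihood linear mixed models with unstructured random covariance.

The model for subject i with n_i visits is

    y_i = X_i beta + Z_i b_i + e_i,   b_i ~ N(0, Sigma),   e_i ~ N(0, sigma^2 I),

with Sigma an unstructured q x q covariance over the random basis (intercept
plus time slope(s)).  Estimation is full ML (not REML): writing
Sigma = sigma^2 G and W_i = Z_i G Z_i' + I, both beta (by GLS) and sigma^2 are
profiled out of the marginal Gaussian log-likelihood, leaving an optimization
over the q(q+1)/2 free entries of G only.  G is parameterized through a
log-diagonal Cholesky factor, which keeps it positive semi-definite without
constraints, and the per-subject matrix algebra is reduced via the Woodbury
identity to q x q operations on precomputed cross-products, batched over
subjects.  The optimizer restarts from three dispersed starting values (unit
G, near-zero G, and a method-of-moments guess) and keeps the best optimum.

ML is the convention throughout because the downstream model comparison uses
likelihood-ratio tests on fixed effects, and because the ladder's information
criteria count k = (#fixed) + q(q+1)/2 + 1 parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import DesignMatrices, ModelSpec
from .errors import FitError, NonNestedError

__all__ = [
    "FitResult",
    "LRTResult",
    "fit_lmm",
    "information_criteria",
    "lrt",
    "nakagawa_r2",
    "blup_random_effects",
]

_SIGMA2_FLOOR = 1e-12


def information_criteria(loglik: float, k: int, n_obs: int) -> tuple[float, float]:
    """AIC and BIC from a log-likelihood: ``2k - 2*ll`` and ``k*ln(n) - 2*ll``."""
    aic = 2.0 * k - 2.0 * loglik
    bic = k * math.log(n_obs) - 2.0 * loglik if n_obs >= 1 else math.nan
    return aic, bic


@dataclass
class FitResult:
    """ML estimates and fit statistics for one mixed-model fit."""

    spec: ModelSpec
    fixed_names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    Sigma: np.ndarray
    sigma2: float
    loglik: float
    k: int
    n_obs: int
    n_subjects: int
    aic: float
    bic: float
    r2_marginal: float
    r2_conditional: float
    converged: bool
    n_restarts_used: int
    singular: bool
    design: DesignMatrices = field(repr=False, default=None)

    @property
    def resid_sd(self) -> float:
        return math.sqrt(self.sigma2)

    def coef(self, term: str) -> float:
        """Point estimate of one fixed-effect term."""
        return float(self.beta[self.fixed_names.index(term)])

    def beta_dict(self) -> dict[str, float]:
        return {t: float(b) for t, b in zip(self.fixed_names, self.beta)}

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name if self.spec else None,
            "knot": self.spec.knot if self.spec else None,
            "coefficients": [
                {"term": t, "estimate": float(b), "se": float(s),
                 "z": float(z), "p": float(p)}
                for t, b, s, z, p in zip(
                    self.fixed_names, self.beta, self.se, self.wald_z, self.wald_p
                )
            ],
            "random_covariance": self.Sigma.tolist(),
            "random_basis": list(self.spec.random_basis) if self.spec else None,
            "residual_variance": float(self.sigma2),
            "loglik": float(self.loglik),
            "k": int(self.k),
            "n_obs": int(self.n_obs),
            "n_subjects": int(self.n_subjects),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "r2_marginal": float(self.r2_marginal),
            "r2_conditional": float(self.r2_conditional),
            "converged": bool(self.converged),
            "n_restarts_used": int(self.n_restarts_used),
            "singular": bool(self.singular),
        }

    def summary(self) -> str:
        """Human-readable coefficient table (one published-style column)."""
        lines = [
            f"Model {self.spec.name}"
            + (f" (knot = {self.spec.knot:g} y)" if self.spec.knot else ""),
            f"  n_obs = {self.n_obs}, n_subjects = {self.n_subjects}, k = {self.k}",
            "  term            estimate (SE)        p",
        ]
        for t, b, s, p in zip(self.fixed_names, self.beta, self.se, self.wald_p):
            p_str = "<0.001" if p < 0.001 else f"{p:.3f}"
            lines.append(f"  {t:<15} {b:>9.3f} ({s:.3f})   {p_str}")
        lines += [
            f"  residual SD = {self.resid_sd:.3f}",
            f"  logLik = {self.loglik:.3f}  AIC = {self.aic:.3f}  BIC = {self.bic:.3f}",
            f"  R2 marginal = {self.r2_marginal:.3f}  conditional = {self.r2_conditional:.3f}",
        ]
        if not self.converged:
            lines.append("  WARNING: optimizer did not report convergence")
        if self.singular:
            lines.append("  NOTE: random-effects covariance is singular (boundary fit)")
        return "\n".join(lines)


@dataclass
class LRTResult:
    """Likelihood-ratio (ANOVA) comparison of two nested ML fits."""

    stat: float
    df: int
    p: float


class _Profiled:
    """Profiled negative log-likelihood over the scaled covariance G."""

    def __init__(self, design: DesignMatrices):
        X, Z, y, groups = design.X, design.Z, design.y, design.groups
        n, p = X.shape
        q = Z.shape[1]
        self.n, self.p, self.q = n, p, q
        # per-subject cross-products, stacked
        codes, uniques = pd.factorize(groups)
        m = len(uniques)
        self.m = m
        self.subjects = uniques
        self.codes = codes
        S = np.zeros((m, q, q))
        ZtX = np.zeros((m, q, p))
        Zty = np.zeros((m, q))
        np.add.at(S, codes, Z[:, :, None] * Z[:, None, :])
        np.add.at(ZtX, codes, Z[:, :, None] * X[:, None, :])
        np.add.at(Zty, codes, Z * y[:, None])
        self.n_per_subject = np.bincount(codes, minlength=m)
        self.S, self.ZtX, self.Zty = S, ZtX, Zty
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.eye = np.eye(q)

    def theta_to_G(self, theta: np.ndarray) -> np.ndarray:
        q = self.q
        L = np.zeros((q, q))
        L[np.tril_indices(q)] = theta
        L[np.diag_indices(q)] = np.exp(np.diag(L))
        return L @ L.T

    def _pieces(self, G: np.ndarray):
        M = self.eye[None, :, :] + np.matmul(G[None, :, :], self.S)
        _, logdet = np.linalg.slogdet(M)
        A = np.linalg.solve(M, np.broadcast_to(G, M.shape))
        A = 0.5 * (A + np.transpose(A, (0, 2, 1)))
        Sxx = self.XtX - np.einsum("mqp,mqk,mkr->pr", self.ZtX, A, self.ZtX)
        Sxy = self.Xty - np.einsum("mqp,mqk,mk->p", self.ZtX, A, self.Zty)
        Syy = self.yty - np.einsum("mq,mqk,mk->", self.Zty, A, self.Zty)
        return A, logdet, Sxx, Sxy, Syy

    def beta_sigma2(self, G: np.ndarray):
        A, logdet, Sxx, Sxy, Syy = self._pieces(G)
        beta = np.linalg.solve(Sxx, Sxy)
        rss = Syy - float(beta @ Sxy)
        sigma2 = max(rss / self.n, _SIGMA2_FLOOR)
        return beta, sigma2, logdet, Sxx, A

    def nll(self, theta: np.ndarray) -> float:
        try:
            G = self.theta_to_G(theta)
            _, sigma2, logdet, _, _ = self.beta_sigma2(G)
        except np.linalg.LinAlgError:
            return 1e12
        val = 0.5 * (
            self.n * (math.log(2.0 * math.pi) + math.log(sigma2) + 1.0)
            + float(logdet.sum())
        )
        return val if np.isfinite(val) else 1e12

    def nll_grad(self, theta: np.ndarray):
        """Profiled negative log-likelihood and its analytic gradient.

        beta is the GLS minimizer of the weighted RSS at the current G, so by
        the envelope theorem only the explicit G-dependence contributes:
        d(r'W^-1 r)/dG = -(Z'W^-1 r)(Z'W^-1 r)' and
        d(logdet W)/dG = Z'W^-1 Z = S - S A S, chained through G = L L' with
        exponentiated diagonal.
        """
        q = self.q
        L = np.zeros((q, q))
        tril = np.tril_indices(q)
        L[tril] = theta
        diag_raw = np.diag(L).copy()
        L[np.diag_indices(q)] = np.exp(diag_raw)
        G = L @ L.T
        try:
            beta, sigma2, logdet, _, A = self.beta_sigma2(G)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(theta)
        val = 0.5 * (
            self.n * (math.log(2.0 * math.pi) + math.log(sigma2) + 1.0)
            + float(logdet.sum())
        )
        if not np.isfinite(val):
            return 1e12, np.zeros_like(theta)
        # u_i = Z_i' W_i^-1 r_i = (I - S_i A_i) v_i with v_i = Z_i'(y_i - X_i beta)
        v = self.Zty - np.einsum("mqp,p->mq", self.ZtX, beta)
        u = v - np.einsum("mqk,mkj,mj->mq", self.S, A, v)
        sum_uu = np.einsum("mq,mk->qk", u, u)
        SAS = np.einsum("mqk,mkj,mjr->mqr", self.S, A, self.S)
        sum_zwz = self.S.sum(axis=0) - SAS.sum(axis=0)
        D = 0.5 * (-sum_uu / sigma2 + sum_zwz)
        grad_L = 2.0 * D @ L
        grad_L[np.diag_indices(q)] *= np.diag(L)  # chain: L_ii = exp(theta_ii)
        return val, grad_L[tril]

    def mom_start(self) -> np.ndarray | None:
        """Method-of-moments start: covariance of per-subject OLS coefficients
        of pooled-OLS residuals on the random basis, scaled by the residual
        variance."""
        q = self.q
        try:
            beta0 = np.linalg.solve(self.XtX, self.Xty)
        except np.linalg.LinAlgError:
            return None
        coefs = []
        sse, n_used = 0.0, 0
        for j in range(self.m):
            S, ZtX, Zty = self.S[j], self.ZtX[j], self.Zty[j]
            nj = int(self.n_per_subject[j])
            if nj < q + 1:
                continue
            rhs = Zty - ZtX @ beta0
            try:
                c = np.linalg.solve(S + 1e-10 * np.eye(q), rhs)
            except np.linalg.LinAlgError:
                continue
            coefs.append(c)
            n_used += nj
        if len(coefs) < 3:
            return None
        C = np.cov(np.asarray(coefs).T)
        C = np.atleast_2d(C)
        # rough residual variance from the pooled OLS fit
        rss0 = self.yty - 2 * beta0 @ self.Xty + beta0 @ self.XtX @ beta0
        sigma2_0 = max(rss0 / self.n * 0.5, 1e-6)
        G0 = C / sigma2_0
        # project to a usable Cholesky factor
        w, V = np.linalg.eigh(0.5 * (G0 + G0.T))
        w = np.clip(w, 1e-6, 1e6)
        L = np.linalg.cholesky(V @ np.diag(w) @ V.T)
        theta = np.zeros(q * (q + 1) // 2)
        tril = np.tril_indices(q)
        Lp = L.copy()
        d = np.clip(np.diag(Lp), 1e-8, None)
        Lp[np.diag_indices(q)] = np.log(d)
        theta[:] = Lp[tril]
        return np.clip(theta, -10.0, 10.0)


def _check_rank(X: np.ndarray, names: tuple[str, ...]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # greedy scan: a column that does not raise the rank is collinear
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            cols = kept + [j]
            if np.linalg.matrix_rank(X[:, cols]) == len(cols):
                kept.append(j)
            else:
                bad.append(names[j])
        raise FitError(f"fixed design is rank-deficient; collinear columns: {bad}")


def fit_lmm(design: DesignMatrices, n_restarts: int = 3,
            maxiter: int = 400) -> FitResult:
    """Fit the linear mixed model by full maximum likelihood.

    Requires at least two subjects and a full-column-rank fixed design.
    Returns a :class:`FitResult`; non-convergence after all restarts is
    reported via ``converged=False`` rather than an exception, and a singular
    (boundary) random covariance is flagged, never re-parameterized.
    """
    if design.n_subjects < 2:
        raise FitError("at least 2 subjects are required")
    _check_rank(design.X, design.fixed_names)

    prof = _Profiled(design)
    q, p = prof.q, prof.p
    n_theta = q * (q + 1) // 2
    tril = np.tril_indices(q)
    diag_mask = np.asarray([i == j for i, j in zip(*tril)])
    bounds = [(-10.0, 10.0) if d else (-1e3, 1e3) for d in diag_mask]

    starts = [np.zeros(n_theta)]
    near_zero = np.zeros(n_theta)
    near_zero[diag_mask] = -4.0
    starts.append(near_zero)
    mom = prof.mom_start()
    if mom is not None:
        starts.append(mom)
    else:
        dispersed = np.zeros(n_theta)
        dispersed[diag_mask] = 1.5
        starts.append(dispersed)
    starts = starts[:max(n_restarts, 1)]

    best = None
    n_used = 0
    any_success = False
    for x0 in starts:
        n_used += 1
        res = optimize.minimize(
            prof.nll_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-8},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    # derivative-free polish: finite-difference quasi-Newton can stall near
    # variance boundaries, Nelder-Mead closes the last ~1e-4 of likelihood
    polish = optimize.minimize(
        prof.nll, best.x, method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-10, "maxfev": 1200},
    )
    if polish.fun < best.fun:
        best = polish

    G = prof.theta_to_G(best.x)
    beta, sigma2, logdet, Sxx, A = prof.beta_sigma2(G)
    loglik = -0.5 * (
        prof.n * (math.log(2.0 * math.pi) + math.log(sigma2) + 1.0)
        + float(logdet.sum())
    )
    Sigma = sigma2 * G

    # SEs from the GLS information: sum_i X_i' V_i^-1 X_i = Sxx / sigma^2
    cov_beta = sigma2 * np.linalg.inv(Sxx)
    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    wald_p = 2.0 * stats.norm.sf(np.abs(z))

    eigs = np.linalg.eigvalsh(Sigma)
    singular = bool(eigs.min() < 1e-8 * max(eigs.max(), 1.0))
    if singular:
        warnings.warn(
            "random-effects covariance is singular (boundary fit)",
            RuntimeWarning, stacklevel=2,
        )

    k = p + n_theta + 1
    aic, bic = information_criteria(loglik, k, prof.n)

    fit = FitResult(
        spec=design.spec, fixed_names=tuple(design.fixed_names),
        beta=beta, se=se, wald_z=z, wald_p=wald_p,
        Sigma=Sigma, sigma2=float(sigma2), loglik=float(loglik),
        k=k, n_obs=prof.n, n_subjects=prof.m,
        aic=aic, bic=bic, r2_marginal=math.nan, r2_conditional=math.nan,
        converged=any_success and np.isfinite(best.fun),
        n_restarts_used=n_used, singular=singular, design=design,
    )
    fit.r2_marginal, fit.r2_conditional = nakagawa_r2(fit, design)
    return fit


def nakagawa_r2(fit: FitResult, design: DesignMatrices) -> tuple[float, float]:
    """Marginal and conditional R^2 (fixed-effect vs fixed+random share).

    sigma2_f is the population variance of the fitted fixed part X beta;
    sigma2_r is the row-average of z' Sigma z (the random-slope extension of
    the intercept-variance formula); the denominator adds the residual
    variance.
    """
    fitted = design.X @ fit.beta
    var_f = float(np.var(fitted))  # population (divide-by-n) convention
    var_r = float(np.mean(np.einsum("nq,qk,nk->n", design.Z, fit.Sigma, design.Z)))
    total = var_f + var_r + fit.sigma2
    if total <= 0:
        raise FitError("total variance is zero; R^2 undefined")
    return var_f / total, (var_f + var_r) / total


def blup_random_effects(fit: FitResult, design: DesignMatrices | None = None
                        ) -> pd.DataFrame:
    """Empirical-Bayes (BLUP) random-effect estimates per subject.

    b_i = Sigma Z_i' V_i^-1 (y_i - X_i beta); returned as a DataFrame indexed
    by subject with one column per random-basis term.
    """
    design = design or fit.design
    prof = _Profiled(design)
    G = fit.Sigma / fit.sigma2
    A, *_ = prof._pieces(G)
    resid_proj = prof.Zty - np.einsum("mqp,p->mq", prof.ZtX, fit.beta)
    b = np.einsum("mqk,mk->mq", A, resid_proj)
    return pd.DataFrame(b, index=pd.Index(prof.subjects, name="subject_id"),
                        columns=list(design.random_names))


def _span_contained(small: np.ndarray, big: np.ndarray) -> bool:
    """True if col-span(small) is contained in col-span(big) on these rows."""
    r_big = np.linalg.matrix_rank(big)
    r_all = np.linalg.matrix_rank(np.hstack([big, small]))
    return r_all == r_big


def lrt(nested: FitResult, full: FitResult) -> LRTResult:
    """Likelihood-ratio (ANOVA) test of two nested ML fits.

    Nesting is verified numerically: the smaller model's fixed and random
    design column spans must lie inside the larger model's, on the data both
    were fitted to, and the parameter counts must increase.  The statistic
    2(ll_full - ll_nested) is floored at zero and referred to the chi-square
    distribution with df = k_full - k_nested.
    """
    if nested.n_obs != full.n_obs:
        raise NonNestedError("fits are on different data (n_obs differs)")
    if nested.k >= full.k:
        raise NonNestedError(
            f"nested model must have fewer parameters "
            f"(k={nested.k} vs k={full.k})"
        )
    if nested.design is not None and full.design is not None:
        if not (_span_contained(nested.design.X, full.design.X)
                and _span_contained(nested.design.Z, full.design.Z)):
            raise NonNestedError(
                f"{nested.spec.name if nested.spec else 'nested'} is not nested "
                f"in {full.spec.name if full.spec else 'full'}"
            )
    else:
        if not set(nested.fixed_names) <= set(full.fixed_names):
            raise NonNestedError("fixed terms of the nested model are not a subset")
    stat = max(0.0, 2.0 * (full.loglik - nested.loglik))
    df = full.k - nested.k
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(stat=stat, df=df, p=p)
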
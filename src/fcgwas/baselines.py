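"""Comparison tests: MANOVA, PCA, GEE, TATES, FC-chi2 and FC-permutation.

All methods share the uniform signature ``fn(Y, x, **options) -> p`` through
the ``METHOD_REGISTRY`` so the simulation harness and the scan treat them as
plug-ins selected by name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special

from .calibration import pvalue_correlation_polynomial
from .core import (
    _check_polymorphic,
    _ols_zp,
    fisher_T,
    marginal_associations,
)
from .exceptions import (
    ConvergenceError,
    DegenerateGenotypeError,
    DomainError,
    SingularMatrixError,
)
from .types import (
    MIN_P,
    CorrelationEstimate,
    as_genotype_vector,
    as_phenotype_matrix,
)

__all__ = [
    "manova_test",
    "pca_test",
    "gee_test",
    "tates_test",
    "simes_test",
    "fc_chi2_test",
    "fc_permutation_test",
    "TatesResult",
]


# ---------------------------------------------------------------------------
# MANOVA (Wilks' Lambda with Rao's F approximation)
# ---------------------------------------------------------------------------

def _wilks_rao(values: np.ndarray, x: np.ndarray) -> float:
    n, m = values.shape
    levels = np.unique(x)
    g = levels.size
    if g < 2:
        raise DegenerateGenotypeError("MANOVA needs at least two genotype groups")
    if n - g <= m:
        raise DomainError("within-group df must exceed the trait count")
    grand = values.mean(axis=0)
    W = np.zeros((m, m))
    B = np.zeros((m, m))
    for lv in levels:
        grp = values[x == lv]
        mu = grp.mean(axis=0)
        dev = grp - mu
        W += dev.T @ dev
        dmu = (mu - grand)[:, None]
        B += grp.shape[0] * (dmu @ dmu.T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        raise SingularMatrixError("singular within-group covariance in MANOVA")
    lam = math.exp(logdet_w - logdet_t)  # Wilks' Lambda in (0, 1]
    p_, q_ = m, g - 1
    v_ = n - g
    denom = p_ * p_ + q_ * q_ - 5
    t_ = math.sqrt((p_ * p_ * q_ * q_ - 4) / denom) if denom > 0 else 1.0
    w_ = v_ + q_ - (p_ + q_ + 1) / 2.0
    df1 = p_ * q_
    df2 = w_ * t_ - (p_ * q_ - 2) / 2.0
    if df2 <= 0:
        raise DomainError("degenerate F approximation (df2 <= 0)")
    lam_t = lam ** (1.0 / t_)
    F = (1.0 - lam_t) / lam_t * df2 / df1
    return float(min(max(special.fdtrc(df1, df2, F), MIN_P), 1.0))


def manova_test(Y, x) -> float:
    """One-way MANOVA of the trait vector on genotype as a categorical factor.

    Wilks' Lambda with Rao's F approximation; exact F in the two-group and
    single-trait cases.  Genotype levels with no members are simply absent.
    """
    pm = as_phenotype_matrix(Y)
    gv = as_genotype_vector(x)
    if pm.n != gv.n:
        raise DomainError("phenotype and genotype lengths differ")
    _check_polymorphic(gv.counts)
    return _wilks_rao(pm.values, gv.counts)


# ---------------------------------------------------------------------------
# PCA first principal component
# ---------------------------------------------------------------------------

def pca_test(Y, x, reference: str = "student") -> float:
    """Slope test of the first principal component on the additive genotype.

    Traits are standardised and PC1 is taken from the correlation matrix, so
    the result is invariant to trait units and to the sign of the component.
    """
    pm = as_phenotype_matrix(Y)
    gv = as_genotype_vector(x)
    if pm.n != gv.n:
        raise DomainError("phenotype and genotype lengths differ")
    _check_polymorphic(gv.counts)
    vals = pm.values
    sd = vals.std(axis=0, ddof=1)
    if np.any(sd == 0):
        from .exceptions import DegeneratePhenotypeError

        raise DegeneratePhenotypeError("constant trait column")
    Z = (vals - vals.mean(axis=0)) / sd
    if pm.m == 1:
        scores = Z[:, 0]
    else:
        corr = np.corrcoef(vals, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(corr)
        scores = Z @ eigvecs[:, -1]
    _, p = _ols_zp(scores[:, None], gv.counts.astype(float), reference)
    return float(p[0])


# ---------------------------------------------------------------------------
# GEE with exchangeable working correlation
# ---------------------------------------------------------------------------

def gee_test(Y, x, maxiter: int = 60, tol: float = 1e-8) -> float:
    """Marginal regression of the stacked traits on a shared genotype slope.

    Identity link, trait-specific intercepts, one genotype coefficient,
    exchangeable (compound-symmetry) working correlation clustered by
    subject, robust sandwich variance; returns the two-sided Wald p for the
    genotype coefficient.  With a single trait this is the OLS slope test
    with a heteroskedasticity-robust variance.
    """
    pm = as_phenotype_matrix(Y)
    gv = as_genotype_vector(x)
    if pm.n != gv.n:
        raise DomainError("phenotype and genotype lengths differ")
    _check_polymorphic(gv.counts)
    vals = pm.values
    n, m = vals.shape
    xf = gv.counts.astype(float)
    sx, sxx = float(xf.sum()), float(xf @ xf)
    ysum = vals.sum(axis=0)
    yx = xf @ vals
    pdim = m + 1
    N = n * m
    alpha = 0.0
    beta = np.zeros(pdim)
    ones = np.ones(m)
    for it in range(maxiter):
        # inverse of the working correlation (1-a)I + aJ, up to the scale phi
        denom = 1.0 + (m - 1) * alpha
        Rinv = (np.eye(m) - (alpha / denom) * np.ones((m, m))) / (1.0 - alpha)
        r1 = Rinv @ ones
        s11 = float(ones @ r1)
        A = np.empty((pdim, pdim))
        A[:m, :m] = n * Rinv
        A[:m, m] = sx * r1
        A[m, :m] = sx * r1
        A[m, m] = sxx * s11
        c = np.empty(pdim)
        c[:m] = Rinv @ ysum
        c[m] = float(r1 @ yx)
        new_beta = np.linalg.solve(A, c)
        resid = vals - new_beta[:m] - np.outer(xf, ones) * new_beta[m]
        phi = float((resid * resid).sum()) / (N - pdim)
        rowsum = resid.sum(axis=1)
        cross = 0.5 * float((rowsum * rowsum).sum() - (resid * resid).sum())
        new_alpha = cross / phi / (n * m * (m - 1) / 2.0 - pdim)
        new_alpha = min(max(new_alpha, -1.0 / (m - 1) + 1e-6), 1.0 - 1e-6) if m > 1 else 0.0
        done = np.max(np.abs(new_beta - beta)) < tol and abs(new_alpha - alpha) < tol
        beta, alpha = new_beta, new_alpha
        if done:
            break
    else:
        raise ConvergenceError(
            f"GEE did not converge within {maxiter} iterations"
        )
    # sandwich variance; the scale phi cancels between bread and meat
    denom = 1.0 + (m - 1) * alpha
    Rinv = (np.eye(m) - (alpha / denom) * np.ones((m, m))) / (1.0 - alpha)
    r1 = Rinv @ ones
    A = np.empty((pdim, pdim))
    A[:m, :m] = n * Rinv
    A[:m, m] = sx * r1
    A[m, :m] = sx * r1
    A[m, m] = sxx * float(ones @ r1)
    resid = vals - beta[:m] - np.outer(xf, ones) * beta[m]
    U = resid @ Rinv
    V = np.column_stack([U, xf * U.sum(axis=1)])
    M = V.T @ V
    Ainv = np.linalg.inv(A)
    cov = Ainv @ M @ Ainv
    se = math.sqrt(cov[m, m])
    z = beta[m] / se
    return float(min(max(2.0 * special.ndtr(-abs(z)), MIN_P), 1.0))


# ---------------------------------------------------------------------------
# TATES (extended Simes with effective numbers of traits)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TatesResult:
    """TATES global p-value with the per-rank effective trait counts."""

    global_p: float
    m_e: float
    per_j: tuple  # ((p_(1), j_e1), (p_(2), j_e2), ...)


def _effective_number(R: np.ndarray, strict: bool = True) -> float:
    """Eigenvalue-based effective number of independent tests.

    Li-Ji style: each eigenvalue contributes 1 if it is >= 1, plus its
    fractional part.  Sums to m for an identity matrix and to ~1 for a
    perfectly correlated block.
    """
    lam = np.linalg.eigvalsh(R)
    if strict and lam.min() < -1e-8 * R.shape[0]:
        raise DomainError("correlation matrix is not positive semi-definite")
    lam = np.clip(lam, 0.0, None)
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


def tates_test(p, R, map_to_pvalue_correlations: bool = True) -> TatesResult:
    """TATES global test from marginal p-values and the trait correlations.

    Sorts the p-values ascending and returns
    ``min_j m_e * p_(j) / j_e`` capped at 1, where m_e (j_e) is the
    effective number of independent tests among all m (the j most
    significant) traits.  The effective numbers are computed from the
    correlation matrix of the two-sided *p-values*, obtained by mapping the
    trait correlations through the quadrature-calibrated polynomial
    :func:`fcgwas.calibration.pvalue_correlation_polynomial` (dependence
    between two-sided p-values is much weaker than between the traits
    themselves).  Set ``map_to_pvalue_correlations=False`` to apply the
    eigenvalue formula to the trait correlations directly.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    R = np.asarray(R, dtype=float)
    m = p.shape[0]
    if R.shape != (m, m):
        raise DomainError("correlation matrix shape does not match p length")
    # validate on the supplied matrix before any mapping
    _effective_number(R)
    strict = True
    if map_to_pvalue_correlations:
        R = pvalue_correlation_polynomial(R)
        np.fill_diagonal(R, 1.0)
        strict = False  # entrywise mapping need not preserve PSD exactly
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    m_e = _effective_number(R, strict=strict)
    per_j = []
    best = np.inf
    for j in range(1, m + 1):
        idx = order[:j]
        j_e = (
            _effective_number(R[np.ix_(idx, idx)], strict=strict)
            if j > 1
            else 1.0
        )
        per_j.append((float(p_sorted[j - 1]), float(j_e)))
        best = min(best, m_e * p_sorted[j - 1] / j_e)
    return TatesResult(
        global_p=float(min(max(best, MIN_P), 1.0)),
        m_e=m_e,
        per_j=tuple(per_j),
    )


def simes_test(p) -> float:
    """Plain Simes global p-value min_j m * p_(j) / j (internal oracle)."""
    p = np.sort(np.atleast_1d(np.asarray(p, dtype=float)))
    m = p.shape[0]
    return float(min(1.0, np.min(m * p / np.arange(1, m + 1))))


# ---------------------------------------------------------------------------
# Fisher combination baselines
# ---------------------------------------------------------------------------

def fc_chi2_test(p) -> float:
    """Fisher combination with the independence chi-squared_{2m} null."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    T = fisher_T(p)
    return float(min(max(special.chdtrc(2 * p.shape[0], T), MIN_P), 1.0))


def fc_permutation_test(
    Y,
    x,
    B: int = 1000,
    rng=None,
    seed: Optional[int] = None,
    reference: str = "student",
) -> float:
    """Permutation p-value for the Fisher statistic T.

    The genotype vector is permuted uniformly at random B times, T is
    recomputed each time, and the add-one estimator
    ``(1 + #{T_b >= T_obs}) / (B + 1)`` is returned, so the smallest
    attainable p is 1/(B+1).
    """
    if B < 1:
        raise DomainError("B must be at least 1")
    pm = as_phenotype_matrix(Y)
    gv = as_genotype_vector(x)
    if pm.n != gv.n:
        raise DomainError("phenotype and genotype lengths differ")
    _check_polymorphic(gv.counts)
    if rng is None:
        rng = np.random.default_rng(seed)
    n, m = pm.n, pm.m
    xf = gv.counts.astype(float)
    marg = marginal_associations(pm, gv, reference=reference)
    T_obs = fisher_T(marg.p)
    xc = xf - xf.mean()
    sxx = float(xc @ xc)
    Yc = pm.values - pm.values.mean(axis=0)
    syy = np.einsum("ij,ij->j", Yc, Yc)
    perms = rng.permuted(np.broadcast_to(xc, (B, n)).copy(), axis=1)
    sxy = perms @ Yc  # (B, m)
    rss = np.maximum(syy[None, :] - sxy * sxy / sxx, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z2 = np.where(rss > 0, (n - 2) * sxy * sxy / (sxx * rss), np.inf)
    if reference == "student":
        pmat = 2.0 * special.stdtr(n - 2, -np.sqrt(z2))
    else:
        pmat = 2.0 * special.ndtr(-np.sqrt(z2))
    T_b = -2.0 * np.log(np.clip(pmat, MIN_P, 1.0)).sum(axis=1)
    return float((1 + int(np.sum(T_b >= T_obs))) / (B + 1))
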
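"""Fisher-combination association tests with a moment-matched gamma null.

For one SNP ``x`` and ``m`` continuous traits, each trait is tested with an
ordinary-least-squares slope test and the marginal two-sided p-values are
combined as ``T = sum_j -2 log p_j``.  Under independence T is chi-squared
with 2m df; correlated traits inflate Var(T), which is estimated as

    sigma^2 = 4m + sum_{j != k} [ f(r_jk) - (c1/n) (1 - r_jk^2)^2 ]

where f is the calibrated even polynomial in the (bias-corrected) trait
correlation and the subtracted term removes the estimation bias of plugging
a sample correlation into f.  The global p-value is the survival function of
a gamma distribution matching (E[T], Var[T]).

The trait correlations depend only on the phenotype matrix, so a scan over
many SNPs estimates them once and reuses them for every SNP.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
from scipy import special, stats

from .calibration import DeltaPolynomial, delta_polynomial
from .exceptions import (
    DegenerateGenotypeError,
    DegeneratePhenotypeError,
    DomainError,
    InsufficientSampleError,
)
from .types import (
    MIN_P,
    CombinedTestResult,
    CorrelationEstimate,
    GammaNull,
    GenotypeVector,
    MarginalResults,
    PhenotypeMatrix,
    as_genotype_vector,
    as_phenotype_matrix,
)

__all__ = [
    "marginal_association",
    "marginal_associations",
    "fisher_T",
    "bias_corrected_correlation",
    "kendall_to_pearson",
    "estimate_correlations",
    "delta_unbiased",
    "variance_T",
    "gamma_null",
    "gamma_global_pvalue",
    "fc_test",
]

#: Floor applied to the estimated Var(T); guards against pathological
#: negative sums from the bias correction at tiny n with near-zero correlations.
SIGMA2_FLOOR = 1e-8


def _check_polymorphic(counts: np.ndarray) -> None:
    if counts.size == 0 or counts.min() == counts.max():
        raise DegenerateGenotypeError(
            "degenerate genotype: monomorphic SNP, no slope identifiable"
        )


def _ols_zp(Y: np.ndarray, x: np.ndarray, reference: str):
    """Vectorised slope z-statistics and two-sided p-values, one per column.

    z is the OLS slope divided by its standard error (residual df n-2).
    reference='student' uses the exact t_{n-2} tail (uniform null p under
    Gaussian errors); 'normal' uses 2*Phi(-|z|).
    """
    n = x.shape[0]
    if n < 4:
        raise InsufficientSampleError("at least 4 subjects are required")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    Yc = Y - Y.mean(axis=0)
    syy = np.einsum("ij,ij->j", Yc, Yc)
    if np.any(syy <= 0):
        j = int(np.argmax(syy <= 0))
        raise DegeneratePhenotypeError(
            f"degenerate phenotype: column {j} has zero variance"
        )
    b = (xc @ Yc) / sxx
    rss = np.maximum(syy - b * b * sxx, 0.0)
    se = np.sqrt(rss / (n - 2) / sxx)
    with np.errstate(divide="ignore"):
        z = np.where(se > 0, b / np.where(se > 0, se, 1.0), np.inf * np.sign(b))
    if reference == "student":
        p = 2.0 * special.stdtr(n - 2, -np.abs(z))
    elif reference == "normal":
        p = 2.0 * special.ndtr(-np.abs(z))
    else:
        raise DomainError("reference must be 'student' or 'normal'")
    return z, np.clip(p, MIN_P, 1.0)


def marginal_association(
    y, x, reference: str = "student"
) -> tuple[float, float]:
    """Additive-model slope test of one trait against one SNP.

    Returns ``(z, p)`` for the model ``y ~ intercept + x``: z is the OLS
    slope over its standard error and p the two-sided tail probability.
    """
    gv = as_genotype_vector(x)
    _check_polymorphic(gv.counts)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    if y.shape[0] != gv.n:
        raise DomainError("phenotype and genotype lengths differ")
    z, p = _ols_zp(y, gv.counts.astype(float), reference)
    return float(z[0]), float(p[0])


def marginal_associations(
    Y: Union[PhenotypeMatrix, np.ndarray], x, reference: str = "student"
) -> MarginalResults:
    """Per-trait slope tests for all columns of a phenotype matrix."""
    pm = as_phenotype_matrix(Y)
    gv = as_genotype_vector(x)
    _check_polymorphic(gv.counts)
    if pm.n != gv.n:
        raise DomainError("phenotype and genotype lengths differ")
    z, p = _ols_zp(pm.values, gv.counts.astype(float), reference)
    return MarginalResults(z=z, p=p, reference=reference)


def fisher_T(p) -> float:
    """Fisher combination statistic ``T = sum_j -2 ln p_j``."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    return float(-2.0 * np.log(np.maximum(p, MIN_P)).sum())


def bias_corrected_correlation(rho_hat, n: int):
    """Small-sample bias correction rho*(1 + (1-rho^2)/(2(n-3))).

    Clamped to [-1, 1]: the raw correction can exceed 1 in magnitude when
    |rho| is close to 1 at small n.
    """
    if n < 4:
        raise InsufficientSampleError(
            "insufficient sample size: bias correction requires n >= 4"
        )
    rho = np.asarray(rho_hat, dtype=float)
    if np.any(np.abs(rho) > 1 + 1e-12):
        raise DomainError("correlation must lie in [-1, 1]")
    out = np.clip(rho * (1.0 + (1.0 - rho * rho) / (2.0 * (n - 3))), -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def kendall_to_pearson(tau):
    """Map Kendall's tau to the Pearson correlation of a bivariate normal:
    rho = sin(pi*tau/2)."""
    tau = np.asarray(tau, dtype=float)
    if np.any(np.abs(tau) > 1 + 1e-12):
        raise DomainError("tau must lie in [-1, 1]")
    out = np.sin(0.5 * np.pi * tau)
    return float(out) if out.ndim == 0 else out


def _raw_correlation(values: np.ndarray, method: str) -> np.ndarray:
    n, m = values.shape
    sd = values.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise DegeneratePhenotypeError(
            f"degenerate phenotype: trait column {j} is constant"
        )
    if method == "pearson":
        raw = np.corrcoef(values, rowvar=False)
    elif method == "kendall":
        raw = np.eye(m)
        for j in range(m):
            for k in range(j + 1, m):
                # tie-adjusted tau-b: phenotype data contain ties
                tau = stats.kendalltau(values[:, j], values[:, k]).statistic
                raw[j, k] = raw[k, j] = np.sin(0.5 * np.pi * tau)
    else:
        raise DomainError("correlation method must be 'pearson' or 'kendall'")
    return np.clip(raw, -1.0, 1.0)


def estimate_correlations(
    Y: Union[PhenotypeMatrix, np.ndarray], method: str = "pearson"
) -> CorrelationEstimate:
    """Pairwise trait correlations, raw and bias-corrected.

    Depends only on the phenotype matrix: compute once per trait set and
    reuse across all SNPs of a scan.
    """
    pm = as_phenotype_matrix(Y)
    if pm.m < 2:
        raise DomainError("correlation estimation needs at least two traits")
    raw = _raw_correlation(pm.values, method)
    corrected = bias_corrected_correlation(raw, pm.n)
    np.fill_diagonal(corrected, 1.0)
    return CorrelationEstimate(
        raw=raw, corrected=corrected, method=method, n_used=pm.n
    )


def delta_unbiased(
    r_hat, n: int, poly: Optional[DeltaPolynomial] = None
):
    """Bias-removed estimator of delta: ``f(r) - (c1/n) (1 - r^2)^2``.

    The subtracted term is the leading-order (Taylor) bias of evaluating the
    calibrated polynomial at a noisy correlation estimate; it vanishes at
    |r| = 1 and as n grows.
    """
    if n < 4:
        raise InsufficientSampleError("bias removal requires n >= 4")
    r = np.asarray(r_hat, dtype=float)
    f = delta_polynomial(r, poly)
    c1 = (poly.coefficients if poly else DeltaPolynomial().coefficients)[0]
    out = f - (c1 / n) * (1.0 - r * r) ** 2
    return float(out) if np.ndim(out) == 0 else out


def variance_T(
    corr: CorrelationEstimate,
    poly: Optional[DeltaPolynomial] = None,
    bias_correction: bool = True,
) -> float:
    """Estimate Var(T) = 4m + sum over ordered trait pairs of delta.

    Each unordered pair is counted twice.  The result is floored at a small
    positive constant so the gamma null is always defined.
    """
    m = corr.m
    if m == 1:
        return 4.0
    iu = np.triu_indices(m, 1)
    r = corr.corrected[iu]
    if bias_correction:
        d = delta_unbiased(r, corr.n_used, poly)
    else:
        d = delta_polynomial(r, poly)
    sigma2 = 4.0 * m + 2.0 * float(np.sum(d))
    return max(sigma2, SIGMA2_FLOOR)


def gamma_null(m: int, sigma2: float) -> GammaNull:
    """Moment-matched gamma null with mean 2m and variance sigma2."""
    if m < 1:
        raise DomainError("m must be at least 1")
    if sigma2 <= 0:
        raise DomainError("sigma2 must be positive")
    return GammaNull(mu=2.0 * m, sigma2=float(sigma2))


def gamma_global_pvalue(T: float, null: GammaNull) -> float:
    """Survival function of the moment-matched gamma at T."""
    if T < 0:
        raise DomainError("T must be non-negative")
    p = float(special.gammaincc(null.shape, T / null.scale))
    return min(max(p, MIN_P), 1.0)


def fc_test(
    Y: Union[PhenotypeMatrix, np.ndarray],
    x,
    method: str = "pearson",
    corr: Optional[CorrelationEstimate] = None,
    poly: Optional[DeltaPolynomial] = None,
    reference: str = "student",
) -> CombinedTestResult:
    """Fisher-combination test with the gamma (Brown-type) null.

    ``method`` selects how the trait correlations are estimated ("pearson"
    or "kendall") when ``corr`` is not supplied.  A supplied ``corr`` is
    reused as-is, which is what makes genome-wide scans cheap: only the
    marginal tests depend on the SNP.
    """
    pm = as_phenotype_matrix(Y)
    gv = as_genotype_vector(x)
    marg = marginal_associations(pm, gv, reference=reference)
    T = fisher_T(marg.p)
    if pm.m == 1:
        sigma2 = 4.0
    else:
        if corr is None:
            corr = estimate_correlations(pm, method=method)
        elif corr.m != pm.m:
            raise DomainError(
                "supplied correlation estimate does not match trait count"
            )
        sigma2 = variance_T(corr, poly)
    null = gamma_null(pm.m, sigma2)
    p_global = gamma_global_pvalue(T, null)
    return CombinedTestResult(
        T=T,
        global_p=p_global,
        null=null,
        method=f"fc-{method}",
        marginals=marg,
        snp_id=gv.snp_id,
    )
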
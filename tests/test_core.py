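"""Unit and property tests for the Fisher-combination core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import fcgwas as fg
from fcgwas.core import _ols_zp, variance_T
from fcgwas.exceptions import (
    DegenerateGenotypeError,
    DegeneratePhenotypeError,
    DomainError,
    InsufficientSampleError,
)
from fcgwas.types import CorrelationEstimate


# ---------------------------------------------------------------------------
# marginal association
# ---------------------------------------------------------------------------

def test_marginal_monomorphic_genotype_rejected():
    y = np.arange(10.0)
    with pytest.raises(DegenerateGenotypeError):
        fg.marginal_association(y, np.ones(10, dtype=int))


def test_marginal_constant_phenotype_rejected(rng):
    x = rng.binomial(2, 0.5, 20)
    with pytest.raises(DegeneratePhenotypeError):
        fg.marginal_association(np.full(20, 3.0), x)


def test_marginal_perfect_fit_underflows(rng):
    x = rng.binomial(2, 0.25, 100)
    z, p = fg.marginal_association(x.astype(float), x)
    assert p <= 1e-300
    assert not np.isfinite(z) or abs(z) > 1e8


def test_marginal_null_p_uniform(rng):
    """Fraction of null p below 0.05 matches the nominal level (Monte Carlo)."""
    x = rng.binomial(2, 0.25, 100).astype(float)
    Y = rng.standard_normal((100, 10_000))
    _, p = _ols_zp(Y, x, "student")
    frac = float(np.mean(p < 0.05))
    assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 10_000)


def test_marginal_normal_reference_identity(rng):
    """Under the normal reference, p = 2*Phi(-|z|) to machine precision."""
    x = rng.binomial(2, 0.25, 50)
    y = rng.standard_normal(50)
    z, p = fg.marginal_association(y, x, reference="normal")
    assert p == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-15)


# ---------------------------------------------------------------------------
# Fisher statistic and correlation helpers
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p, expected",
    [
        ((1.0, 1.0, 1.0, 1.0, 1.0), 0.0),
        ((np.exp(-1.0),), 2.0),
        ((0.05, 0.01), 15.2018),
    ],
)
def test_fisher_T_values(p, expected):
    assert fg.fisher_T(p) == pytest.approx(expected, abs=1e-4)


@pytest.mark.parametrize("bad", [(0.0,), (1.5,), (-0.1, 0.5)])
def test_fisher_T_domain(bad):
    with pytest.raises(DomainError):
        fg.fisher_T(bad)


@pytest.mark.parametrize(
    "rho, n, expected",
    [(0.0, 10, 0.0), (1.0, 10, 1.0), (-1.0, 10, -1.0), (0.5, 103, 0.501875)],
)
def test_bias_corrected_correlation_values(rho, n, expected):
    assert fg.bias_corrected_correlation(rho, n) == pytest.approx(
        expected, abs=1e-12
    )


def test_bias_corrected_correlation_needs_n4():
    with pytest.raises(InsufficientSampleError):
        fg.bias_corrected_correlation(0.5, 3)


@given(
    rho=st.floats(-1.0, 1.0),
    n=st.integers(4, 10_000),
)
def test_bias_correction_clamped_and_magnifying(rho, n):
    """Output stays in [-1,1], keeps the sign and never shrinks |rho|."""
    r = fg.bias_corrected_correlation(rho, n)
    assert -1.0 <= r <= 1.0
    assert np.sign(r) == np.sign(rho) or rho == 0
    assert abs(r) >= abs(rho) - 1e-15


@pytest.mark.parametrize(
    "tau, expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 0.70711)]
)
def test_kendall_to_pearson(tau, expected):
    assert fg.kendall_to_pearson(tau) == pytest.approx(expected, abs=1e-5)


def test_kendall_to_pearson_domain():
    with pytest.raises(DomainError):
        fg.kendall_to_pearson(1.2)


def test_estimate_correlations_duplicate_column(rng):
    y = rng.standard_normal(50)
    Y = np.column_stack([y, y, rng.standard_normal(50)])
    est = fg.estimate_correlations(Y)
    assert est.raw[0, 1] == pytest.approx(1.0)
    assert est.corrected[0, 1] == pytest.approx(1.0)


def test_estimate_correlations_consistency(rng):
    """Pearson and Kendall-based estimates agree with the generating rho."""
    n, rho = 10_000, 0.5
    L = np.linalg.cholesky([[1, rho], [rho, 1]])
    Y = rng.standard_normal((n, 2)) @ L.T
    pear = fg.estimate_correlations(Y, method="pearson")
    kend = fg.estimate_correlations(Y, method="kendall")
    assert pear.corrected[0, 1] == pytest.approx(rho, abs=0.03)
    assert kend.corrected[0, 1] == pytest.approx(
        pear.corrected[0, 1], abs=0.03
    )


def test_estimate_correlations_constant_trait(rng):
    Y = np.column_stack([rng.standard_normal(20), np.full(20, 2.0)])
    with pytest.raises(DegeneratePhenotypeError, match="column 1"):
        fg.estimate_correlations(Y)


# ---------------------------------------------------------------------------
# variance of T and the gamma null
# ---------------------------------------------------------------------------

def _corr(corrected: np.ndarray, n: int) -> CorrelationEstimate:
    raw = corrected.copy()
    return CorrelationEstimate(raw=raw, corrected=corrected, method="pearson", n_used=n)


def test_delta_unbiased_values():
    assert fg.delta_unbiased(1.0, 100) == pytest.approx(3.9979, abs=1e-4)
    assert fg.delta_unbiased(-1.0, 7) == pytest.approx(3.9979, abs=1e-4)
    assert fg.delta_unbiased(0.0, 100) == pytest.approx(-0.039081, abs=1e-6)
    assert fg.delta_unbiased(0.5, 10**12) == pytest.approx(
        fg.delta_polynomial(0.5), abs=1e-10
    )


def test_variance_T_independence():
    m = 5
    est = _corr(np.eye(m), 100)
    est = CorrelationEstimate(
        raw=np.eye(m), corrected=np.eye(m), method="pearson", n_used=100
    )
    # zero off-diagonals with the bias term suppressed: exactly 4m
    zero = CorrelationEstimate(
        raw=np.eye(m), corrected=np.eye(m), method="pearson", n_used=100
    )
    assert variance_T(zero, bias_correction=False) == pytest.approx(20.0)
    # with the bias term: 4m - m(m-1) * c1/n
    assert variance_T(zero) == pytest.approx(20 - 20 * 0.039081, abs=1e-4)


def test_variance_T_perfect_pair():
    corrected = np.array([[1.0, 1.0], [1.0, 1.0]])
    est = CorrelationEstimate(
        raw=corrected, corrected=corrected, method="pearson", n_used=10**9
    )
    assert variance_T(est) == pytest.approx(8 + 2 * 3.9979, abs=1e-3)


def test_variance_T_monotone_in_common_correlation():
    m, n = 4, 200
    values = []
    for r in np.linspace(0.0, 1.0, 21):
        corrected = np.full((m, m), r)
        np.fill_diagonal(corrected, 1.0)
        est = CorrelationEstimate(
            raw=corrected, corrected=corrected, method="pearson", n_used=n
        )
        values.append(variance_T(est))
    assert np.all(np.diff(values) >= -1e-12)


@given(
    r=st.floats(-0.999, 0.999),
    n=st.integers(4, 500),
    m=st.integers(2, 8),
)
def test_variance_T_positive_for_exchangeable_inputs(r, n, m):
    lo = -1.0 / (m - 1) + 1e-6
    r = max(r, lo)
    corrected = np.full((m, m), r)
    np.fill_diagonal(corrected, 1.0)
    est = CorrelationEstimate(
        raw=corrected, corrected=corrected, method="pearson", n_used=n
    )
    assert variance_T(est) >= 1e-8


def test_gamma_null_identities():
    null = fg.gamma_null(5, 20.0)
    assert (null.shape, null.scale) == (5.0, 2.0)  # chi-squared_10
    null = fg.gamma_null(1, 4.0)
    assert (null.shape, null.scale) == (1.0, 2.0)
    null = fg.gamma_null(5, 30.0)
    assert null.shape * null.scale == pytest.approx(null.mu)
    assert null.shape * null.scale**2 == pytest.approx(null.sigma2)
    with pytest.raises(DomainError):
        fg.gamma_null(5, 0.0)


def test_gamma_global_pvalue():
    null10 = fg.gamma_null(5, 20.0)
    assert fg.gamma_global_pvalue(0.0, null10) == 1.0
    # chi-squared_10 special case, checked against an independent chi2 routine
    assert fg.gamma_global_pvalue(10.0, null10) == pytest.approx(
        stats.chi2.sf(10.0, 10), abs=1e-3
    )
    exp_null = fg.gamma_null(1, 4.0)
    for T in (0.5, 2.0, 9.0):
        assert fg.gamma_global_pvalue(T, exp_null) == pytest.approx(
            np.exp(-T / 2), rel=1e-10
        )
    with pytest.raises(DomainError):
        fg.gamma_global_pvalue(-1.0, null10)


# ---------------------------------------------------------------------------
# the combined test
# ---------------------------------------------------------------------------

def test_fc_test_single_trait_reduces_to_marginal(rng):
    """With m=1 the gamma null is exponential and the global p equals the
    marginal p exactly."""
    for _ in range(5):
        x = rng.binomial(2, 0.3, 60)
        if x.min() == x.max():
            continue
        y = rng.standard_normal(60) + 0.2 * x
        res = fg.fc_test(y[:, None], x)
        _, p_marg = fg.marginal_association(y, x)
        assert abs(res.global_p - p_marg) < 1e-12


def test_fc_test_independence_reduces_to_chi2():
    """Zero correlations with the bias term off give the chi-squared_{2m} null."""
    m = 5
    est = CorrelationEstimate(
        raw=np.eye(m), corrected=np.eye(m), method="pearson", n_used=100
    )
    sigma2 = variance_T(est, bias_correction=False)
    null = fg.gamma_null(m, sigma2)
    for T in np.linspace(0.0, 60.0, 25):
        assert fg.gamma_global_pvalue(T, null) == pytest.approx(
            stats.chi2.sf(T, 2 * m), abs=1e-10
        )


def test_fc_test_reuses_supplied_correlations(trait_data):
    Y, x = trait_data
    corr = fg.estimate_correlations(Y, method="pearson")
    res_pre = fg.fc_test(Y, x, corr=corr)
    res_fresh = fg.fc_test(Y, x, method="pearson")
    assert res_pre.global_p == res_fresh.global_p
    # a deliberately different correlation estimate changes the answer
    ident = CorrelationEstimate(
        raw=np.eye(Y.m), corrected=np.eye(Y.m), method="pearson", n_used=Y.n
    )
    res_ident = fg.fc_test(Y, x, corr=ident)
    assert res_ident.global_p != res_fresh.global_p
    assert res_ident.T == res_fresh.T


def test_fc_test_statistic_matches_marginals(trait_data):
    Y, x = trait_data
    res = fg.fc_test(Y, x)
    assert res.T == pytest.approx(
        float(-2 * np.log(res.marginals.p).sum()), rel=1e-12
    )
    assert 0 < res.global_p <= 1


def test_fc_test_monomorphic(trait_data):
    Y, _ = trait_data
    with pytest.raises(DegenerateGenotypeError):
        fg.fc_test(Y, np.zeros(Y.n, dtype=int))


def test_fc_test_dimension_mismatch(trait_data):
    Y, x = trait_data
    bad = CorrelationEstimate(
        raw=np.eye(3), corrected=np.eye(3), method="pearson", n_used=Y.n
    )
    with pytest.raises(DomainError):
        fg.fc_test(Y, x, corr=bad)
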
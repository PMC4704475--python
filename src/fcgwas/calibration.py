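"""Calibration of the covariance delta(rho) between dependent -2*log(p) terms.

Under a bivariate standard Gaussian pair (z_j, z_k) with correlation rho,
the two-sided p-values p = 2*Phi(-|z|) are uniform but dependent, and

    delta(rho) = cov(-2 log p_j, -2 log p_k)
               = 4 * E[ log(2 Phi(-|z_j|)) * log(2 Phi(-|z_k|)) ] - 4.

``delta_numeric`` evaluates this expectation by nested adaptive quadrature;
``fit_delta_polynomial`` least-squares fits the even polynomial

    f(rho) = c1 rho^2 + c2 rho^4 + c3 rho^6 + c4 rho^8 + c5 rho^10

on the grid rho = -0.99(0.01)0.99.  The package ships a fixed reference
calibration (``DEFAULT_COEFFICIENTS``) so downstream results are bit-stable
across quadrature backends; refit coefficients can be substituted anywhere a
``DeltaPolynomial`` is accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import IntegrationWarning, quad
from scipy.special import log_ndtr

from .exceptions import DomainError

__all__ = [
    "DeltaPolynomial",
    "DEFAULT_COEFFICIENTS",
    "DELTA_AT_UNITY",
    "delta_numeric",
    "delta_polynomial",
    "fit_delta_polynomial",
]

#: Reference calibration of (c1..c5); reproducible via fit_delta_polynomial.
DEFAULT_COEFFICIENTS = (3.9081, 0.0313, 0.1022, -0.1378, 0.0941)

#: Analytic limit of delta as |rho| -> 1: Var(-2 log U) = 4 for U ~ Uniform(0,1).
DELTA_AT_UNITY = 4.0

# Quadrature domain: |z| <= 8.5.  The integrand carries a Gaussian weight, so
# the truncated tails contribute < 1e-13 (phi(8.5) ~ 4e-16, log-factor ~ 40).
_ZMAX = 8.5
_LOG2 = np.log(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _g(z: float) -> float:
    """log(2*Phi(-|z|)) = log of the two-sided p-value at z."""
    return _LOG2 + log_ndtr(-abs(z))


def _phi(z: float) -> float:
    return _INV_SQRT_2PI * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class DeltaPolynomial:
    """A fitted (or reference) even polynomial approximating delta(rho)."""

    coefficients: tuple = DEFAULT_COEFFICIENTS
    max_residual: float = 0.0
    grid: Optional[np.ndarray] = None

    def __post_init__(self):
        coef = tuple(float(c) for c in self.coefficients)
        if len(coef) != 5:
            raise DomainError("exactly five even-power coefficients expected")
        object.__setattr__(self, "coefficients", coef)

    def __call__(self, r):
        return delta_polynomial(r, self)


def delta_polynomial(r, poly: Optional[DeltaPolynomial] = None):
    """Evaluate c1 r^2 + c2 r^4 + c3 r^6 + c4 r^8 + c5 r^10.

    Accepts scalars or arrays; |r| must not exceed 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise DomainError("delta polynomial argument must lie in [-1, 1]")
    c1, c2, c3, c4, c5 = (poly or _DEFAULT_POLY).coefficients
    r2 = r * r
    out = r2 * (c1 + r2 * (c2 + r2 * (c3 + r2 * (c4 + r2 * c5))))
    return float(out) if out.ndim == 0 else out


_DEFAULT_POLY = DeltaPolynomial()


def delta_numeric(rho: float, tol: float = 1e-6) -> float:
    """Covariance of the two -2*log(p) terms at correlation ``rho``.

    Nested adaptive quadrature: conditioning on z_j, the inner integral
    averages log(2*Phi(-|rho*z_j + sqrt(1-rho^2)*u|)) over u ~ N(0,1), with a
    breakpoint where the argument changes sign; the outer integral exploits
    the even symmetry of the integrand in z_j.  Absolute error is held well
    below ``tol``.

    For |rho| = 1 use the analytic limit ``DELTA_AT_UNITY`` instead.
    """
    rho = float(rho)
    if abs(rho) >= 1:
        raise DomainError(
            "delta_numeric requires |rho| < 1; the |rho|=1 limit is 4"
        )
    if tol <= 0:
        raise DomainError("tol must be positive")
    s = np.sqrt(1.0 - rho * rho)
    inner_eps = max(tol * 1e-3, 1e-13)

    def inner(z1: float) -> float:
        a = rho * z1
        u0 = -a / s
        pts = [u0] if -_ZMAX < u0 < _ZMAX else None
        val, _ = quad(
            lambda u: _phi(u) * _g(a + s * u),
            -_ZMAX,
            _ZMAX,
            epsabs=inner_eps,
            epsrel=0.0,
            limit=300,
            points=pts,
        )
        return val

    with warnings.catch_warnings():
        # epsabs is deliberately pushed near machine precision; QUADPACK's
        # round-off warning is expected and harmless here.
        warnings.simplefilter("ignore", IntegrationWarning)
        half, _ = quad(
            lambda z: _phi(z) * _g(z) * inner(z),
            0.0,
            _ZMAX,
            epsabs=tol * 0.05,
            epsrel=0.0,
            limit=300,
        )
    return 4.0 * (2.0 * half) - 4.0


#: Even-polynomial coefficients (of rho^2..rho^10) mapping a trait
#: correlation to the correlation between the two-sided p-values; fitted to
#: pvalue_correlation on the 0..0.99 grid (max residual ~1.3e-3).
PVALUE_CORRELATION_COEFFICIENTS = (
    0.615886, 0.096898, 0.516038, -0.664907, 0.431492
)


def pvalue_correlation(rho: float, tol: float = 1e-8) -> float:
    """corr(p_j, p_k) for two-sided p-values under bivariate normal z's.

    With p = 2*Phi(-|z|) uniform on (0,1), E[p] = 1/2 and Var(p) = 1/12, so
    the correlation is 12*(E[p_j p_k] - 1/4); the expectation is evaluated
    by the same nested adaptive quadrature as :func:`delta_numeric`.  An
    even function of rho.  Used by the TATES effective-number computation,
    which operates on p-value (not trait) correlations.
    """
    rho = float(rho)
    if abs(rho) > 1:
        raise DomainError("correlation must lie in [-1, 1]")
    if abs(rho) == 1:
        return 1.0  # the two p-values coincide
    s = np.sqrt(1.0 - rho * rho)
    from scipy.special import ndtr

    def inner(z1: float) -> float:
        a = rho * z1
        u0 = -a / s
        pts = [u0] if -_ZMAX < u0 < _ZMAX else None
        val, _ = quad(
            lambda u: _phi(u) * ndtr(-abs(a + s * u)),
            -_ZMAX,
            _ZMAX,
            epsabs=max(tol * 1e-2, 1e-13),
            epsrel=0.0,
            limit=300,
            points=pts,
        )
        return val

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IntegrationWarning)
        half, _ = quad(
            lambda z: _phi(z) * ndtr(-abs(z)) * inner(z),
            0.0,
            _ZMAX,
            epsabs=tol,
            epsrel=0.0,
            limit=300,
        )
    return 12.0 * (4.0 * (2.0 * half) - 0.25)


def pvalue_correlation_polynomial(r):
    """Polynomial approximation of :func:`pvalue_correlation` (vectorised)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise DomainError("correlation must lie in [-1, 1]")
    c1, c2, c3, c4, c5 = PVALUE_CORRELATION_COEFFICIENTS
    r2 = r * r
    out = r2 * (c1 + r2 * (c2 + r2 * (c3 + r2 * (c4 + r2 * c5))))
    return float(out) if out.ndim == 0 else out


def default_grid(step: float = 0.01, rho_max: float = 0.99) -> np.ndarray:
    """Symmetric fitting grid -rho_max .. rho_max with the given step."""
    if step <= 0:
        raise DomainError("step must be positive")
    k = round(rho_max / step)
    if abs(k * step - rho_max) > 1e-9:
        raise DomainError("step must divide the grid evenly")
    return np.round(np.arange(-k, k + 1) * step, 10)


def fit_even_polynomial(grid, values) -> tuple:
    """Zero-intercept least squares of the 5-term even polynomial.

    Returns ``(coefficients, max_abs_residual)``.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    design = np.column_stack([grid ** (2 * k) for k in range(1, 6)])
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    residuals = design @ coef - values
    return tuple(coef), float(np.abs(residuals).max())


def fit_delta_polynomial(step: float = 0.01, tol: float = 1e-6) -> DeltaPolynomial:
    """Refit the even polynomial to delta(rho) on the -0.99..0.99 grid.

    Plain (unweighted) least squares with zero intercept; records the maximum
    absolute residual over the grid.
    """
    grid = default_grid(step=step)
    values = np.array([delta_numeric(r, tol=tol) for r in grid])
    coef, max_residual = fit_even_polynomial(grid, values)
    return DeltaPolynomial(
        coefficients=coef, max_residual=max_residual, grid=grid
    )
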
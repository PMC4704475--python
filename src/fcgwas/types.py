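"""Core in-memory containers for multivariate-phenotype association testing.

The model throughout is ``Y = x beta + eps`` for ``n`` subjects, ``m``
continuous traits and a single SNP coded additively (allele counts 0/1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import DomainError, InsufficientSampleError

__all__ = [
    "PhenotypeMatrix",
    "GenotypeVector",
    "MarginalResults",
    "CorrelationEstimate",
    "GammaNull",
    "CombinedTestResult",
]

#: Smallest p-value carried through logarithms; guards -2*log(p) overflow.
MIN_P = 1e-300


@dataclass(frozen=True)
class PhenotypeMatrix:
    """An ``n x m`` matrix of continuous trait values, complete cases only.

    Parameters
    ----------
    values
        Real matrix with one row per subject, one column per trait.
    trait_names
        Column labels; generated as ``trait1..traitm`` when omitted.
    subject_ids
        Optional subject labels retained after complete-case filtering.
    kept_rows
        Optional 0-based positions of the retained rows in the source file,
        used to align streamed genotype vectors.
    """

    values: np.ndarray
    trait_names: tuple = ()
    subject_ids: Optional[tuple] = None
    kept_rows: Optional[np.ndarray] = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise DomainError("phenotype values must be a 2-D matrix")
        n, m = values.shape
        if m < 1:
            raise DomainError("at least one trait is required")
        if n < 4:
            raise InsufficientSampleError(
                f"phenotype matrix has {n} complete rows; at least 4 are "
                "required (the correlation bias correction divides by n-3)"
            )
        if not np.all(np.isfinite(values)):
            raise DomainError(
                "phenotype matrix contains missing or non-finite values; "
                "apply complete-case filtering first"
            )
        object.__setattr__(self, "values", values)
        names = tuple(self.trait_names) or tuple(
            f"trait{j + 1}" for j in range(m)
        )
        if len(names) != m:
            raise DomainError("trait_names length does not match column count")
        object.__setattr__(self, "trait_names", names)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GenotypeVector:
    """Additively coded allele counts (0, 1 or 2) for one SNP."""

    counts: np.ndarray
    snp_id: Optional[str] = None

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise DomainError("genotype counts must be a 1-D vector")
        if not np.isin(counts, (0, 1, 2)).all():
            raise DomainError("genotype entries must be allele counts in {0,1,2}")
        object.__setattr__(self, "counts", counts.astype(np.int8))

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def is_polymorphic(self) -> bool:
        c = self.counts
        return bool(c.size) and c.min() != c.max()


@dataclass(frozen=True)
class MarginalResults:
    """Per-trait association statistics ``z`` and two-sided p-values."""

    z: np.ndarray
    p: np.ndarray
    reference: str = "student"  # "student" (t_{n-2}) or "normal"

    def __post_init__(self):
        z = np.atleast_1d(np.asarray(self.z, dtype=float))
        p = np.atleast_1d(np.asarray(self.p, dtype=float))
        if z.shape != p.shape:
            raise DomainError("z and p must have the same length")
        if np.any(p <= 0) or np.any(p > 1):
            raise DomainError("marginal p-values must lie in (0, 1]")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "p", p)

    @property
    def m(self) -> int:
        return self.p.shape[0]


@dataclass(frozen=True)
class CorrelationEstimate:
    """Pairwise trait correlations, raw and bias-corrected.

    ``raw`` holds the Pearson product-moment correlations, or Kendall's
    tau-b mapped through ``rho = sin(pi*tau/2)``.  ``corrected`` applies the
    small-sample bias correction ``rho*(1 + (1-rho^2)/(2(n-3)))`` to every
    off-diagonal entry, clamped to [-1, 1].
    """

    raw: np.ndarray
    corrected: np.ndarray
    method: str
    n_used: int

    def __post_init__(self):
        raw = np.asarray(self.raw, dtype=float)
        corrected = np.asarray(self.corrected, dtype=float)
        for name, mat in (("raw", raw), ("corrected", corrected)):
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                raise DomainError(f"{name} correlation matrix must be square")
            if not np.allclose(mat, mat.T, atol=1e-12):
                raise DomainError(f"{name} correlation matrix must be symmetric")
            if not np.allclose(np.diag(mat), 1.0, atol=1e-12):
                raise DomainError(f"{name} correlation matrix needs a unit diagonal")
            if np.any(np.abs(mat) > 1 + 1e-12):
                raise DomainError(f"{name} correlation entries must lie in [-1,1]")
        if self.method not in ("pearson", "kendall"):
            raise DomainError("correlation method must be 'pearson' or 'kendall'")
        object.__setattr__(self, "raw", raw)
        object.__setattr__(self, "corrected", corrected)

    @property
    def m(self) -> int:
        return self.raw.shape[0]


@dataclass(frozen=True)
class GammaNull:
    """Moment-matched gamma null for the Fisher statistic T.

    Matches ``E[T] = mu = 2m`` and ``Var[T] = sigma2``; equivalently a scaled
    chi-squared ``gamma * chisq_v`` with ``v = 2 mu^2/sigma2`` and
    ``gamma = sigma2/(2 mu)``.  ``shape = v/2`` and ``scale = 2 gamma``.
    """

    mu: float
    sigma2: float

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise DomainError("sigma2 must be positive")
        if self.mu <= 0:
            raise DomainError("mu must be positive")

    @property
    def shape(self) -> float:
        return self.mu**2 / self.sigma2

    @property
    def scale(self) -> float:
        return self.sigma2 / self.mu


@dataclass(frozen=True)
class CombinedTestResult:
    """Outcome of a Fisher-combination test for one SNP."""

    T: float
    global_p: float
    null: Optional[GammaNull]
    method: str
    marginals: MarginalResults
    snp_id: Optional[str] = None

    def __post_init__(self):
        if self.T < 0:
            raise DomainError("T must be non-negative")
        if not (0 < self.global_p <= 1):
            raise DomainError("global p-value must lie in (0, 1]")


def as_phenotype_matrix(Y) -> PhenotypeMatrix:
    """Coerce an array-like or PhenotypeMatrix to PhenotypeMatrix."""
    if isinstance(Y, PhenotypeMatrix):
        return Y
    return PhenotypeMatrix(np.asarray(Y, dtype=float))


def as_genotype_vector(x) -> GenotypeVector:
    """Coerce an array-like or GenotypeVector to GenotypeVector."""
    if isinstance(x, GenotypeVector):
        return x
    return GenotypeVector(np.asarray(x))
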
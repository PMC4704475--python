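"""Synthetic genotype/phenotype generation and the type-I error / power study.

The generating model is ``Y_i = x_i * beta + eps_i`` with
``x_i ~ Binomial(2, maf)`` (Hardy-Weinberg) and ``eps_i ~ MVN(0, Sigma)``,
where Sigma is compound symmetric (unit diagonal, common off-diagonal rho).
The contaminated ("mixture") error model draws each subject's error from
``MVN(0, mixture_scale * Sigma)`` with probability ``mixture_weight``,
giving the long-tailed trait distributions common in real data.

Defaults mirror the validation study's conditions: n=100 subjects, m=5
traits, MAF 0.25, rho in {0, 0.25, 0.5, 0.75}, 10,000 replicates, alpha 0.05,
effect vectors (0,...,0), (0.3,...,0.3) and (0.1,0.2,0.3,0.4,0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import baselines, core
from .exceptions import DomainError, FcgwasError
from .types import CorrelationEstimate, GenotypeVector, PhenotypeMatrix

__all__ = [
    "SimulationConfig",
    "PowerTable",
    "simulate_genotype",
    "simulate_phenotypes",
    "run_power_study",
    "ALL_METHODS",
]

ALL_METHODS = (
    "manova",
    "pca",
    "gee",
    "tates",
    "fc-chi2",
    "fc-permutation",
    "fc-pearson",
    "fc-kendall",
)


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation condition (one effect vector, one trait correlation)."""

    n: int = 100
    m: int = 5
    maf: float = 0.25
    beta: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    rho: float = 0.0
    error_model: str = "normal"  # "normal" or "mixture"
    mixture_weight: float = 0.10
    mixture_scale: float = 5.0
    reps: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    methods: tuple = ALL_METHODS
    permutations: int = 1000

    def __post_init__(self):
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        object.__setattr__(self, "methods", tuple(self.methods))
        if not 0 < self.maf < 1:
            raise DomainError("maf must lie strictly between 0 and 1")
        if len(self.beta) != self.m:
            raise DomainError("beta length must equal the trait count m")
        if self.m > 1 and not (-1.0 / (self.m - 1) < self.rho < 1.0):
            raise DomainError(
                "rho must keep the compound-symmetry matrix positive definite"
            )
        if not 0 <= self.mixture_weight <= 1:
            raise DomainError("mixture_weight must lie in [0, 1]")
        if self.error_model not in ("normal", "mixture"):
            raise DomainError("error_model must be 'normal' or 'mixture'")
        if self.reps < 1:
            raise DomainError("reps must be at least 1")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise DomainError(f"unknown methods: {sorted(unknown)}")

    @property
    def effect_setting(self) -> str:
        return "null" if all(b == 0 for b in self.beta) else (
            "equal" if len(set(self.beta)) == 1 else "varied"
        )


@dataclass(frozen=True)
class PowerTable:
    """Per-method rejection proportions with Monte-Carlo standard deviations.

    ``table`` columns: method, rejections, n_valid, n_fail, rejection_rate,
    mc_sd (= sqrt(p_hat (1 - p_hat) / R)), invalid (True when more than 1 %
    of replicates failed for that method).
    """

    config: SimulationConfig
    table: pd.DataFrame
    genotype_redraws: int = 0


def simulate_genotype(n: int, maf: float, rng: np.random.Generator) -> GenotypeVector:
    """Draw n i.i.d. allele counts from Binomial(2, maf) (Hardy-Weinberg)."""
    if not 0 < maf < 1:
        raise DomainError("maf must lie strictly between 0 and 1")
    return GenotypeVector(rng.binomial(2, maf, size=n))


def _cs_cholesky(m: int, rho: float) -> np.ndarray:
    sigma = np.full((m, m), rho)
    np.fill_diagonal(sigma, 1.0)
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise DomainError("compound-symmetry matrix is not positive definite") from exc


def simulate_phenotypes(
    x,
    beta: Sequence[float],
    rho: float,
    rng: np.random.Generator,
    error_model: str = "normal",
    mixture_weight: float = 0.10,
    mixture_scale: float = 5.0,
    _chol: Optional[np.ndarray] = None,
) -> PhenotypeMatrix:
    """Generate Y = x beta + eps with compound-symmetric Gaussian errors."""
    counts = x.counts if isinstance(x, GenotypeVector) else np.asarray(x)
    beta = np.asarray(beta, dtype=float)
    n, m = counts.shape[0], beta.shape[0]
    L = _chol if _chol is not None else _cs_cholesky(m, rho)
    eps = rng.standard_normal((n, m)) @ L.T
    if error_model == "mixture":
        contaminated = rng.random(n) < mixture_weight
        eps[contaminated] *= np.sqrt(mixture_scale)
    elif error_model != "normal":
        raise DomainError("error_model must be 'normal' or 'mixture'")
    return PhenotypeMatrix(counts[:, None] * beta[None, :] + eps)


def _method_pvalue(
    name: str,
    Y: PhenotypeMatrix,
    x: GenotypeVector,
    rng: np.random.Generator,
    cache: dict,
    config: SimulationConfig,
) -> float:
    """Dispatch one method on one replicate, sharing marginal p-values."""
    if name in ("tates", "fc-chi2", "fc-permutation", "fc-pearson", "fc-kendall"):
        if "marg_p" not in cache:
            cache["marg_p"] = core.marginal_associations(Y, x).p
    if name == "manova":
        return baselines.manova_test(Y, x)
    if name == "pca":
        return baselines.pca_test(Y, x)
    if name == "gee":
        return baselines.gee_test(Y, x)
    if name == "tates":
        if "pearson_raw" not in cache:
            cache["pearson_raw"] = np.corrcoef(Y.values, rowvar=False)
        return baselines.tates_test(cache["marg_p"], cache["pearson_raw"]).global_p
    if name == "fc-chi2":
        return baselines.fc_chi2_test(cache["marg_p"])
    if name == "fc-permutation":
        return baselines.fc_permutation_test(
            Y, x, B=config.permutations, rng=rng
        )
    if name in ("fc-pearson", "fc-kendall"):
        method = name.split("-")[1]
        corr = core.estimate_correlations(Y, method=method)
        T = core.fisher_T(cache["marg_p"])
        sigma2 = core.variance_T(corr)
        null = core.gamma_null(Y.m, sigma2)
        return core.gamma_global_pvalue(T, null)
    raise DomainError(f"unknown method {name!r}")


def run_power_study(config: SimulationConfig) -> PowerTable:
    """Monte-Carlo rejection proportions for every requested method.

    Each replicate draws a fresh genotype (redrawn if monomorphic) and fresh
    phenotypes from its own seed stream spawned deterministically from
    ``config.seed``, and every method is evaluated on that same replicate
    data, so methods are compared on identical data streams and scaled-down
    runs are extendable.  Per-replicate method failures are counted; a cell
    with more than 1 % failures is flagged invalid.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.reps)
    L = _cs_cholesky(config.m, config.rho)
    rejections = {name: 0 for name in config.methods}
    n_fail = {name: 0 for name in config.methods}
    redraws = 0
    for stream in streams:
        rng = np.random.default_rng(stream)
        x = simulate_genotype(config.n, config.maf, rng)
        while not x.is_polymorphic:
            redraws += 1
            x = simulate_genotype(config.n, config.maf, rng)
        Y = simulate_phenotypes(
            x,
            config.beta,
            config.rho,
            rng,
            error_model=config.error_model,
            mixture_weight=config.mixture_weight,
            mixture_scale=config.mixture_scale,
            _chol=L,
        )
        cache: dict = {}
        for name in config.methods:
            try:
                p = _method_pvalue(name, Y, x, rng, cache, config)
            except FcgwasError:
                n_fail[name] += 1
                continue
            if p < config.alpha:
                rejections[name] += 1
    rows = []
    for name in config.methods:
        n_valid = config.reps - n_fail[name]
        rate = rejections[name] / n_valid if n_valid else np.nan
        rows.append(
            {
                "effect_setting": config.effect_setting,
                "rho": config.rho,
                "error_model": config.error_model,
                "method": name,
                "rejections": rejections[name],
                "n_valid": n_valid,
                "n_fail": n_fail[name],
                "rejection_rate": rate,
                "mc_sd": float(np.sqrt(rate * (1 - rate) / config.reps))
                if n_valid
                else np.nan,
                "invalid": n_fail[name] > 0.01 * config.reps,
            }
        )
    return PowerTable(
        config=config, table=pd.DataFrame(rows), genotype_redraws=redraws
    )
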
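"""File formats and the genome-wide scan driver.

Canonical formats are plain tab-separated text:

* phenotypes — header row of trait names, one row per subject, optional
  leading subject-ID column (detected when its values are non-numeric);
* genotypes — one SNP per row, optional leading SNP identifier, then n
  allele counts in {0,1,2}; streamed, never fully loaded;
* scan output — '#'-prefixed metadata header followed by one row per SNP.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Optional

import numpy as np
import pandas as pd

from . import __version__
from . import baselines, core
from .calibration import DeltaPolynomial
from .exceptions import (
    DomainError,
    FcgwasError,
    InsufficientSampleError,
    ParseError,
)
from .types import GenotypeVector, PhenotypeMatrix

logger = logging.getLogger("fcgwas")

__all__ = [
    "read_phenotypes",
    "read_genotypes",
    "scan",
    "ScanResult",
    "qq_points",
    "write_scan_result",
    "read_scan_result",
    "write_power_table",
    "write_delta_polynomial",
]

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "N/A", "na"}

SCAN_METHODS = (
    "fc-pearson",
    "fc-kendall",
    "fc-chi2",
    "fc-permutation",
    "manova",
    "pca",
    "gee",
    "tates",
)


def read_phenotypes(path) -> PhenotypeMatrix:
    """Read a tab-separated phenotype table and keep complete cases.

    The first row holds trait names.  A leading subject-ID column is
    auto-detected when its values are not all numeric.  Rows containing any
    missing value (empty, NA, NaN) are dropped with a logged count; the
    retained 0-based row positions are stored on the result for genotype
    alignment.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 1:
        raise ParseError(f"{path}: no columns found")

    def _numeric(col: pd.Series) -> pd.Series:
        cleaned = col.str.strip()
        out = pd.to_numeric(cleaned.where(~cleaned.isin(_MISSING_TOKENS)), errors="coerce")
        bad = out.isna() & ~cleaned.isin(_MISSING_TOKENS)
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"{path}: non-numeric value {cleaned.iloc[row]!r} in column "
                f"{col.name!r}, line {row + 2}"
            )
        return out

    first = df.iloc[:, 0].str.strip()
    has_ids = not pd.to_numeric(first, errors="coerce").notna().all()
    subject_ids = first.tolist() if has_ids else None
    data = df.iloc[:, 1:] if has_ids else df
    if data.shape[1] < 1:
        raise ParseError(f"{path}: no trait columns found")
    numeric = pd.concat([_numeric(data[c]) for c in data.columns], axis=1)
    complete = ~numeric.isna().any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("read_phenotypes: dropped %d incomplete rows", dropped)
    kept = np.flatnonzero(complete.to_numpy())
    if kept.shape[0] < 4:
        raise InsufficientSampleError(
            f"{path}: only {kept.shape[0]} complete rows; at least 4 required"
        )
    return PhenotypeMatrix(
        values=numeric.to_numpy(dtype=float)[kept],
        trait_names=tuple(data.columns),
        subject_ids=tuple(np.asarray(subject_ids, dtype=object)[kept])
        if subject_ids is not None
        else None,
        kept_rows=kept,
    )


class GenotypeRecord(NamedTuple):
    """One parsed genotype row; ``genotype`` is None when skipped."""

    snp_id: str
    genotype: Optional[GenotypeVector]
    skip_reason: Optional[str]


def read_genotypes(
    path,
    n_expected: int,
    keep_rows: Optional[np.ndarray] = None,
) -> Iterator[GenotypeRecord]:
    """Stream genotype rows, aligning subjects to the phenotype matrix.

    ``n_expected`` is the subject count in the genotype file; ``keep_rows``
    gives the subject positions retained by :func:`read_phenotypes`.
    Invalid rows are yielded as skip records rather than raising.
    """
    with open(path) as handle:
        for i, line in enumerate(handle):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if fields[0].strip() in ("0", "1", "2"):
                snp_id, tokens = f"snp{i + 1}", fields
            else:
                snp_id, tokens = fields[0].strip(), fields[1:]
            if len(tokens) != n_expected:
                yield GenotypeRecord(
                    snp_id, None,
                    f"row length mismatch ({len(tokens)} != {n_expected})",
                )
                continue
            try:
                counts = np.array([int(t) for t in tokens])
            except ValueError:
                yield GenotypeRecord(snp_id, None, "invalid genotype code")
                continue
            if not np.isin(counts, (0, 1, 2)).all():
                yield GenotypeRecord(snp_id, None, "invalid genotype code")
                continue
            if keep_rows is not None:
                counts = counts[keep_rows]
            if counts.min() == counts.max():
                yield GenotypeRecord(snp_id, None, "monomorphic")
                continue
            yield GenotypeRecord(
                snp_id, GenotypeVector(counts, snp_id=snp_id), None
            )


@dataclass
class ScanResult:
    """Per-SNP results of a genome-wide scan plus provenance metadata."""

    table: pd.DataFrame
    skipped: list  # [(snp_id, reason), ...]
    metadata: dict


def scan(
    phenotypes: PhenotypeMatrix,
    genotypes: Iterable,
    method: str = "fc-pearson",
    threshold: Optional[float] = None,
    permutations: int = 1000,
    seed: Optional[int] = None,
    poly: Optional[DeltaPolynomial] = None,
) -> ScanResult:
    """Apply one association method to every polymorphic SNP.

    Trait correlations are estimated once from the phenotype matrix and
    reused for every SNP (only the marginal tests depend on the genotype).
    ``genotypes`` may be an iterable of :class:`GenotypeRecord` (from
    :func:`read_genotypes`) or of :class:`GenotypeVector`.
    """
    if method not in SCAN_METHODS:
        raise DomainError(f"unknown scan method {method!r}")
    m = phenotypes.m
    corr = None
    if m > 1 and method in ("fc-pearson", "fc-kendall", "tates"):
        corr_method = "kendall" if method == "fc-kendall" else "pearson"
        corr = core.estimate_correlations(phenotypes, method=corr_method)
    rng = np.random.default_rng(seed)
    rows = []
    skipped: list = []
    for item in genotypes:
        if isinstance(item, GenotypeRecord):
            if item.skip_reason is not None:
                skipped.append((item.snp_id, item.skip_reason))
                continue
            gv = item.genotype
        else:
            gv = item if isinstance(item, GenotypeVector) else GenotypeVector(item)
        if gv.n != phenotypes.n:
            raise DomainError(
                "genotype length does not match the filtered phenotype matrix"
            )
        snp_id = gv.snp_id or f"snp{len(rows) + len(skipped) + 1}"
        try:
            row = {"snp_id": snp_id}
            marg = core.marginal_associations(phenotypes, gv)
            if method in ("fc-pearson", "fc-kendall"):
                res = core.fc_test(
                    phenotypes, gv,
                    method="kendall" if method == "fc-kendall" else "pearson",
                    corr=corr, poly=poly,
                )
                row["T"], row["global_p"] = res.T, res.global_p
            elif method == "fc-chi2":
                row["T"] = core.fisher_T(marg.p)
                row["global_p"] = baselines.fc_chi2_test(marg.p)
            elif method == "fc-permutation":
                row["T"] = core.fisher_T(marg.p)
                row["global_p"] = baselines.fc_permutation_test(
                    phenotypes, gv, B=permutations, rng=rng
                )
            elif method == "tates":
                R = corr.raw if corr is not None else np.eye(m)
                row["T"] = np.nan
                row["global_p"] = baselines.tates_test(marg.p, R).global_p
            elif method == "manova":
                row["T"] = np.nan
                row["global_p"] = baselines.manova_test(phenotypes, gv)
            elif method == "pca":
                row["T"] = np.nan
                row["global_p"] = baselines.pca_test(phenotypes, gv)
            elif method == "gee":
                row["T"] = np.nan
                row["global_p"] = baselines.gee_test(phenotypes, gv)
            for name, pj in zip(phenotypes.trait_names, marg.p):
                row[f"p_{name}"] = pj
            rows.append(row)
        except FcgwasError as exc:
            skipped.append((snp_id, str(exc)))
    columns = ["snp_id", "T", "global_p"] + [
        f"p_{name}" for name in phenotypes.trait_names
    ]
    table = pd.DataFrame(rows, columns=columns)
    metadata = {
        "package": "fcgwas",
        "version": __version__,
        "method": method,
        "n": phenotypes.n,
        "m": m,
        "correlation_method": corr.method if corr is not None else "none",
        "coefficients": "refit" if poly is not None else "default",
        "seed": seed if seed is not None else "none",
        "permutations": permutations if method == "fc-permutation" else "none",
        "n_snps": len(rows),
        "n_skipped": len(skipped),
    }
    if threshold is not None:
        metadata["threshold"] = threshold
        metadata["n_significant"] = int((table["global_p"] < threshold).sum())
    logger.info(
        "scan: %s method=%s n=%d m=%d corr=%s coeffs=%s seed=%s",
        f"{len(rows)} SNPs tested, {len(skipped)} skipped",
        method, phenotypes.n, m, metadata["correlation_method"],
        metadata["coefficients"], metadata["seed"],
    )
    return ScanResult(table=table, skipped=skipped, metadata=metadata)


def qq_points(pvals) -> np.ndarray:
    """(expected, observed) -log10 p pairs for a QQ plot.

    Observed p-values are sorted ascending; the i-th expected quantile is
    i/(k+1) under the uniform null.
    """
    p = np.atleast_1d(np.asarray(pvals, dtype=float))
    if p.size == 0:
        raise DomainError("qq_points requires at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    k = p.size
    observed = -np.log10(np.sort(p))
    expected = -np.log10(np.arange(1, k + 1) / (k + 1.0))
    return np.column_stack([expected, observed])


# ---------------------------------------------------------------------------
# Writers / readers
# ---------------------------------------------------------------------------

def _format_p(p: float) -> str:
    if p == 1.0:
        return "1.0"
    if p <= 1e-300:
        return "1e-300"
    return f"{p:.6e}"


def write_scan_result(result: ScanResult, path) -> None:
    """Tab-separated scan output with a '#' metadata header.

    p-values carry 6 significant digits in scientific notation; exact 1 is
    written as "1.0" and underflow as "1e-300" with the flag column set.
    """
    pcols = [c for c in result.table.columns if c == "global_p" or c.startswith("p_")]
    with open(path, "w") as out:
        for key, value in result.metadata.items():
            out.write(f"# {key}={value}\n")
        for snp_id, reason in result.skipped:
            out.write(f"# skipped\t{snp_id}\t{reason}\n")
        header = list(result.table.columns) + ["underflow"]
        out.write("\t".join(header) + "\n")
        for _, row in result.table.iterrows():
            fields = []
            underflow = 0
            for col in result.table.columns:
                val = row[col]
                if col in pcols:
                    if val <= 1e-300:
                        underflow = 1
                    fields.append(_format_p(val))
                elif col == "T":
                    fields.append("NA" if pd.isna(val) else f"{val:.6f}")
                else:
                    fields.append(str(val))
            out.write("\t".join(fields + [str(underflow)]) + "\n")


def read_scan_result(path) -> ScanResult:
    """Inverse of :func:`write_scan_result` (values at printed precision)."""
    metadata: dict = {}
    skipped: list = []
    rows: list = []
    header: Optional[list] = None
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("# skipped\t"):
                _, snp_id, reason = line.split("\t", 2)
                skipped.append((snp_id, reason))
            elif line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                metadata[key.strip()] = value
            elif header is None:
                header = line.split("\t")
            elif line:
                rows.append(line.split("\t"))
    if header is None:
        raise ParseError(f"{path}: no header row found")
    df = pd.DataFrame(rows, columns=header)
    for col in df.columns:
        if col not in ("snp_id",):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return ScanResult(
        table=df.drop(columns=["underflow"]), skipped=skipped, metadata=metadata
    )


def write_power_table(power, path) -> None:
    """Write a PowerTable as tab-separated text with a '#' metadata header."""
    cfg = power.config
    with open(path, "w") as out:
        out.write(f"# package=fcgwas version={__version__}\n")
        out.write(
            f"# n={cfg.n} m={cfg.m} maf={cfg.maf} beta={list(cfg.beta)} "
            f"rho={cfg.rho} error_model={cfg.error_model} reps={cfg.reps} "
            f"alpha={cfg.alpha} seed={cfg.seed} "
            f"permutations={cfg.permutations}\n"
        )
        out.write(f"# genotype_redraws={power.genotype_redraws}\n")
        cols = ["effect_setting", "rho", "method", "rejection_rate", "mc_sd", "n_fail"]
        out.write("\t".join(cols) + "\n")
        for _, row in power.table.iterrows():
            out.write(
                f"{row['effect_setting']}\t{row['rho']}\t{row['method']}\t"
                f"{row['rejection_rate']:.6f}\t{row['mc_sd']:.6f}\t{row['n_fail']}\n"
            )


def write_delta_polynomial(poly: DeltaPolynomial, path, step=0.01, tol=1e-6) -> None:
    """Emit a fitted DeltaPolynomial as a small JSON document."""
    doc = {
        "coefficients": list(poly.coefficients),
        "max_residual": poly.max_residual,
        "grid_step": step,
        "tolerance": tol,
    }
    with open(path, "w") as out:
        json.dump(doc, out, indent=2)
        out.write("\n")


def read_delta_polynomial(path) -> DeltaPolynomial:
    with open(path) as handle:
        doc = json.load(handle)
    return DeltaPolynomial(
        coefficients=tuple(doc["coefficients"]),
        max_residual=float(doc.get("max_residual", 0.0)),
    )
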
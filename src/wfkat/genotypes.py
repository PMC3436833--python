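"""Genotype matrices, traits and covariates.

A SNP set is held as an ``n x p`` integer matrix of diploid allele counts,
one row per individual, one column per SNP, entries in ``{0, 1, 2}``.  The
``coding`` flag records which allele is being counted: ``"minor"`` (each
column counts its minor allele, the convention of the IBS kernel) or
``"major"`` (the convention of the Wright-Fisher kernel).  Flipping the
coding maps every entry ``x`` to ``2 - x``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "TraitVector",
    "CovariateMatrix",
    "read_genotypes",
    "read_trait",
    "read_covariates",
    "compute_maf",
    "classify_variants",
    "recode",
]

_CODINGS = ("minor", "major")
_DEFAULT_MISSING = ("NA", "na", "NaN", "nan", ".", "-9", "")


@dataclass
class GenotypeMatrix:
    """Diploid allele-count matrix for one SNP set.

    Parameters
    ----------
    values
        ``n x p`` integer matrix with entries in ``{0, 1, 2}``.
    coding
        ``"minor"`` or ``"major"`` — which allele each entry counts.
    snp_ids
        ``p`` SNP identifiers; generated as ``snp0001, ...`` when absent.
    sample_ids
        Optional ``n`` sample identifiers (populated by the VCF reader).
    """

    values: np.ndarray
    coding: str = "minor"
    snp_ids: list[str] | None = None
    sample_ids: list[str] | None = None
    maf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            if not np.allclose(self.values, rounded, atol=1e-8):
                raise ValueError("genotype entries must be integers in {0, 1, 2}")
            self.values = rounded.astype(np.int16)
        else:
            self.values = self.values.astype(np.int16)
        bad = (self.values < 0) | (self.values > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype entry out of range at row {i}, column {j}: "
                f"{self.values[i, j]} (allowed: 0, 1, 2)"
            )
        if self.coding not in _CODINGS:
            raise ValueError(f"coding must be one of {_CODINGS}, got {self.coding!r}")
        if self.snp_ids is None:
            self.snp_ids = [f"snp{j + 1:04d}" for j in range(self.n_snps)]
        if len(self.snp_ids) != self.n_snps:
            raise ValueError("snp_ids length does not match number of columns")
        self.maf = compute_maf(self)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


@dataclass
class TraitVector:
    """Length-``n`` trait; ``kind`` is ``"binary"`` ({0,1}) or ``"quantitative"``."""

    values: np.ndarray
    kind: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        is_binary = np.isin(self.values, (0.0, 1.0)).all()
        if self.kind is None:
            self.kind = "binary" if is_binary else "quantitative"
        if self.kind not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "binary" and not is_binary:
            raise ValueError("binary trait must contain only 0/1 values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CovariateMatrix:
    """``n x t`` numeric matrix of non-genetic covariates."""

    values: np.ndarray
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.names is None:
            self.names = [f"c{j + 1}" for j in range(self.values.shape[1])]
        if len(self.names) != self.values.shape[1]:
            raise ValueError("covariate names length does not match columns")


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency, folded into ``[0, 0.5]``.

    Invariant to the coding flag: the count of the coded allele is folded at
    0.5, so e.g. a column of all 2s under minor coding (an impossible minor
    frequency of 1) is reported as 0.
    """
    n = g.values.shape[0]
    freq = g.values.sum(axis=0) / (2.0 * n)
    return np.minimum(freq, 1.0 - freq)


def classify_variants(
    g: GenotypeMatrix, common_thresh: float = 0.10, rare_thresh: float = 0.01
) -> np.ndarray:
    """Classify each SNP as ``common`` (MAF > common_thresh), ``rare``
    (MAF < rare_thresh) or ``intermediate``."""
    if not 0.0 < rare_thresh < common_thresh < 0.5:
        raise ValueError(
            f"thresholds must satisfy 0 < rare < common < 0.5, got "
            f"rare={rare_thresh}, common={common_thresh}"
        )
    out = np.full(g.n_snps, "intermediate", dtype=object)
    out[g.maf > common_thresh] = "common"
    out[g.maf < rare_thresh] = "rare"
    return out


def recode(g: GenotypeMatrix, target: str) -> GenotypeMatrix:
    """Return a copy counting the other allele (``x -> 2 - x``) when the
    target coding differs; recoding twice is the identity."""
    if target not in _CODINGS:
        raise ValueError(f"target coding must be one of {_CODINGS}")
    if target == g.coding:
        values = g.values.copy()
    else:
        values = 2 - g.values
    return GenotypeMatrix(values, coding=target, snp_ids=list(g.snp_ids),
                          sample_ids=g.sample_ids)


def read_genotypes(path: str, format: str = "matrix",
                   missing_values: tuple[str, ...] = _DEFAULT_MISSING) -> GenotypeMatrix:
    """Read a genotype matrix from a plain numeric matrix or a VCF.

    Matrix dialect: rows are individuals, columns SNPs, whitespace/comma/tab
    separated, entries in {0, 1, 2} or a missing code; an optional header row
    carries SNP ids.  VCF: biallelic SNP records only, genotypes taken from
    the GT field (phasing ignored).  Missing genotypes are imputed to the
    per-SNP rounded mean count; columns whose coded-allele frequency exceeds
    0.5 are flipped so that minor coding holds throughout.
    """
    if format == "matrix":
        return _read_matrix(path, missing_values)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r} (use 'matrix' or 'vcf')")


def _read_matrix(path: str, missing_values: tuple[str, ...]) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None,
                         na_values=list(missing_values), keep_default_na=False,
                         comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse genotype matrix {path}: {exc}") from exc
    snp_ids = None
    first = df.iloc[0]
    if first.map(lambda v: isinstance(v, str)).any():
        snp_ids = [str(v) for v in first]
        df = df.iloc[1:].reset_index(drop=True)
    values = df.to_numpy(dtype=float)
    valid = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise ValueError(
            f"invalid genotype entry {values[i, j]!r} at data line {i + 1}, "
            f"column {j + 1} of {path}: expected 0, 1, 2 or a missing code"
        )
    values = _impute_missing(values)
    return _enforce_minor(values, snp_ids, None)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    ids: list[str] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} in {path}; "
                "only biallelic SNPs are supported"
            )
        counts = np.full(len(samples), np.nan)
        for i, gt in enumerate(rec.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if alleles:
                counts[i] = float(sum(alleles))
        columns.append(counts)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
    if not columns:
        raise ValueError(f"no variant records found in {path}")
    values = _impute_missing(np.column_stack(columns))
    return _enforce_minor(values, ids, samples)


def _impute_missing(values: np.ndarray) -> np.ndarray:
    """Fill missing calls with the per-SNP rounded mean count (keeps the
    {0,1,2} state space); an all-missing column imputes to 0."""
    if np.isnan(values).any():
        col_mean = np.nanmean(np.where(np.isnan(values), np.nan, values), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        fill = np.rint(col_mean)
        idx = np.argwhere(np.isnan(values))
        values[idx[:, 0], idx[:, 1]] = fill[idx[:, 1]]
    return values.astype(np.int16)


def _enforce_minor(values: np.ndarray, snp_ids: list[str] | None,
                   sample_ids: list[str] | None) -> GenotypeMatrix:
    n = values.shape[0]
    freq = values.sum(axis=0) / (2.0 * n)
    flip = freq > 0.5
    if flip.any():
        values = np.where(flip[None, :], 2 - values, values)
        warnings.warn(
            f"{int(flip.sum())} column(s) counted the major allele; flipped to "
            "minor coding", stacklevel=2,
        )
    return GenotypeMatrix(values, coding="minor", snp_ids=snp_ids,
                          sample_ids=sample_ids)


def read_trait(path: str, column: str | None = None) -> TraitVector:
    """Read a trait vector from a one- or two-column CSV/TSV.

    A ``sample_id``-like first column is ignored for matching-by-order; with
    ``column`` the named column is used, otherwise the last column.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] == 0:
        raise ValueError(f"no columns found in trait file {path}")
    col = column if column is not None else df.columns[-1]
    if col not in df.columns:
        raise ValueError(f"column {col!r} not found in {path}")
    return TraitVector(df[col].to_numpy(dtype=float))


def read_covariates(path: str, id_column: str | None = None) -> CovariateMatrix:
    """Read covariates from CSV/TSV; ``id_column`` (if given) is dropped."""
    df = pd.read_csv(path, sep=None, engine="python")
    if id_column is not None and id_column in df.columns:
        df = df.drop(columns=[id_column])
    return CovariateMatrix(df.to_numpy(dtype=float), names=list(df.columns))
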
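"""Core data containers: genotype matrices and phenotype tables.

Genotypes are hard-call additive dosages (count of alternate alleles, 0/1/2,
with -1 marking a missing call). Phenotypes and covariates live in a plain
:class:`pandas.DataFrame` keyed by ``individual_id``; helper functions below
build the covariate design matrices used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


class DataError(ValueError):
    """Raised when input data violate a precondition (too few values, etc.)."""


class ParameterError(ValueError):
    """Raised when a numeric parameter is outside its valid range."""


@dataclass
class GenotypeMatrix:
    """Individuals x variants additive dosage matrix with variant metadata.

    Parameters
    ----------
    dosages
        ``(n_individuals, m_variants)`` integer array with entries in
        ``{0, 1, 2}`` (alternate-allele count) or ``-1`` for a missing call.
    variants
        DataFrame with columns ``id, chrom, pos, ref, alt`` (``pos`` 1-based).
    individual_ids
        One identifier per row of ``dosages``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be a 2-D array")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise DataError("dosages must be in {0,1,2} or -1 for missing")
        self.variants = pd.DataFrame(self.variants)
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise DataError(f"variant table missing columns: {missing_cols}")
        if self.variants["id"].duplicated().any():
            dups = self.variants["id"][self.variants["id"].duplicated()].tolist()
            raise DataError(f"duplicate variant ids: {dups}")
        if len(self.variants) != self.dosages.shape[1]:
            raise DataError("variant table length does not match dosage columns")
        if not self.individual_ids:
            self.individual_ids = [f"I{i}" for i in range(self.dosages.shape[0])]
        if len(self.individual_ids) != self.dosages.shape[0]:
            raise DataError("individual_ids length does not match dosage rows")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["id"].tolist()

    def index_of(self, variant_id: str) -> int:
        idx = np.flatnonzero((self.variants["id"] == variant_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"variant {variant_id!r} not in genotype matrix")
        return int(idx[0])

    def dosage(self, variant_id: str) -> np.ndarray:
        """Dosage vector for one variant as float, missing as NaN."""
        col = self.dosages[:, self.index_of(variant_id)].astype(float)
        col[col == MISSING] = np.nan
        return col

    def allele_freq(self) -> np.ndarray:
        """Per-variant empirical alternate-allele frequency (missing excluded)."""
        d = self.dosages.astype(float)
        d[d == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=0)

    def subset_variants(self, variant_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.index_of(v) for v in variant_ids]
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.variants.iloc[idx].reset_index(drop=True),
            list(self.individual_ids),
        )

    def region(self, chrom: str, start: int, end: int) -> "GenotypeMatrix":
        """Variants within a 1-based inclusive interval on ``chrom``."""
        mask = (
            (self.variants["chrom"].astype(str) == str(chrom))
            & (self.variants["pos"] >= start)
            & (self.variants["pos"] <= end)
        ).to_numpy()
        return GenotypeMatrix(
            self.dosages[:, mask],
            self.variants[mask].reset_index(drop=True),
            list(self.individual_ids),
        )


@dataclass
class HaplotypePair:
    """Phased binary allele indicators; ``hap1 + hap2`` equals the dosages."""

    hap1: np.ndarray
    hap2: np.ndarray

    def dosages(self) -> np.ndarray:
        return self.hap1 + self.hap2


def covariate_columns(n_pcs: int) -> list[str]:
    """Standard covariate set: age, age squared, sex, leading PCs."""
    return ["age", "age2", "sex"] + [f"PC{i}" for i in range(1, n_pcs + 1)]


def covariate_design(
    phenotypes: pd.DataFrame, columns: list[str] | None = None, n_pcs: int = 10
) -> np.ndarray:
    """Covariate design matrix (no intercept column) from a phenotype table."""
    cols = columns if columns is not None else covariate_columns(n_pcs)
    missing = [c for c in cols if c not in phenotypes.columns]
    if missing:
        raise DataError(f"phenotype table missing covariate columns: {missing}")
    return phenotypes[cols].to_numpy(dtype=float)
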
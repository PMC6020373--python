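"""In-memory containers shared across the pipeline.

Expression is carried as a genes x samples :class:`pandas.DataFrame` plus a
gene-annotation table; genotypes as a SNPs x samples dosage frame (0/1/2,
``NaN`` for missing) plus a SNP-annotation table.  The ``unit`` tag on
:class:`ExpressionMatrix` records where a matrix sits in the normalization
chain and may only move forward through the declared operations
(raw-count -> fpkm -> log-normalized -> z-score).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_UNITS = ("raw-count", "fpkm", "log-normalized", "z-score")


class BloodtxError(ValueError):
    """Base class for user-facing errors raised by this package."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with coordinates.

    Parameters
    ----------
    values
        Numeric frame indexed by gene id, columns are sample ids.
    genes
        Annotation frame indexed by gene id with columns ``chrom``,
        ``start``, ``stop`` (1-based inclusive) and ``length`` (bp).
    unit
        One of ``raw-count``, ``fpkm``, ``log-normalized``, ``z-score``.
    """

    values: pd.DataFrame
    genes: pd.DataFrame
    unit: str = "raw-count"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise BloodtxError(f"unknown expression unit {self.unit!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise BloodtxError(f"duplicate gene ids: {list(dups[:5])}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        keep = self.values.index.intersection(pd.Index(gene_ids))
        return replace(self, values=self.values.loc[keep],
                       genes=self.genes.loc[keep])

    def zscore(self) -> "ExpressionMatrix":
        """Per-gene standardization across samples (constant genes -> 0)."""
        v = self.values.to_numpy(dtype=float)
        mu = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (v - mu) / sd
        return replace(self, values=pd.DataFrame(z, index=self.values.index,
                                                 columns=self.values.columns),
                       unit="z-score")


@dataclass
class GenotypeMatrix:
    """SNPs x samples additive dosages with SNP annotation.

    ``dosages`` holds 0/1/2 with ``NaN`` for missing calls.  ``snps`` is
    indexed by SNP id with columns ``chrom``, ``pos`` (1-based), ``ref``,
    ``alt``.  Dosage counts the ALT allele.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> pd.Series:
        """ALT-allele frequency per SNP (missing ignored)."""
        return self.dosages.mean(axis=1, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        p = self.allele_freq()
        return pd.concat([p, 1 - p], axis=1).min(axis=1).rename("maf")

    def missing_rate(self) -> pd.Series:
        return self.dosages.isna().mean(axis=1).rename("missing_rate")

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        keep = self.dosages.index.intersection(pd.Index(snp_ids))
        return GenotypeMatrix(self.dosages.loc[keep], self.snps.loc[keep])

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        cols = [s for s in sample_ids if s in self.dosages.columns]
        return GenotypeMatrix(self.dosages[cols], self.snps)

    def mean_imputed(self) -> "GenotypeMatrix":
        """Replace missing dosages with the per-SNP mean."""
        d = self.dosages.to_numpy(dtype=float)
        means = np.nanmean(d, axis=1)
        idx = np.where(np.isnan(d))
        d = d.copy()
        d[idx] = means[idx[0]]
        return GenotypeMatrix(pd.DataFrame(d, index=self.dosages.index,
                                           columns=self.dosages.columns),
                              self.snps)


@dataclass
class ScoreTable:
    """Samples x scores table (axis scores, module scores, TRS, ...)."""

    scores: pd.DataFrame                      # samples x score columns
    variance_explained: dict = field(default_factory=dict)
    groups: pd.Series | None = None           # sample -> group label

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise BloodtxError("non-finite score values")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.scores.index)

    def group_means(self) -> pd.DataFrame:
        """Score column x group mean matrix (heat-map export)."""
        if self.groups is None:
            raise BloodtxError("no group labels attached")
        return self.scores.groupby(self.groups).mean().T
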
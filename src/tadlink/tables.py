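"""In-memory containers for methylation and expression data.

Both wrap pandas objects; rows are features (CpG sites / probes / genes) and
columns are samples.  Sample metadata (genotype group or cell type) travels
alongside as a Series indexed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

GENOTYPE_GROUPS = ("DNMT3A", "IDH", "DOUBLE", "WT")


@dataclass
class MethylationTable:
    """Per-site (or per-probe) methylation fractions.

    ``sites`` has columns chrom, pos (0-based) indexed by site id; ``fractions``
    is site x sample in [0, 1].  In site-level (ERRBS-like) mode ``coverage``
    holds per-site, per-sample integer read counts; probe-level (array-like)
    data carries no coverage.
    """

    sites: pd.DataFrame
    fractions: pd.DataFrame
    coverage: Optional[pd.DataFrame] = None
    sample_groups: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if not self.sites.index.equals(self.fractions.index):
            raise ValueError("sites and fractions must share the same index")
        vals = self.fractions.to_numpy()
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("methylation fractions must lie in [0, 1]")
        if self.coverage is not None:
            if not self.coverage.index.equals(self.fractions.index):
                raise ValueError("coverage index mismatch")
            if (self.coverage.to_numpy() < 0).any():
                raise ValueError("coverage must be >= 0")
        dup = self.sites.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate site positions per chromosome")

    @property
    def mode(self) -> str:
        return "site-level" if self.coverage is not None else "probe-level"

    @property
    def samples(self) -> pd.Index:
        return self.fractions.columns

    def subset_sites(self, site_ids) -> "MethylationTable":
        return MethylationTable(
            self.sites.loc[site_ids],
            self.fractions.loc[site_ids],
            None if self.coverage is None else self.coverage.loc[site_ids],
            self.sample_groups,
        )

    def subset_samples(self, sample_ids) -> "MethylationTable":
        return MethylationTable(
            self.sites,
            self.fractions[list(sample_ids)],
            None if self.coverage is None else self.coverage[list(sample_ids)],
            None if self.sample_groups is None else self.sample_groups.loc[list(sample_ids)],
        )


@dataclass
class ExpressionMatrix:
    """Gene x sample non-negative expression values plus sample metadata."""

    values: pd.DataFrame
    sample_meta: Optional[pd.Series] = None  # group or cell type per sample
    biotypes: Optional[pd.Series] = None  # per-gene biotype

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)],
            self.sample_meta,
            None if self.biotypes is None else self.biotypes.loc[list(gene_ids)],
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)],
            None if self.sample_meta is None else self.sample_meta.loc[list(sample_ids)],
            self.biotypes,
        )
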
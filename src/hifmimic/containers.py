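"""Core in-memory containers shared across the pipeline stages.

The pipeline operates on three kinds of objects: an integer count matrix
(genes x samples) with optional gene lengths, a sample table mapping each
sequencing library to its experimental condition and replicate index, and
plain named gene sets. All three validate their invariants on construction
so downstream stages can assume well-formed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "SampleTable", "GeneSet"]


@dataclass(frozen=True)
class CountMatrix:
    """Gene-level counts for a multi-sample experiment.

    Parameters
    ----------
    counts
        DataFrame of non-negative integer counts, indexed by gene identifier,
        one column per sample.
    gene_lengths
        Optional Series of positive gene lengths in base pairs, indexed like
        ``counts``. Required for FPKM computation.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(values < 0):
            g, s = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if not np.allclose(values, np.round(values)):
            g, s = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise ValueError(
                f"non-integral count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if self.gene_lengths is not None:
            lengths = self.gene_lengths.reindex(self.counts.index)
            if lengths.isna().any():
                missing = lengths.index[lengths.isna()].tolist()
                raise ValueError(f"gene lengths missing for: {missing[:5]}")
            if (lengths <= 0).any():
                raise ValueError("gene lengths must be positive")
            object.__setattr__(self, "gene_lengths", lengths.astype(float))

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class SampleTable:
    """Maps each sample to an experimental condition and replicate index."""

    table: pd.DataFrame  # columns: sample, condition, replicate

    REQUIRED = ("sample", "condition", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        if self.table["sample"].duplicated().any():
            dups = self.table.loc[self.table["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample"])

    @property
    def conditions(self) -> list[str]:
        # unique conditions, first-appearance order
        return list(dict.fromkeys(self.table["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        sel = self.table.loc[self.table["condition"] == condition, "sample"]
        if sel.empty:
            raise KeyError(f"unknown condition {condition!r}")
        return sel.tolist()

    def validate_against(self, counts: CountMatrix) -> None:
        """Check that the table and a count matrix describe the same samples."""
        table_ids = set(self.sample_ids)
        matrix_ids = set(counts.sample_ids)
        if table_ids != matrix_ids:
            only_t = sorted(table_ids - matrix_ids)
            only_m = sorted(matrix_ids - table_ids)
            raise ValueError(
                f"sample mismatch; only in table: {only_t[:5]}, only in counts: {only_m[:5]}"
            )


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers (one GMT line)."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __init__(self, name: str, genes: Iterable[str], description: str = "") -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", frozenset(genes))
        object.__setattr__(self, "description", description)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))

    def intersection(self, other: "GeneSet" | Iterable[str]) -> "GeneSet":
        other_genes = other.genes if isinstance(other, GeneSet) else frozenset(other)
        return GeneSet(self.name, self.genes & other_genes, self.description)
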
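"""Readers and writers for the pipeline's plain-text formats.

Counts, sample metadata and gene lengths travel as TSV; gene sets as GMT
("name TAB description TAB gene..."); dendrograms as Newick with bootstrap
probabilities as internal-node labels and merge-height differences as branch
lengths. Every writer round-trips through the matching reader.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .clustering import Dendrogram
from .containers import CountMatrix, GeneSet, SampleTable

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_gene_lengths",
    "write_gene_lengths",
    "read_gmt",
    "write_gmt",
    "newick_string",
    "write_newick",
    "read_newick",
]


def read_counts(path: str | Path, lengths_path: str | Path | None = None) -> CountMatrix:
    """Read a counts TSV (first column gene_id, one column per sample).

    Validation errors name the offending gene and sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            gene = df.index[bad.isna()][0]
            raise ValueError(
                f"non-numeric count at gene {gene!r}, sample {col!r} in {path}"
            )
    lengths = read_gene_lengths(lengths_path) if lengths_path is not None else None
    return CountMatrix(df, gene_lengths=lengths)


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    out = counts.counts.copy()
    out.index.name = "gene_id"
    out.astype(np.int64).to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str})
    return SampleTable(df)


def write_metadata(samples: SampleTable, path: str | Path) -> None:
    samples.table.to_csv(path, sep="\t", index=False)


def read_gene_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float).rename("length_bp")


def write_gene_lengths(lengths: pd.Series, path: str | Path) -> None:
    out = lengths.rename("length_bp").to_frame()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file; malformed lines are reported with their line number."""
    sets = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"(expected name, description and at least one gene)"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: GMT line has no genes")
            sets.append(GeneSet(name, genes, description))
    return sets


def write_gmt(sets: list[GeneSet] | GeneSet, path: str | Path) -> None:
    if isinstance(sets, GeneSet):
        sets = [sets]
    with open(path, "w") as handle:
        for s in sets:
            handle.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def newick_string(dend: Dendrogram) -> str:
    """Serialise a dendrogram to Newick.

    Branch lengths are merge-height differences (leaves hang from their first
    merge at its full height); internal-node labels carry BP where present.
    """
    n = dend.n_leaves
    heights = np.concatenate([np.zeros(n), dend.merges[:, 2]])

    def render(node: int, parent_height: float) -> str:
        if node < n:
            return f"{dend.leaf_ids[node]}:{parent_height:.10g}"
        row = node - n
        a, b, h, _ = dend.merges[row]
        left = render(int(a), h - heights[int(a)])
        right = render(int(b), h - heights[int(b)])
        label = "" if dend.bp is None else f"{dend.bp[row]:.10g}"
        length = "" if parent_height is None else f":{parent_height:.10g}"
        return f"({left},{right}){label}{length}"

    root = 2 * n - 2
    a, b, h, _ = dend.merges[-1]
    left = render(int(a), h - heights[int(a)])
    right = render(int(b), h - heights[int(b)])
    label = "" if dend.bp is None else f"{dend.bp[-1]:.10g}"
    return f"({left},{right}){label};"


def write_newick(dend: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(newick_string(dend) + "\n")


def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a Newick file into a dendropy tree (internal labels preserved)."""
    return dendropy.Tree.get(
        path=str(path), schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )
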
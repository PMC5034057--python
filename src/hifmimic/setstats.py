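"""Set-level statistics: overlap/mimicry, permutation and hypergeometric
enrichment, and the core hypoxic signature check.

The central quantity is the *mimicry fraction*: the proportion of
hypoxia-regulated genes that an inhibitor treatment also regulates. Gene-set
enrichment against annotation lists (e.g. nearest genes to HIF1α/HIF2α
binding sites) is assessed empirically: repeatedly draw a random gene set of
the same size as the cluster from the analysis universe, record the overlap
with the annotation list, and take the fraction of null draws with an overlap
at least as large as observed. Because uniform equal-size sampling without
replacement makes the null overlap exactly hypergeometric, an analytic
hypergeometric tail is also provided and doubles as an independent oracle for
the sampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import GeneSet

__all__ = [
    "VennCounts",
    "OverlapEnrichment",
    "venn_counts",
    "mimicry_fraction",
    "permutation_overlap",
    "hypergeom_enrichment",
    "signature_status",
    "core_hypoxia_signature",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VennCounts:
    """Exclusive region cardinalities for 2-3 named sets.

    ``regions`` maps each non-empty name subset (frozenset) to the number of
    elements belonging to exactly those sets.
    """

    set_names: tuple[str, ...]
    regions: dict[frozenset[str], int]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def exclusive(self, *names: str) -> int:
        return self.regions.get(frozenset(names), 0)


def venn_counts(sets: Sequence[GeneSet]) -> VennCounts:
    """Exact Venn region counts by per-element membership pattern."""
    if not 2 <= len(sets) <= 3:
        raise ValueError(f"venn_counts supports 2-3 sets, got {len(sets)}")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("set names must be unique")
    regions: dict[frozenset[str], int] = {}
    universe = set().union(*(s.genes for s in sets))
    for gene in universe:
        pattern = frozenset(s.name for s in sets if gene in s)
        regions[pattern] = regions.get(pattern, 0) + 1
    return VennCounts(tuple(names), regions)


def mimicry_fraction(hypoxia_set: GeneSet, condition_set: GeneSet) -> float:
    """|hypoxia ∩ condition| / |hypoxia|: how much of the hypoxic response the
    treatment recapitulates."""
    if len(hypoxia_set) == 0:
        raise ValueError("hypoxia set is empty; mimicry fraction undefined")
    return len(hypoxia_set.genes & condition_set.genes) / len(hypoxia_set)


@dataclass(frozen=True)
class OverlapEnrichment:
    """Result of the empirical overlap-enrichment sampling test."""

    cluster_name: str
    annotation_name: str
    k_obs: int
    n_set: int
    n_annotation: int
    n_universe: int
    n_samples: int
    null_mean: float
    null_sd: float
    p_value: float
    fold_enrichment: float
    seed: int
    conservative: bool

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def permutation_overlap(
    cluster_set: GeneSet,
    annotation_set: GeneSet,
    universe: GeneSet,
    n_samples: int = 1000,
    seed: int = 0,
    conservative: bool = True,
) -> OverlapEnrichment:
    """Empirical overlap enrichment of a gene cluster against an annotation set.

    Each null draw samples |cluster| genes uniformly *without replacement*
    from the universe (a random gene set of equal size) and records its
    overlap with the annotation set. By default the empirical p carries the
    add-one correction p = (1 + #{null >= k_obs}) / (1 + n_samples), so p is
    never exactly zero; ``conservative=False`` gives the raw fraction of null
    draws with an overlap at least as large as observed. Annotation members
    outside the universe are dropped (and logged) before testing.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    univ = sorted(universe.genes)
    if len(cluster_set) > len(univ):
        raise ValueError("cluster set is larger than the universe")
    outside = cluster_set.genes - universe.genes
    if outside:
        raise ValueError(
            f"cluster members outside the universe: {sorted(outside)[:5]}"
        )
    dropped = annotation_set.genes - universe.genes
    if dropped:
        logger.info(
            "dropping %d annotation gene(s) outside the universe for %s",
            len(dropped), annotation_set.name,
        )
    ann = annotation_set.genes & universe.genes
    k_obs = len(cluster_set.genes & ann)

    univ_arr = np.array(univ)
    ann_mask = np.isin(univ_arr, sorted(ann))
    n_draw = len(cluster_set)
    rng = np.random.default_rng(seed)
    # vectorised equal-size sampling without replacement: per draw, take the
    # n_draw smallest random keys over the universe
    keys = rng.random((n_samples, len(univ_arr)))
    idx = np.argpartition(keys, n_draw - 1, axis=1)[:, :n_draw]
    null = ann_mask[idx].sum(axis=1)

    ge = int(np.sum(null >= k_obs))
    p = (1 + ge) / (1 + n_samples) if conservative else ge / n_samples
    null_mean = float(null.mean())
    fold = k_obs / max(null_mean, np.finfo(float).eps)
    return OverlapEnrichment(
        cluster_name=cluster_set.name,
        annotation_name=annotation_set.name,
        k_obs=k_obs,
        n_set=n_draw,
        n_annotation=int(ann_mask.sum()),
        n_universe=len(univ_arr),
        n_samples=n_samples,
        null_mean=null_mean,
        null_sd=float(null.std()),
        p_value=float(p),
        fold_enrichment=float(fold),
        seed=seed,
        conservative=conservative,
    )


def hypergeom_enrichment(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """Upper-tail hypergeometric p and fold enrichment.

    k annotated genes observed in a set of n, where K of the N universe genes
    carry the annotation. p = P(X >= k) for X ~ Hypergeom(N, K, n);
    fold enrichment = (k/n) / (K/N).
    """
    if min(k, n, K, N) < 0:
        raise ValueError("counts must be non-negative")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n={n}, K={K})")
    if n > N or K > N:
        raise ValueError(f"n={n} and K={K} must not exceed N={N}")
    if n == 0 or K == 0 or N == 0:
        raise ValueError("n, K and N must be positive for a meaningful test")
    p = float(hypergeom.sf(k - 1, N, K, n))
    fold = (k / n) / (K / N)
    return p, fold


def core_hypoxia_signature() -> GeneSet:
    """The packaged 12-gene core hypoxic signature (ADM ... VEGFA)."""
    text = (resources.files("hifmimic") / "data" / "core_hypoxia_signature.gmt").read_text()
    line = text.strip().splitlines()[0]
    name, description, *genes = line.split("\t")
    return GeneSet(name, genes, description)


def signature_status(
    de: pd.DataFrame,
    signature: GeneSet | None = None,
    fdr: float = 0.05,
    min_fc: float = 2.0,
) -> pd.DataFrame:
    """Per-signature-gene induction check against a hypoxia DE table.

    Returns one row per signature gene with its log2FC, q-value and a
    ``passes`` flag (linear FC > min_fc and q < fdr, up-regulation only).
    Genes absent from the DE table get status "missing" rather than an error.
    """
    if signature is None:
        signature = core_hypoxia_signature()
    cut = np.log2(min_fc)
    rows = []
    for gene in signature:
        if gene in de.index:
            lfc = float(de.at[gene, "log2FC"])
            q = float(de.at[gene, "qvalue"])
            passes = (lfc > cut) and (q < fdr)
            rows.append({"gene": gene, "log2FC": lfc, "qvalue": q,
                         "passes": passes, "status": "pass" if passes else "fail"})
        else:
            rows.append({"gene": gene, "log2FC": np.nan, "qvalue": np.nan,
                         "passes": False, "status": "missing"})
    return pd.DataFrame(rows).set_index("gene")
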
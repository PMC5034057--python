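"""Synthetic multi-condition RNA-seq experiments with a latent response structure.

This module emulates the design of a pharmacological hypoxia-mimicry study:
cultured cells profiled under normoxia, hypoxia, a broad-spectrum
2-oxoglutarate-oxygenase inhibitor (DMOG) and several selective HIF prolyl
hydroxylase inhibitors (PHIs: IOX2, BIQ, BNS), with a small number of
replicates per condition. Genes carry a latent response class:

* cluster 0 — unresponsive background (all true effects zero),
* cluster 1 — down in hypoxia and DMOG, attenuated down under the PHIs,
* cluster 2 — up in every treatment,
* cluster 3 — up in hypoxia and DMOG, attenuated up under the PHIs,
* cluster 4 — up only in hypoxia.

Counts are negative-binomial draws with mean ``s_j * mu_g * 2**effect(g, c)``
and variance ``mu + alpha * mu**2``. The generator is a pure function of its
config (seed included); independent sub-streams are spawned for gene/cluster
assignment, baselines, counts, gene lengths, and annotation sets so stages
can be re-run in isolation.

Annotation ("HIF target") gene sets are generated by per-cluster inclusion
probabilities, calibrated so the strongly HIF-dependent cluster (cluster 3)
reaches realistic overlap levels with HIF1α/HIF2α target lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSet, SampleTable

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "GeneSetSpec",
    "DEFAULT_CONDITIONS",
    "default_cluster_templates",
    "simulate_experiment",
    "simulate_gene_sets",
    "default_hif_target_specs",
    "mimicry_preset",
    "null_preset",
]

#: Condition labels in the order used throughout: reference first.
DEFAULT_CONDITIONS: tuple[str, ...] = ("normoxia", "hypoxia", "DMOG", "IOX2", "BIQ", "BNS")

REFERENCE_CONDITION = "normoxia"

#: Default mimicry calibration: fraction of hypoxia-responsive genes that each
#: treatment also regulates (a documented calibration, not a measured quantity).
DEFAULT_MIMICRY_FRACTIONS: dict[str, float] = {
    "DMOG": 0.50,
    "IOX2": 0.35,
    "BIQ": 0.35,
    "BNS": 0.25,
}


#: Per-PHI "lesser extent" attenuation factors (mean 0.30) and cluster-2
#: response scales, assigned to the selective inhibitors in listed order.
#: Distinct inhibitors respond similarly but not identically, which is what
#: lets replicates of the same treatment pair up in a sample dendrogram.
DEFAULT_PHI_ATTENUATIONS: tuple[float, ...] = (0.45, 0.30, 0.15)
DEFAULT_PHI_CLUSTER2_SCALES: tuple[float, ...] = (1.0, 0.85, 0.7)


def default_cluster_templates(
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    full_effect: float = 2.0,
    phi_attenuations: Sequence[float] = DEFAULT_PHI_ATTENUATIONS,
    phi_cluster2_scales: Sequence[float] = DEFAULT_PHI_CLUSTER2_SCALES,
) -> pd.DataFrame:
    """True log2-fold-change templates for the four canonical response clusters.

    Rows are latent clusters 1..4, columns the non-reference conditions.
    ``full_effect`` is the |log2FC| of a full response (default 2, i.e. a
    4-fold change, comfortably past a linear fold-change-2 calling threshold).
    "Lesser extent" PHI responses in clusters 1 and 3 are scaled by
    ``phi_attenuations`` and cluster-2 PHI responses ("to a varying degree")
    by ``phi_cluster2_scales``; both cycle over the selective inhibitors in
    listed order, so each inhibitor gets a similar but distinguishable
    profile.
    """
    noref = [c for c in conditions if c != REFERENCE_CONDITION]
    if not noref:
        raise ValueError("need at least one non-reference condition")
    phis = [c for c in noref if c not in ("hypoxia", "DMOG")]
    t = pd.DataFrame(0.0, index=pd.Index([1, 2, 3, 4], name="cluster"), columns=noref)
    f = full_effect
    if "hypoxia" in noref:
        t.loc[[2, 3, 4], "hypoxia"] = f
        t.loc[1, "hypoxia"] = -f
    if "DMOG" in noref:
        t.loc[[2, 3], "DMOG"] = f
        t.loc[1, "DMOG"] = -f
    for i, c in enumerate(phis):
        a = f * phi_attenuations[i % len(phi_attenuations)]
        t.loc[1, c] = -a
        t.loc[2, c] = f * phi_cluster2_scales[i % len(phi_cluster2_scales)]
        t.loc[3, c] = a
    return t


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic experiment; the generator is a pure
    function of this object.

    ``cluster_proportions`` covers latent cluster 0 (background) followed by
    one entry per row of ``effect_templates``. ``baseline_log_mean`` gives the
    (natural-log) location and spread of the lognormal baseline expression.
    ``dispersion`` is the NB dispersion alpha (variance = mu + alpha*mu^2),
    scalar or per-gene.
    """

    n_genes: int = 6000
    cluster_proportions: tuple[float, ...] = (0.70, 0.075, 0.075, 0.075, 0.075)
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates_per_condition: int = 2
    baseline_log_mean: tuple[float, float] = (math.log(100.0), 1.0)
    dispersion: float | np.ndarray = 0.05
    effect_templates: pd.DataFrame | None = None
    library_size_factors: np.ndarray | None = None
    gene_length_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        props = np.asarray(self.cluster_proportions, dtype=float)
        if np.any(props < 0) or np.any(props > 1):
            raise ValueError("cluster proportions must be in [0, 1]")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"cluster proportions sum to {props.sum()!r}, not 1")
        if REFERENCE_CONDITION not in self.conditions:
            raise ValueError(f"conditions must include the reference {REFERENCE_CONDITION!r}")
        disp = np.asarray(self.dispersion, dtype=float)
        if np.any(disp < 0):
            raise ValueError("dispersion must be >= 0")
        templates = self.effect_templates
        if templates is None:
            templates = default_cluster_templates(self.conditions)
            object.__setattr__(self, "effect_templates", templates)
        if len(templates) != len(props) - 1:
            raise ValueError(
                f"effect_templates has {len(templates)} rows but "
                f"cluster_proportions implies {len(props) - 1} responsive clusters"
            )
        noref = {c for c in self.conditions if c != REFERENCE_CONDITION}
        unknown = set(templates.columns) - noref
        if unknown:
            raise ValueError(f"effect_templates columns not among conditions: {sorted(unknown)}")
        if set(templates.columns) != noref:
            missing = sorted(noref - set(templates.columns))
            raise ValueError(f"effect_templates missing columns for conditions: {missing}")
        if self.library_size_factors is not None:
            s = np.asarray(self.library_size_factors, dtype=float)
            if np.any(s <= 0):
                raise ValueError("library size factors must be positive")
            if s.size != self.n_samples:
                raise ValueError(
                    f"expected {self.n_samples} library size factors, got {s.size}"
                )

    @property
    def reference(self) -> str:
        return REFERENCE_CONDITION

    @property
    def n_samples(self) -> int:
        return len(self.conditions) * self.replicates_per_condition

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with fields replaced (templates re-validated)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted alongside a simulated experiment.

    ``genes`` is indexed by gene id with columns ``cluster`` (latent label,
    0 = background), ``mu`` (baseline mean at size factor 1) and ``alpha``
    (NB dispersion). ``effects`` holds the true log2 fold change per gene and
    condition (reference column all zeros). Genes are in latent cluster 0 iff
    their whole effect vector is zero.
    """

    genes: pd.DataFrame
    effects: pd.DataFrame
    seed: int

    def cluster_members(self, cluster: int) -> list[str]:
        return self.genes.index[self.genes["cluster"] == cluster].tolist()

    def regulated_genes(self, condition: str, min_abs_log2fc: float = 0.0) -> GeneSet:
        """Genes with a true |log2FC| strictly above a floor in one condition."""
        eff = self.effects[condition]
        members = eff.index[eff.abs() > min_abs_log2fc]
        return GeneSet(f"true_{condition}_regulated", members)


@dataclass(frozen=True)
class GeneSetSpec:
    """Recipe for an annotation gene set: per-latent-cluster inclusion probability."""

    name: str
    inclusion_probability: Mapping[int, float]
    description: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        for cluster, p in self.inclusion_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"inclusion probability for cluster {cluster} is {p}, outside [0, 1]"
                )


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_experiment(
    config: SimConfig,
) -> tuple[CountMatrix, SampleTable, SyntheticTruth]:
    """Draw a complete synthetic experiment from ``config``.

    Returns the count matrix (with gene lengths attached), the sample table,
    and the ground truth. Counts for gene g in sample j of condition c are
    NB(mean = s_j * mu_g * 2**effect(g, c), variance = mean + alpha*mean^2);
    alpha = 0 degenerates to Poisson.
    """
    rng_assign, rng_base, rng_counts, rng_len = _substreams(config.seed, 4)

    n = config.n_genes
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(n)], name="gene_id")
    props = np.asarray(config.cluster_proportions, dtype=float)
    clusters = rng_assign.choice(len(props), size=n, p=props)

    meanlog, sdlog = config.baseline_log_mean
    mu = rng_base.lognormal(mean=meanlog, sigma=sdlog, size=n)
    alpha = np.broadcast_to(np.asarray(config.dispersion, dtype=float), (n,)).copy()

    # True log2FC per gene x condition (reference column zero).
    effects = pd.DataFrame(0.0, index=gene_ids, columns=list(config.conditions))
    templates = config.effect_templates
    for row_pos, cluster_label in enumerate(templates.index):
        mask = clusters == row_pos + 1
        for cond in templates.columns:
            effects.loc[mask, cond] = templates.iloc[row_pos][cond]

    # Canonical labelling: a gene with no true effect is background by definition.
    null_rows = (effects.to_numpy() == 0.0).all(axis=1)
    clusters = np.where(null_rows, 0, clusters)

    reps = config.replicates_per_condition
    sample_rows = [
        {"sample": f"{cond}_{r + 1}", "condition": cond, "replicate": r + 1}
        for cond in config.conditions
        for r in range(reps)
    ]
    samples = SampleTable(pd.DataFrame(sample_rows))
    sample_conditions = [row["condition"] for row in sample_rows]

    s = (
        np.ones(config.n_samples)
        if config.library_size_factors is None
        else np.asarray(config.library_size_factors, dtype=float)
    )
    mean = mu[:, None] * np.power(2.0, effects[sample_conditions].to_numpy()) * s[None, :]

    counts = np.empty(mean.shape, dtype=np.int64)
    poisson_rows = alpha == 0.0
    if poisson_rows.any():
        counts[poisson_rows] = rng_counts.poisson(mean[poisson_rows])
    if (~poisson_rows).any():
        a = alpha[~poisson_rows][:, None]
        m = mean[~poisson_rows]
        r = 1.0 / a
        counts[~poisson_rows] = rng_counts.negative_binomial(r, r / (r + m))

    lengths = pd.Series(
        rng_len.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=n),
        index=gene_ids,
        name="length_bp",
        dtype=float,
    )
    count_matrix = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=[r["sample"] for r in sample_rows]),
        gene_lengths=lengths,
    )
    truth = SyntheticTruth(
        genes=pd.DataFrame({"cluster": clusters, "mu": mu, "alpha": alpha}, index=gene_ids),
        effects=effects,
        seed=config.seed,
    )
    return count_matrix, samples, truth


def simulate_gene_sets(
    truth: SyntheticTruth, specs: Sequence[GeneSetSpec]
) -> list[GeneSet]:
    """Draw annotation gene sets; each gene enters each set independently with
    its latent cluster's inclusion probability."""
    sets = []
    clusters = truth.genes["cluster"].to_numpy()
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        p = np.array([spec.inclusion_probability.get(int(c), 0.0) for c in clusters])
        member = rng.random(len(p)) < p
        sets.append(GeneSet(spec.name, truth.genes.index[member], spec.description))
    return sets


def default_hif_target_specs(seed: int = 0) -> list[GeneSetSpec]:
    """HIF1α/HIF2α-like target set recipes.

    The inclusion probability for cluster 3 (genes up in hypoxia/DMOG but
    attenuated under selective PHIs — the most directly HIF-dependent class)
    is calibrated to 0.30 for HIF1α and 0.22 for HIF2α; the other up-regulated
    clusters get smaller probabilities and the background a low false-positive
    rate, mirroring the ChIP-derived target lists such sets come from.
    """
    children = np.random.SeedSequence(seed).spawn(2)
    return [
        GeneSetSpec(
            "HIF1A_targets",
            {0: 0.02, 1: 0.02, 2: 0.15, 3: 0.30, 4: 0.15},
            "synthetic HIF1a-binding nearest-gene list",
            seed=int(children[0].generate_state(1)[0] % 2**31),
        ),
        GeneSetSpec(
            "HIF2A_targets",
            {0: 0.015, 1: 0.02, 2: 0.10, 3: 0.22, 4: 0.10},
            "synthetic HIF2a-binding nearest-gene list",
            seed=int(children[1].generate_state(1)[0] % 2**31),
        ),
    ]


def mimicry_preset(
    n_genes: int = 6000,
    responsive_fraction: float = 0.12,
    fractions: Mapping[str, float] | None = None,
    effect: float = 2.0,
    replicates_per_condition: int = 2,
    seed: int = 0,
    **kwargs,
) -> SimConfig:
    """Config whose true mimicry fractions are set by construction.

    Every responsive gene is hypoxia-induced (log2FC = ``effect``); each
    treatment independently recapitulates the induction with probability
    ``fractions[treatment]`` (defaults 0.50 DMOG / 0.35 IOX2 / 0.35 BIQ /
    0.25 BNS). Implemented by enumerating all treatment-response patterns as
    latent clusters with product proportions, so the per-treatment marginal
    recapitulation fraction among hypoxia-responsive genes is exact in
    expectation.

    ``responsive_fraction`` keeps the regulated share of the transcriptome
    realistic (~10% in studies of this design); pushing it far higher breaks
    the majority-unchanged assumption behind median-of-ratios normalisation
    and biases every estimated fold change toward zero.
    """
    fractions = dict(DEFAULT_MIMICRY_FRACTIONS if fractions is None else fractions)
    treatments = list(fractions)
    conditions = tuple([REFERENCE_CONDITION, "hypoxia", *treatments])
    rows = []
    proportions = [1.0 - responsive_fraction]
    for pattern in product([1, 0], repeat=len(treatments)):
        row = {"hypoxia": effect}
        prob = responsive_fraction
        for hit, treatment in zip(pattern, treatments):
            row[treatment] = effect * hit
            prob *= fractions[treatment] if hit else 1.0 - fractions[treatment]
        rows.append(row)
        proportions.append(prob)
    templates = pd.DataFrame(rows, index=pd.RangeIndex(1, len(rows) + 1, name="cluster"))
    return SimConfig(
        n_genes=n_genes,
        cluster_proportions=tuple(proportions),
        conditions=conditions,
        replicates_per_condition=replicates_per_condition,
        effect_templates=templates,
        seed=seed,
        **kwargs,
    )


def null_preset(
    n_genes: int = 10000,
    conditions: tuple[str, ...] = (REFERENCE_CONDITION, "hypoxia"),
    replicates_per_condition: int = 3,
    dispersion: float = 0.05,
    seed: int = 0,
    **kwargs,
) -> SimConfig:
    """Config with no true effects at all — for type-I-error calibration."""
    noref = [c for c in conditions if c != REFERENCE_CONDITION]
    templates = pd.DataFrame(
        0.0, index=pd.Index([1], name="cluster"), columns=noref
    )
    return SimConfig(
        n_genes=n_genes,
        cluster_proportions=(1.0, 0.0),
        conditions=conditions,
        replicates_per_condition=replicates_per_condition,
        dispersion=dispersion,
        effect_templates=templates,
        seed=seed,
        **kwargs,
    )
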
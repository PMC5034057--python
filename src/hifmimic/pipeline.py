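"""End-to-end orchestration and the PHD/FIH-dependence classification rule.

``classify_response`` formalises the three-way taxonomy of hypoxia-induced
genes by their requirement for HIF hydroxylase inhibition:

* class I (``I_PHD_sufficient``) — fully induced by a selective PHD
  inhibitor alone;
* class II (``II_PHD_plus_FIH``) — requiring combined PHD and FIH inhibition
  for full induction;
* class III (``III_refractory``) — not substantially induced regardless of
  PHD and FIH inhibition.

"Full" induction is judged on the relative induction ratio
r_c = log2FC_c / log2FC_hypoxia against a threshold tau_full (default 0.7);
multiple PHIs are summarised by the most favourable (maximum) ratio, since
selective PHIs with different scaffolds behave similarly. Ratios are scale
free, so the classification is invariant to positive rescaling of all fold
changes. Genes failing the hypoxia induction gate (q < fdr and linear
FC > min_fc) are ``not_hypoxia_induced``; genes needing the combo contrast
when none was measured are ``unclassifiable``.

``run_pipeline`` wires every stage together: simulate (or load) counts ->
normalise -> DE per contrast -> sample dendrogram with bootstrap support ->
k-means response clusters of hypoxia-regulated genes -> overlap/mimicry ->
permutation and hypergeometric enrichment -> response classification. All
randomness derives from one seed via spawned sub-streams, so a config
reproduces its report bundle exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .clustering import (
    GeneClusterAssignment,
    Dendrogram,
    bootstrap_support,
    kmeans_assign,
    label_clusters_by_template,
    standardize_rows,
)
from .containers import CountMatrix, GeneSet, SampleTable
from .diffexp import call_regulated, compute_fpkm, de_analysis, log_expression
from .setstats import (
    OverlapEnrichment,
    VennCounts,
    hypergeom_enrichment,
    mimicry_fraction,
    permutation_overlap,
    venn_counts,
)
from .simdata import (
    SimConfig,
    SyntheticTruth,
    default_hif_target_specs,
    simulate_experiment,
    simulate_gene_sets,
)

__all__ = [
    "ResponseClassification",
    "PipelineConfig",
    "ReportBundle",
    "classify_response",
    "run_pipeline",
    "write_report",
]

logger = logging.getLogger(__name__)

CLASS_I = "I_PHD_sufficient"
CLASS_II = "II_PHD_plus_FIH"
CLASS_III = "III_refractory"
NOT_INDUCED = "not_hypoxia_induced"
UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class ResponseClassification:
    """Per-gene PHD/FIH-dependence classes plus the thresholds used.

    ``table`` is indexed by gene id with columns ``log2FC_hypoxia``,
    ``r_phi``, ``r_combo`` (NaN when undefined) and ``response_class``.
    ``repressed`` lists hypoxia down-regulated genes, which are excluded from
    the induction taxonomy and reported separately.
    """

    table: pd.DataFrame
    tau_full: float
    fdr: float
    min_fc: float
    repressed: tuple[str, ...] = ()

    def genes_in_class(self, response_class: str) -> list[str]:
        sel = self.table["response_class"] == response_class
        return self.table.index[sel].tolist()

    def class_counts(self) -> pd.Series:
        return self.table["response_class"].value_counts()


def classify_response(
    de_by_contrast: Mapping[str, pd.DataFrame],
    hypoxia_key: str,
    phi_keys: Sequence[str],
    combo_key: str | None = None,
    tau_full: float = 0.7,
    fdr: float = 0.05,
    min_fc: float = 2.0,
) -> ResponseClassification:
    """Assign every gene a PHD/FIH-dependence class (see module docstring)."""
    if hypoxia_key not in de_by_contrast:
        raise ValueError(f"hypoxia contrast {hypoxia_key!r} missing from DE results")
    if not phi_keys:
        raise ValueError("at least one PHI contrast is required")
    missing = [k for k in phi_keys if k not in de_by_contrast]
    if missing:
        raise ValueError(f"PHI contrasts missing from DE results: {missing}")
    if combo_key is not None and combo_key not in de_by_contrast:
        raise ValueError(f"combo contrast {combo_key!r} missing from DE results")
    if not 0.0 < tau_full <= 1.0:
        raise ValueError(f"tau_full must lie in (0, 1], got {tau_full}")

    hyp = de_by_contrast[hypoxia_key]
    cut = math.log2(min_fc)
    lfc_hyp = hyp["log2FC"]
    induced = (hyp["qvalue"] < fdr) & (lfc_hyp > cut)
    repressed = hyp.index[(hyp["qvalue"] < fdr) & (lfc_hyp < -cut)]

    phi_lfc = pd.concat(
        [de_by_contrast[k]["log2FC"].reindex(hyp.index) for k in phi_keys], axis=1
    )
    r_phi = phi_lfc.max(axis=1) / lfc_hyp
    r_combo = (
        de_by_contrast[combo_key]["log2FC"].reindex(hyp.index) / lfc_hyp
        if combo_key is not None
        else pd.Series(np.nan, index=hyp.index)
    )

    classes = pd.Series(NOT_INDUCED, index=hyp.index, name="response_class")
    full_phi = r_phi >= tau_full
    classes[induced & full_phi] = CLASS_I
    if combo_key is not None:
        classes[induced & ~full_phi & (r_combo >= tau_full)] = CLASS_II
        classes[induced & ~full_phi & (r_combo < tau_full)] = CLASS_III
    else:
        # without a combo contrast, class II and III cannot be separated
        classes[induced & ~full_phi] = UNCLASSIFIABLE

    table = pd.DataFrame(
        {
            "log2FC_hypoxia": lfc_hyp,
            "r_phi": r_phi.where(induced),
            "r_combo": r_combo.where(induced),
            "response_class": classes,
        }
    )
    return ResponseClassification(
        table=table,
        tau_full=tau_full,
        fdr=fdr,
        min_fc=min_fc,
        repressed=tuple(repressed),
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to (re)run the full analysis.

    Provide either ``sim`` (a SimConfig) or file paths for counts, metadata
    and gene lengths. Annotation gene sets come from ``gene_sets_path`` (GMT)
    or, when simulating, are generated from the default HIF-target recipes.
    """

    sim: SimConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    lengths_path: str | None = None
    gene_sets_path: str | None = None
    hypoxia_condition: str = "hypoxia"
    dmog_condition: str | None = "DMOG"
    phi_conditions: tuple[str, ...] = ("IOX2", "BIQ", "BNS")
    combo_condition: str | None = None
    reference: str = "normoxia"
    fdr: float = 0.05
    min_fc: float = 2.0
    k: int = 4
    n_boot: int = 1000
    n_perm: int = 1000
    universe: str = "tested"
    tau_full: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim is None and self.counts_path is None:
            raise ValueError("provide either a SimConfig or a counts path")
        if self.sim is not None and self.counts_path is not None:
            raise ValueError("provide a SimConfig or file paths, not both")
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must lie in (0, 1)")
        if self.min_fc <= 1.0:
            raise ValueError("min_fc must exceed 1")
        if self.universe not in ("tested", "all"):
            raise ValueError("universe policy must be 'tested' or 'all'")
        if not 0.0 < self.tau_full <= 1.0:
            raise ValueError("tau_full must lie in (0, 1]")
        if self.k < 1 or self.n_boot < 1 or self.n_perm < 1:
            raise ValueError("k, n_boot and n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "sim" in raw and raw["sim"] is not None:
            sim = raw.pop("sim")
            templates = sim.pop("effect_templates", None)
            if templates is not None:
                templates = pd.DataFrame(templates).T
                templates.index = templates.index.astype(int)
            raw["sim"] = SimConfig(
                effect_templates=templates,
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in sim.items()
                },
            )
        for key in ("phi_conditions",):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = asdict(self)
        if self.sim is not None:
            sim = out["sim"]
            sim["effect_templates"] = {
                str(idx): row.to_dict()
                for idx, row in self.sim.effect_templates.iterrows()
            }
            sim["dispersion"] = (
                self.sim.dispersion.tolist()
                if isinstance(self.sim.dispersion, np.ndarray)
                else self.sim.dispersion
            )
            sim["library_size_factors"] = (
                self.sim.library_size_factors.tolist()
                if self.sim.library_size_factors is not None
                else None
            )
        return out

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class ReportBundle:
    """Every artefact of one pipeline run, plus a manifest that pins it."""

    config: PipelineConfig
    counts: CountMatrix
    samples: SampleTable
    truth: SyntheticTruth | None
    de: dict[str, pd.DataFrame]
    regulated: dict[str, GeneSet]
    sample_dendrogram: Dendrogram
    gene_clusters: GeneClusterAssignment | None
    venn: VennCounts | None
    mimicry: pd.Series
    enrichments: list[OverlapEnrichment]
    hypergeom: pd.DataFrame
    classification: ResponseClassification
    annotation_sets: list[GeneSet]
    manifest: dict


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage of the analysis; see the module docstring."""
    ss_boot, ss_kmeans, ss_perm, ss_sets = np.random.SeedSequence(config.seed).spawn(4)

    # --- load or simulate -------------------------------------------------
    truth = None
    annotation_sets: list[GeneSet] = []
    if config.sim is not None:
        counts, samples, truth = simulate_experiment(config.sim)
        annotation_sets = simulate_gene_sets(
            truth, default_hif_target_specs(_child_seed(ss_sets))
        )
        logger.info("simulate: %d genes x %d samples", counts.n_genes, counts.n_samples)
    else:
        counts = hio.read_counts(config.counts_path, lengths_path=config.lengths_path)
        samples = hio.read_metadata(config.metadata_path)
    samples.validate_against(counts)
    if config.gene_sets_path is not None:
        annotation_sets = hio.read_gmt(config.gene_sets_path)

    wanted = [config.hypoxia_condition, *config.phi_conditions]
    if config.dmog_condition is not None:
        wanted.append(config.dmog_condition)
    if config.combo_condition is not None:
        wanted.append(config.combo_condition)
    present = set(samples.conditions)
    absent = [c for c in [config.reference, *wanted] if c not in present]
    if absent:
        raise ValueError(f"conditions named in the config are absent from metadata: {absent}")

    # --- differential expression -----------------------------------------
    contrasts = [c for c in samples.conditions if c != config.reference]
    de = de_analysis(
        counts, samples, conditions=contrasts, reference=config.reference,
        fdr=config.fdr, min_fc=config.min_fc,
    )
    regulated = {
        cond: call_regulated(tab, fdr=config.fdr, min_fc=config.min_fc,
                             direction="both", name=f"{cond}_regulated")
        for cond, tab in de.items()
    }
    logger.info("de: %s", {c: len(s) for c, s in regulated.items()})

    # --- sample clustering with bootstrap support -------------------------
    fpkm = compute_fpkm(counts)
    logexpr = log_expression(fpkm, pseudocount=1.0)
    dendrogram = bootstrap_support(
        logexpr.values, n_boot=config.n_boot, seed=_child_seed(ss_boot)
    )
    logger.info("cluster: dendrogram over %d samples, %d resamples",
                dendrogram.n_leaves, config.n_boot)

    # --- gene response clusters -------------------------------------------
    hyp_set = regulated[config.hypoxia_condition]
    gene_clusters = None
    if len(hyp_set) >= config.k:
        cond_means = pd.DataFrame(
            {
                cond: logexpr.values.loc[list(hyp_set), samples.samples_for(cond)].mean(axis=1)
                for cond in samples.conditions
            }
        )
        profiles = standardize_rows(cond_means)
        gene_clusters = kmeans_assign(
            profiles, k=config.k, seed=_child_seed(ss_kmeans)
        )
        if config.sim is not None and config.k == len(config.sim.effect_templates):
            templates = config.sim.effect_templates.copy()
            templates.insert(0, config.reference, 0.0)
            templates = standardize_rows(templates[list(samples.conditions)])
            semantic = label_clusters_by_template(gene_clusters.centroids, templates)
            gene_clusters = GeneClusterAssignment(
                labels=gene_clusters.labels,
                centroids=gene_clusters.centroids,
                inertia=gene_clusters.inertia,
                semantic_labels=semantic,
            )
        logger.info("cluster: k-means k=%d on %d hypoxia-regulated genes",
                    config.k, len(hyp_set))

    # --- overlap / mimicry -------------------------------------------------
    mimicry = pd.Series(
        {
            cond: mimicry_fraction(hyp_set, regulated[cond])
            for cond in de
        },
        name="mimicry_fraction",
    )
    venn = None
    if config.dmog_condition is not None:
        venn = venn_counts([hyp_set, regulated[config.dmog_condition]])

    # --- enrichment against annotation sets --------------------------------
    if config.universe == "tested":
        tested = de[config.hypoxia_condition]["baseMean"] > 0
        universe = GeneSet("tested_genes", de[config.hypoxia_condition].index[tested])
    else:
        universe = GeneSet("all_genes", counts.gene_ids)
    enrichments: list[OverlapEnrichment] = []
    hyper_rows = []
    if annotation_sets and gene_clusters is not None:
        perm_children = ss_perm.spawn(
            len(annotation_sets) * gene_clusters.k
        )
        i = 0
        for cluster_id in gene_clusters.centroids.index:
            members = [g for g in gene_clusters.members(cluster_id) if g in universe.genes]
            if not members:
                i += len(annotation_sets)
                continue
            semantic = (
                gene_clusters.semantic_labels.get(cluster_id)
                if gene_clusters.semantic_labels
                else None
            )
            cluster_set = GeneSet(
                f"cluster{semantic if semantic is not None else cluster_id}", members
            )
            for ann in annotation_sets:
                enr = permutation_overlap(
                    cluster_set, ann, universe,
                    n_samples=config.n_perm, seed=_child_seed(perm_children[i]),
                )
                i += 1
                enrichments.append(enr)
                p_hyp, fold = hypergeom_enrichment(
                    enr.k_obs, enr.n_set, enr.n_annotation, enr.n_universe
                )
                hyper_rows.append(
                    {"cluster": cluster_set.name, "annotation": ann.name,
                     "k": enr.k_obs, "n": enr.n_set, "K": enr.n_annotation,
                     "N": enr.n_universe, "p_hypergeom": p_hyp, "fold_enrichment": fold}
                )
    hypergeom_table = pd.DataFrame(hyper_rows)

    # --- response classification -------------------------------------------
    classification = classify_response(
        de,
        hypoxia_key=config.hypoxia_condition,
        phi_keys=list(config.phi_conditions),
        combo_key=config.combo_condition,
        tau_full=config.tau_full,
        fdr=config.fdr,
        min_fc=config.min_fc,
    )

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "package": "hifmimic",
        "version": _package_version(),
        "n_genes": int(counts.n_genes),
        "n_samples": int(counts.n_samples),
    }
    return ReportBundle(
        config=config,
        counts=counts,
        samples=samples,
        truth=truth,
        de=de,
        regulated=regulated,
        sample_dendrogram=dendrogram,
        gene_clusters=gene_clusters,
        venn=venn,
        mimicry=mimicry,
        enrichments=enrichments,
        hypergeom=hypergeom_table,
        classification=classification,
        annotation_sets=annotation_sets,
        manifest=manifest,
    )


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("hifmimic")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def write_report(bundle: ReportBundle, outdir: str | Path) -> dict:
    """Write every artefact as TSV/JSON/GMT/Newick and return the manifest
    (now including a content hash of each written file)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    hio.write_counts(bundle.counts, outdir / "counts.tsv")
    hio.write_metadata(bundle.samples, outdir / "metadata.tsv")
    if bundle.counts.gene_lengths is not None:
        hio.write_gene_lengths(bundle.counts.gene_lengths, outdir / "gene_lengths.tsv")
    for cond, tab in bundle.de.items():
        out = tab.copy()
        out.index.name = "gene_id"
        out.to_csv(outdir / f"de_{cond}.tsv", sep="\t")
    hio.write_gmt(list(bundle.regulated.values()), outdir / "regulated_sets.gmt")
    if bundle.annotation_sets:
        hio.write_gmt(bundle.annotation_sets, outdir / "annotation_sets.gmt")
    hio.write_newick(bundle.sample_dendrogram, outdir / "sample_dendrogram.nwk")
    if bundle.gene_clusters is not None:
        labels = bundle.gene_clusters.labels.to_frame()
        labels.index.name = "gene_id"
        if bundle.gene_clusters.semantic_labels:
            labels["semantic_label"] = [
                bundle.gene_clusters.semantic_labels.get(c, c)
                for c in bundle.gene_clusters.labels
            ]
        labels.to_csv(outdir / "gene_clusters.tsv", sep="\t")
    bundle.mimicry.to_frame().to_csv(outdir / "mimicry.tsv", sep="\t")
    if bundle.enrichments:
        pd.DataFrame([e.as_dict() for e in bundle.enrichments]).to_csv(
            outdir / "permutation_enrichment.tsv", sep="\t", index=False
        )
    if not bundle.hypergeom.empty:
        bundle.hypergeom.to_csv(outdir / "hypergeom_enrichment.tsv", sep="\t", index=False)
    cls = bundle.classification.table.copy()
    cls.index.name = "gene_id"
    cls.to_csv(outdir / "response_classes.tsv", sep="\t")
    if bundle.truth is not None:
        truth = bundle.truth.genes.join(bundle.truth.effects, rsuffix="_log2fc")
        truth.index.name = "gene_id"
        truth.to_csv(outdir / "truth.tsv", sep="\t")

    manifest = dict(bundle.manifest)
    manifest["files"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(outdir.iterdir())
        if p.name != "manifest.json"
    }
    manifest["config"] = bundle.config.to_dict()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
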
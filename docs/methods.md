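# Methods

This note documents the models, estimators and design choices behind
`hifmimic`, in the order the pipeline runs them. Everything stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external data.

## Synthetic experiment model

The generator (`hifmimic.simdata`) emulates a pharmacological hypoxia-mimicry
study: one reference condition (normoxia), hypoxia, a broad-spectrum
2OG-oxygenase inhibitor (DMOG) and three selective PHD inhibitors (IOX2,
BIQ, BNS), with `replicates_per_condition = 2` by default. Counts are drawn
per gene g and sample j as

    K_gj ~ NB(mean = s_j · μ_g · 2^{β_{g,c(j)}},  var = mean + α·mean²)

with baseline μ_g ~ LogNormal(log 100, 1) (typical bulk RNA-seq magnitudes),
NB dispersion α = 0.05 (a clean, moderately replicable cell-line experiment),
library size factors s_j = 1 unless configured, and true log₂ fold changes
β taken from per-cluster effect templates. α = 0 degenerates to Poisson.
Gene lengths are uniform on 500–5000 bp and only matter for FPKM.

Latent response clusters (defaults: 70% background, 7.5% each of clusters
1–4):

| cluster | hypoxia | DMOG | PHIs |
|---|---|---|---|
| 1 | −2 | −2 | −2·a_i |
| 2 | +2 | +2 | +2·b_i |
| 3 | +2 | +2 | +2·a_i |
| 4 | +2 | 0 | 0 |

The full effect ±2 (a 4-fold change) sits comfortably past the FC > 2
calling gate, so the templates exercise both sides of the gate. The PHI
attenuations a_i = (0.45, 0.30, 0.15) and cluster-2 scales
b_i = (1.0, 0.85, 0.7) are *distinct per inhibitor*, with mean attenuation
0.30. Giving the three PHIs identical templates would make them
statistically indistinguishable — replicates of one PHI would be no closer
to each other than to another PHI's samples, and no sample dendrogram could
support replicate pairs as clades. Distinct-but-similar profiles are also
what "the selective inhibitors behave similarly, to a varying degree" means
operationally. The default `n_genes = 6000` approaches a realistically sized
expressed-gene analysis; at a few thousand genes the bootstrap fluctuation
of Manhattan distances (which grows as √G) is comparable to the inter-PHI
signal (which grows as G) and replicate support degrades.

A gene whose realised effect vector is identically zero is relabelled to
background cluster 0, making "cluster 0 ⇔ no true effect" an invariant.

Annotation ("HIF-target") gene sets are drawn by per-cluster inclusion
probabilities. The defaults put the strongest probability on cluster 3 —
genes up in hypoxia/DMOG but attenuated under selective PHIs, the most
directly HIF-dependent class — calibrated to 0.30 (HIF1α-like) and 0.22
(HIF2α-like), with smaller probabilities for the other up-regulated clusters
and a low background rate, mimicking ChIP-derived nearest-gene lists.

The **mimicry preset** constructs experiments whose true mimicry fractions
are known: every responsive gene is hypoxia-induced (+2), and each treatment
independently recapitulates the induction with probability 0.50 (DMOG),
0.35 (IOX2), 0.35 (BIQ) or 0.25 (BNS); all 2⁴ response patterns are
enumerated as latent clusters with product proportions. The responsive share
of the genome is 12% — deliberately realistic, because median-of-ratios
normalisation assumes a majority of unchanged genes; pushing the share far
higher folds the treatment signal into the size factors and biases every
estimated fold change toward zero.

All randomness flows from one seed through spawned `SeedSequence`
sub-streams (assignment, baselines, counts, lengths, gene sets, bootstrap,
k-means, permutation), so stages can be re-run in isolation and a config
reproduces its outputs bit-identically.

**What the generator does not model:** batch effects, GC/length bias,
isoform structure, correlated genes, outlier samples, or library-size
heterogeneity beyond explicit size factors. Tests passing on this generator
therefore demonstrate correctness of the estimators and the pipeline's
logic under its stated model, not robustness to real-data artefacts.

## Differential expression

Size factors are median-of-ratios over genes with no zero count, rescaled
to geometric mean 1. FPKM is count·10⁹/(length·total), with totals
defaulting to column sums; clustering uses log₂(FPKM+1).

Dispersions are method-of-moments on normalised counts:
`raw = max(α₀, (v − m)/m²)` with v the within-condition variance pooled
over replicated conditions, m the mean over those samples and floor
α₀ = 10⁻⁴. The per-gene raw estimate keeps weight 0.3 against the trimmed
(1% per tail) global mean of the raw values, **and the result is never
allowed below that global value**. Two deliberate choices here:

* *Light trimming.* At 2–3 replicates the sampling distribution of the raw
  estimator is strongly right-skewed; a conventional 10% trim biases the
  global centre down by ~12% of its value, which inflates every Wald
  statistic.
* *Conservative (max-type) sharing.* A gene whose replicates landed close
  together by chance gets both a small dispersion estimate and, often, an
  inflated mean split; letting the per-gene estimate lower the variance
  couples the two and produces far-tail false positives that survive BH at
  10⁴ genes. Per-gene information may therefore raise a dispersion above
  the shared value (genuinely overdispersed genes stay testable) but never
  lower it — the classic conservative sharing mode of count-based DE tools.
  With this estimator the null calibration is clean: raw-p rejection at
  0.05 lands at 0.042–0.049 across seeds, and the combined q < 0.05 & FC > 2
  gate stays silent on 20/20 null experiments of 10⁴ genes.

The contrast statistic is a Wald z on log₂FC = log₂((m_t + c)/(m_r + c))
with pseudocount c = 0.5 (finite fold changes at zero counts) and
delta-method variance (m + αm²)/(n·(m + c)²·ln²2) per group, referred to a
standard normal. Identical groups give log₂FC = 0 and p = 1 exactly;
swapping the groups negates log₂FC and preserves p. BH adjustment is
per-contrast; the calling gate is q < fdr and linear |FC| > min_fc applied
directionally (up and down sets separately). No GLM covariates, no
fold-change shrinkage, no exact tests — the pipeline consumes set-level
outputs, and a transparent deterministic statistic is worth more here than
a cloned tool.

## Clustering

Sample trees use Manhattan distance with Ward's linkage. Ward on a
non-Euclidean dissimilarity is geometrically improper but is the established
convention of the tooling this mirrors; we apply the Lance–Williams Ward
update to *squared* input distances and report heights on the original
scale (the Ward.D2 convention). Ties break deterministically by index
order. On Euclidean inputs this provably equals direct ESS-minimising
agglomeration, which the test suite exploits as a brute-force oracle.

Node support is the plain bootstrap probability: resample genes with
replacement (1000×), recluster the samples, and report the percentage of
resamples in which a node's exact leaf set recurs. No approximately-unbiased
correction is attempted.

Gene response clusters: hypoxia-regulated genes (up ∪ down), profiled as
per-condition replicate means of log₂(FPKM+1), z-scored per gene
(population SD; constant rows map to zeros with a warning), partitioned by
k-means with k = 4, k-means++ initialisation, 25 restarts, best inertia,
fixed seed (scikit-learn's Lloyd implementation). Centroids are matched
one-to-one onto the effect templates (reference column 0 inserted, rows
z-scored identically) by Hungarian assignment on cosine similarity, which
converts arbitrary k-means labels into the canonical cluster-1..4 semantics.

## Set statistics

The mimicry fraction of treatment T is |H ∩ T|/|H| over the
hypoxia-regulated set H. The permutation overlap test draws, 1000 times by
default, a uniform random gene *set* of the cluster's size (without
replacement) from the universe and counts overlaps with the annotation list;
p = (1 + #{null ≥ k_obs})/(1 + n) by default (the add-one correction keeps
p > 0; the raw fraction is available via `conservative=False`), and fold
enrichment is k_obs over the null mean. The universe defaults to the genes
that entered DE testing ("tested"; configurable to all genes): random gene
sets should be drawn from the space the analysis actually saw. Annotation
members outside the universe are dropped and logged. Because this null is
exactly hypergeometric, `hypergeom_enrichment` doubles as an independent
analytic check; the acceptance suite verifies agreement within Monte-Carlo
error at 10⁴ samples.

The packaged 12-gene core hypoxic signature (ADM … VEGFA) is checked
per-gene against the hypoxia contrast with the same FC > 2 / q < 0.05 rule;
absent genes report "missing" rather than failing.

## Response classification

For genes passing the hypoxia induction gate, r_c = log₂FC_c/log₂FC_hypoxia.
With τ_full = 0.7: class I if the best PHI reaches r ≥ τ; class II if the
PHI falls short but the PHD+FIH combo reaches τ; class III if neither does;
genes that would need the combo contrast when none was measured are
"unclassifiable" rather than guessed. Choices worth recording: multiple
PHIs are summarised by their maximum ratio (the inhibitors behave
similarly, so the most favourable one defines attainability); significantly
*down*-regulated genes are excluded from the induction taxonomy and reported
separately; and overshoot (r > 1, a treatment inducing harder than hypoxia)
counts as class-satisfying. τ = 0.7 encodes "induced to a level comparable
with hypoxia" as a reproducible rule — the underlying biology was never
assigned by formula, so τ is a tunable with a deliberate default, and the
classification is invariant to positive rescaling of all fold changes by
construction.

## Problem sizes and numerical conventions

Defaults throughout: 6000 genes × 12 samples for preset experiments, 10⁴
genes for null calibration, 1000 bootstrap resamples, 1000 permutation
samples (10⁴ where compared against the analytic tail), 25 k-means
restarts. These sizes give sub-percent Monte-Carlo error on every reported
fraction while keeping a full test run in seconds. Degenerate inputs have
explicit policies: constant genes floor the dispersion at 10⁻⁴, all-zero
genes have FPKM 0 and p = 1, constant profile rows z-score to zeros,
empty hypoxia sets are an error for mimicry, and p-values from the
conservative permutation test are bounded below by 1/(n+1).

## Known limitations

The DE stage's normal-reference Wald test is slightly conservative in bulk
at n = 2–3 under the max-type sharing (rejection ~0.045 at nominal 0.05)
and, like all moment methods, relies on many genes to pin the global
dispersion. The bootstrap support values are plain BP, which underestimate
support for deep nodes relative to multiscale methods. The classifier
thresholds a ratio of noisy estimates and so inherits DE noise near the
gate; it does not model measurement error in r. None of the stages handle
batch structure or outlier samples.
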
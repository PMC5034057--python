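# hifmimic

How well do small-molecule HIF hydroxylase inhibitors mimic the
transcriptional response to hypoxia?

Cells sense oxygen through the HIF prolyl hydroxylases (PHD1–3), which mark
the HIFα transcription factors for degradation, and the asparaginyl
hydroxylase FIH, which blocks HIFα's interaction with its co-activators.
Selective PHD inhibitors (PHIs such as IOX2, BIQ and BNS) stabilise HIFα but
leave FIH active; a broad-spectrum 2-oxoglutarate-oxygenase inhibitor (DMOG)
hits both. Comparing the transcriptome-wide response to these compounds
against true hypoxia tells you which hypoxia-inducible genes need PHD
inhibition alone, which need PHD *and* FIH inhibition, and which respond to
neither — a question that matters for PHI drugs in the clinic.

`hifmimic` is a tested, reusable implementation of that analysis for
multi-condition bulk RNA-seq contrast designs:

* **Differential expression** per condition-vs-normoxia contrast: a
  transparent negative-binomial Wald test (median-of-ratios size factors
  `s_j`, moment dispersion estimates `α̂ = max(α₀, (v − m)/m²)` with
  conservative sharing toward the trimmed global mean, delta-method variance
  of the log₂ ratio of group means, Benjamini–Hochberg FDR), calling genes
  at q < 0.05 and linear |FC| > 2.
* **Sample clustering**: Ward's linkage on Manhattan distances of
  log₂(FPKM+1) profiles, with per-node bootstrap probabilities (BP) from
  gene resampling.
* **Gene response clusters**: k-means (k = 4) on z-scored per-condition mean
  profiles of hypoxia-regulated genes, with Hungarian matching of centroids
  onto canonical response templates (down in hypoxia/DMOG; up everywhere; up
  but attenuated under PHIs; up only in hypoxia).
* **Set statistics**: mimicry fractions |hypoxia ∩ treatment| / |hypoxia|,
  Venn regions, an empirical permutation overlap-enrichment test against
  HIF-target gene sets (equal-size random sets drawn from the analysis
  universe; p = fraction of null overlaps ≥ observed, with an add-one
  correction), and the analytic hypergeometric tail with fold enrichment
  (k/n)/(K/N).
* **Response classification**: each hypoxia-induced gene (q < 0.05, FC > 2)
  is classed by its relative induction ratio r = log₂FC_treatment /
  log₂FC_hypoxia — class I (PHD inhibition suffices, r_PHI ≥ τ), class II
  (needs PHD+FIH inhibition, r_PHI < τ ≤ r_combo), class III (refractory),
  with τ = 0.7 by default.
* **Synthetic data**: a negative-binomial generator that emulates the study
  design (6 conditions × 2 replicates, latent 4-cluster response structure,
  HIF1α/HIF2α-like target sets), so every stage is testable without any
  downloads, against known ground truth.

## Worked example

```python
import hifmimic as hm
from hifmimic.diffexp import call_regulated
from hifmimic.setstats import mimicry_fraction
from hifmimic.simdata import mimicry_preset

counts, samples, truth = hm.simulate_experiment(mimicry_preset(seed=9))
de = hm.de_analysis(counts, samples)
regulated = {c: call_regulated(t, direction="both") for c, t in de.items()}
hyp = regulated["hypoxia"]
for cond in ("DMOG", "IOX2", "BIQ", "BNS"):
    print(cond, round(mimicry_fraction(hyp, regulated[cond]), 3))
```

prints

```
DMOG 0.448
IOX2 0.311
BIQ 0.344
BNS 0.29
```

i.e. from 748 genes called hypoxia-regulated, DMOG also regulates ~45% and
each selective PHI ~25–35% — the estimated fractions recover the preset's
construction (50% / 35% / 35% / 25%) up to sampling and calling error, and
in particular the ordering: the broad-spectrum inhibitor mimics hypoxia best.
The `examples/` directory has one short script per capability
(simulation, DE, clustering with bootstrap support, enrichment, response
classes, and the end-to-end pipeline with its reproducibility manifest).

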
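"""Simulate a multi-condition inhibitor-vs-hypoxia RNA-seq experiment.

Draws a small synthetic experiment (normoxia, hypoxia, DMOG and three
selective PHD inhibitors, 2 replicates each) with a latent 4-cluster gene
response structure, and shows the ground truth the generator records.
"""

import hifmimic as hm

config = hm.SimConfig(n_genes=1000, seed=1)
counts, samples, truth = hm.simulate_experiment(config)

print("count matrix:", counts.counts.shape[0], "genes x", counts.counts.shape[1], "samples")
print("conditions:", ", ".join(samples.conditions))
print("\nlatent cluster sizes (0 = unresponsive background):")
print(truth.genes["cluster"].value_counts().sort_index().to_string())
print("\ntrue log2 fold-change templates (cluster x condition):")
print(config.effect_templates.round(2).to_string())
print("\nFirst rows of the count matrix:")
print(counts.counts.head(3).to_string())
print(
    "\nEach count is a negative-binomial draw with mean mu * 2**effect and "
    "variance mu + 0.05*mu^2; the truth table above is what the DE and "
    "clustering stages are later scored against."
)
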
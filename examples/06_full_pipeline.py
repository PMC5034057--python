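"""Run the whole pipeline end-to-end from one config and write the report.

Simulation -> normalisation -> DE per contrast -> bootstrapped sample tree
-> k-means gene clusters -> mimicry -> enrichment -> response classes, all
reproducible from the single seed in the config.
"""

import tempfile
from pathlib import Path

import hifmimic as hm

config = hm.PipelineConfig(
    sim=hm.SimConfig(n_genes=2000, seed=4),
    n_boot=500,
    n_perm=1000,
    seed=4,
)
bundle = hm.run_pipeline(config)

print("mimicry fractions (fraction of hypoxia-regulated genes also regulated):")
print(bundle.mimicry.round(3).to_string())
print("\nresponse-class counts:")
print(bundle.classification.class_counts().to_string())
print("\ncluster-3 enrichment against the simulated HIF target lists:")
for enr in bundle.enrichments:
    if enr.cluster_name == "cluster3":
        print(f"  {enr.annotation_name}: overlap {enr.k_obs}/{enr.n_set}, "
              f"fold {enr.fold_enrichment:.2f}, empirical p {enr.p_value:.4f}")

with tempfile.TemporaryDirectory() as tmp:
    manifest = hm.write_report(bundle, Path(tmp) / "report")
    print(f"\nreport written: {len(manifest['files'])} files, "
          f"config hash {manifest['config_hash'][:12]}...")
print(
    "\nRe-running with the same config reproduces every artefact "
    "bit-identically; the manifest pins the config hash and per-file digests."
)
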
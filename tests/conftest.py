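import numpy as np
import pandas as pd
import pytest

import hifmimic as hm


@pytest.fixture(scope="session")
def default_experiment():
    """Default synthetic experiment at 3 replicates per condition."""
    cfg = hm.SimConfig(replicates_per_condition=3, seed=42)
    counts, samples, truth = hm.simulate_experiment(cfg)
    return cfg, counts, samples, truth


@pytest.fixture(scope="session")
def default_de(default_experiment):
    _, counts, samples, _ = default_experiment
    return hm.de_analysis(counts, samples)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_counts(values, genes=None, samples=None, lengths=None):
    """Small helper to build a CountMatrix from a plain list."""
    arr = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    lengths_s = (
        pd.Series(lengths, index=genes, dtype=float) if lengths is not None else None
    )
    return hm.CountMatrix(
        pd.DataFrame(arr, index=genes, columns=samples), gene_lengths=lengths_s
    )
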
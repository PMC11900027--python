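import numpy as np
import pandas as pd
import pytest

import beetox


@pytest.fixture(scope="session")
def small_dataset():
    """A scaled-down (400-gene) synthetic study used across test modules."""
    cfg = beetox.SynthConfig.scaled_down(seed=11)
    counts, meta, truth = beetox.generate_counts(cfg)
    return cfg, counts, meta, truth


@pytest.fixture(scope="session")
def small_de_tables(small_dataset):
    _, counts, meta, _ = small_dataset
    return beetox.de_pipeline(counts, meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_de_table(log2fc, significant, gene_prefix="g"):
    """Construct a minimal DE table with the engine's stable columns."""
    n = len(log2fc)
    ids = [f"{gene_prefix}{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "gene_id": ids,
            "base_mean": np.full(n, 100.0),
            "log2fc": np.asarray(log2fc, dtype=float),
            "se": np.full(n, 0.1),
            "wald_z": np.asarray(log2fc, dtype=float) / 0.1,
            "pvalue": np.where(significant, 1e-6, 0.5),
            "fdr": np.where(significant, 1e-5, 0.7),
            "significant": np.asarray(significant, dtype=bool),
        }
    ).set_index("gene_id", drop=False)
    df.index.name = None
    return df
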
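import numpy as np
import pandas as pd
import pytest

from lithopredict import simcohort


@pytest.fixture(scope="session")
def small_cohort():
    """300-gene, 10 vs 10 subject, 3-batch study with planted markers."""
    cfg = simcohort.two_group_config(seed=11, n_per_group=10, n_genes=300)
    counts, metadata, annotation = simcohort.generate_cohort(cfg)
    return cfg, counts, metadata, annotation


@pytest.fixture(scope="session")
def tiny_triple():
    """Hand-sized 5-gene x 4-sample triple for I/O contracts."""
    rng = np.random.default_rng(0)
    genes = [f"G{i}" for i in range(5)]
    samples = ["s1", "s2", "s3", "s4"]
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(5, 4)), index=pd.Index(genes, name="gene_id"),
        columns=samples,
    )
    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "subject_id": ["p1", "p1", "p2", "p3"],
            "batch": ["b1", "b1", "b1", "b2"],
            "cohort": ["c1"] * 4,
            "diagnosis": ["BD", "BD", "BD", "CTRL"],
            "response": ["LR", "LR", "NR", "NA"],
            "replicate_index": [0, 1, 0, 0],
        }
    )
    annotation = pd.DataFrame(
        {
            "gene_id": genes,
            "symbol": [f"SYM{g}" for g in genes],
            "is_immunoglobulin": [False, True, False, False, True],
            "is_planted_marker": [False] * 5,
            "true_log2fc": [0.0] * 5,
        }
    )
    return counts, metadata, annotation
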
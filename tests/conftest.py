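import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import chillseq as cs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One desk-scale simulated experiment (default config, seed 0)."""
    cfg = cs.SimConfig(seed=0)
    ann = cs.generate_annotation(cfg)
    cm, truth = cs.generate_counts(ann, cfg)
    return cfg, ann, cm, truth


@pytest.fixture()
def tiny_annotation():
    """Hand-built annotation: one 10-kb chromosome, 4 genes."""
    genes = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4"],
            "chrom": ["chr1"] * 4,
            "start": [100, 2000, 4900, 7000],
            "end": [600, 3000, 5200, 9000],
            "strand": ["+", "-", "+", "-"],
        }
    )
    return cs.GeneAnnotation(genes=genes, chrom_lengths={"chr1": 10_000})


@pytest.fixture()
def small_counts():
    """6-sample, 5-gene count matrix with a 3v3 genotype design."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.integers(10, 200, size=(5, 6)),
        index=pd.Index([f"g{i}" for i in range(1, 6)], name="gene_id"),
        columns=[f"A_leaf_{i}" for i in (1, 2, 3)] + [f"B_leaf_{i}" for i in (1, 2, 3)],
    )
    design = pd.DataFrame(
        {
            "sample": counts.columns,
            "genotype": ["A"] * 3 + ["B"] * 3,
            "tissue": ["leaf"] * 6,
            "replicate": [1, 2, 3, 1, 2, 3],
        }
    )
    return cs.CountMatrix(counts=counts, design=design)
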
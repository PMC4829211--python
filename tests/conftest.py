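import numpy as np
import pandas as pd
import pytest

from agingtx.genome_io import CountMatrix, GeneModel, SampleDesign
from agingtx.synthetic_data import SimulationConfig, simulate_annotation


@pytest.fixture
def tiny_genes() -> list[GeneModel]:
    """Three genes on one chromosome, mixed strands."""
    return [
        GeneModel("g1", "chrI", 10_000, 12_000, "+"),
        GeneModel("g2", "chrI", 20_000, 22_000, "-"),
        GeneModel("g3", "chrI", 40_000, 42_000, "+"),
    ]


@pytest.fixture
def small_annotation():
    cfg = SimulationConfig(n_genes=200, n_chroms=2, seed=0)
    genes, sizes = simulate_annotation(cfg)
    return cfg, genes, sizes


@pytest.fixture
def toy_counts():
    """3 genes x 6 samples (two conditions x one stage x 3 replicates)."""
    counts = pd.DataFrame(
        {
            "t1": [10, 30, 60],
            "t2": [12, 28, 55],
            "t3": [9, 33, 61],
            "c1": [20, 30, 50],
            "c2": [22, 29, 48],
            "c3": [19, 31, 52],
        },
        index=["gA", "gB", "gC"],
    )
    design = pd.DataFrame(
        {
            "condition": ["treated"] * 3 + ["control"] * 3,
            "stage_or_timepoint": ["L1"] * 6,
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=pd.Index(["t1", "t2", "t3", "c1", "c2", "c3"],
                       name="sample_id"),
    )
    return CountMatrix(counts), SampleDesign(design)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
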
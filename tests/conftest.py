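import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import aneuexpr as ax

settings.register_profile(
    "repro", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_experiment():
    """Default three-line experiment at reduced size, fixed seed."""
    cfg = ax.SimConfig(seed=42, genes_per_chrom=60)
    genes, counts, samples, truth = ax.simulate_experiment(cfg)
    expr = ax.compute_fpkm(counts, genes)
    return {
        "config": cfg,
        "genes": genes,
        "counts": counts,
        "samples": samples,
        "truth": truth,
        "expr": expr,
    }


@pytest.fixture()
def tiny_genes():
    """Hand-built annotation: two chromosomes, four genes."""
    return pd.DataFrame(
        {
            "chromosome": ["A01", "A01", "A02", "C01"],
            "start": [1, 5001, 1, 1],
            "end": [2000, 8000, 1500, 900],
            "exonic_length": [1000, 2000, 1200, 600],
            "subgenome": ["A", "A", "A", "C"],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )


@pytest.fixture()
def tiny_samples():
    return pd.DataFrame(
        {
            "sample_id": ["t_1", "t_2", "t_3", "r_1", "r_2", "r_3"],
            "group": ["test"] * 3 + ["ref"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        }
    )


def make_expr(values: dict, index) -> pd.DataFrame:
    return pd.DataFrame(values, index=index, dtype=float)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
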
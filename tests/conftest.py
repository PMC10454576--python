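import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

DATA = Path(__file__).parent / "data"


@pytest.fixture
def sti_fixture() -> pd.DataFrame:
    """Fixed 6-genotype x 4-trait salt-tolerance-index matrix."""
    return pd.read_csv(DATA / "sti_6x4.csv", index_col="genotype")


@pytest.fixture
def tiny_trait_table() -> pd.DataFrame:
    """Two genotypes x two traits, control + salt, 2 replicates."""
    rows = []
    values = {
        ("GA", "DW_shoot", "control"): 1.0, ("GA", "DW_shoot", "salt"): 0.8,
        ("GA", "Na_leaf", "control"): 5.0, ("GA", "Na_leaf", "salt"): 9.0,
        ("GB", "DW_shoot", "control"): 1.2, ("GB", "DW_shoot", "salt"): 0.6,
        ("GB", "Na_leaf", "control"): 5.5, ("GB", "Na_leaf", "salt"): 13.0,
    }
    for (g, t, c), v in values.items():
        for rep in (1, 2):
            rows.append({"genotype": g, "trait": t, "condition": c,
                         "timepoint": "24h", "replicate": rep, "value": v})
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_de_table() -> pd.DataFrame:
    return pd.DataFrame({
        "contrast": ["c1", "c1", "c1", "c2"],
        "gene": ["g1", "g2", "g3", "g1"],
        "log2fc": [2.0, -0.5, 1.0, -3.0],
        "fdr": [0.001, 0.9, 0.05, 0.2],
    })


def random_de_rows(rng: np.random.Generator, spec, n_genes: int) -> pd.DataFrame:
    """A random combined DE table covering all contrasts of ``spec``."""
    genes = [f"g{i:04d}" for i in range(n_genes)]
    rows = []
    for t in spec.timepoints:
        for contrast in (spec.tolerant_vs_baseline(t),
                         spec.sensitive_vs_baseline(t),
                         spec.sensitive_vs_tolerant(t)):
            for g in genes:
                rows.append({"contrast": contrast, "gene": g,
                             "log2fc": float(rng.normal(0, 1.5)),
                             "fdr": float(rng.uniform(0, 0.2))})
    return pd.DataFrame(rows)
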
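import numpy as np
import pandas as pd
import pytest

import cellprior as cp


@pytest.fixture(scope="session")
def small_panel() -> cp.ReferencePanel:
    cfg = cp.SimConfig(seed=7, n_blocks=4, snps_per_block=25, n_ref=120)
    return cp.simulate_panel(cfg)


@pytest.fixture(scope="session")
def toy_sumstats() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(1, 6)],
            "CHR": ["1", "1", "6", "2", "2"],
            "BP": [100, 200, 30_000_000, 400, 500],
            "A1": ["A", "C", "G", "A", "C"],
            "A2": ["G", "T", "A", "G", "T"],
            "Z": [1.0, -2.0, 0.5, 3.0, 0.25],
            "N": [1000] * 5,
        }
    )


@pytest.fixture(scope="session")
def planted_expression():
    """Counts where a known gene set is expressed only in one type."""
    rng = np.random.default_rng(11)
    n_genes, n_types, cpt = 30, 3, 15
    types = np.array([f"t{i}" for i in range(n_types)], dtype=object)
    labels = np.repeat(types, cpt)
    counts = rng.poisson(3.0, size=(n_genes, n_types * cpt))
    marker_set = np.arange(5)  # genes 0-4 markers for t0, silent elsewhere
    counts[np.ix_(marker_set, np.flatnonzero(labels != "t0"))] = 0
    counts[np.ix_(marker_set, np.flatnonzero(labels == "t0"))] += 20
    x = cp.ExpressionMatrix(
        counts=counts,
        gene_ids=np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        cell_ids=np.array([f"c{i}" for i in range(n_types * cpt)], dtype=object),
        cell_type=labels,
    )
    return x, marker_set
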
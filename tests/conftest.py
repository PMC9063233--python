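import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sctrait as st

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def gwas_sim():
    """A small simulated genome with 4 gene sets and no enrichment."""
    cfg = st.GwasSimConfig(seed=11, n_chromosomes=2, markers_per_chromosome=150)
    return st.generate_gwas(cfg, n_sets=4, genes_per_set=5)


@pytest.fixture(scope="session")
def sc_sim():
    """A small simulated count matrix with one cycling cluster."""
    cfg = st.ScSimConfig(
        seed=5, n_genes=300, n_cells_per_group=80,
        cluster_labels=["monocytes", "CD4_T"],
        cycling_fraction_per_cluster={"monocytes": 0.3},
    )
    cycle_panels, module_panels = st.default_panels(cfg.n_genes)
    return st.generate_sc(cfg, cycle_panels, module_panels)


@pytest.fixture(scope="session")
def sc_norm(sc_sim):
    return st.normalize(sc_sim.adata)


@pytest.fixture()
def toy_annotation():
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC"],
            "chrom": ["1", "1", "2"],
            "start": [100_000, 5_000, 40_000],
            "end": [105_000, 9_000, 60_000],
            "strand": ["+", "-", "+"],
        }
    )
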
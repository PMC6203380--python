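import numpy as np
import pandas as pd
import pytest

from crosstum import SimConfig, gen_expression_panel, compute_direction_matrix


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        seed=11,
        n_lines=300,
        n_genes=120,
        planted_set_size=15,
        n_tissue_pairs=3,
        n_tumor=15,
        n_normal=15,
        ppi_edges=300,
        n_patients=80,
        signature_size=20,
    )


@pytest.fixture(scope="session")
def planted_genes(small_cfg):
    return [f"HS{i:04d}" for i in range(1, small_cfg.planted_set_size + 1)]


@pytest.fixture(scope="session")
def small_panel(small_cfg, planted_genes):
    return gen_expression_panel(small_cfg, planted_genes=planted_genes)


@pytest.fixture(scope="session")
def small_dm(small_panel):
    return compute_direction_matrix(small_panel, alpha=0.01)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
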
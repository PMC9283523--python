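import numpy as np
import pytest

from nkqtl import simdata as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """245-sample cohort with LD, one shared and one NK-specific cis effect."""
    cfg = sd.SimConfig(
        n_samples=245,
        n_variants=400,
        n_genes=10,
        cell_types=("NK", "CD4"),
        ld_rho=0.5,
        seed=11,
    )
    gm = sd.simulate_genotypes(cfg)
    truth = sd.TruthTable(
        cis_effects=[
            sd.CisEffect("GENE0001", "var000006", 0.8, cell_types=("NK",)),
            sd.CisEffect("GENE0002", "var000210", 0.8),
        ]
    )
    tables = sd.simulate_multicell_expression(gm, cfg, truth)
    return cfg, gm, truth, tables
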
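import numpy as np
import pandas as pd
import pytest

from twinbiome.config import SimConfig
from twinbiome.genotypes import infer_phenotypes, resolve_abo
from twinbiome.simulate import simulate_cohort
from twinbiome.taxa import rarefy


@pytest.fixture(scope="session")
def small_sim():
    """A small noise-free-phenotyping cohort reused across tests."""
    cfg = SimConfig(n_mz_pairs=40, n_dz_pairs=40, n_unrelated=30,
                    n_otus=60, n_background_snps=80, mean_depth=3000,
                    typing_error_rate=0.0, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    """Cohort table with inferred phenotypes attached."""
    return infer_phenotypes(small_sim.cohort, small_sim.genotypes)


@pytest.fixture(scope="session")
def small_phenotypes(small_cohort):
    return resolve_abo(small_cohort), small_cohort["secretor"]


@pytest.fixture(scope="session")
def small_rarefied(small_sim):
    return rarefy(small_sim.otu_table, depth=1500, seed=1)


@pytest.fixture(scope="session")
def toy_tree():
    """A 4-leaf tree with hand-set branch lengths used by diversity
    oracles."""
    import io

    from skbio import TreeNode

    return TreeNode.read(io.StringIO(
        "((A:1.0,B:2.0):0.5,(C:1.5,D:0.5):1.0):0.0;"))
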
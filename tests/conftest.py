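import numpy as np
import pandas as pd
import pytest

import stabgwas as sg


@pytest.fixture
def toy_phenotypes() -> pd.DataFrame:
    """Balanced 2 genotypes x 2 environments x 2 replicates, one trait."""
    rows = []
    vals = {("g1", "e1"): (2.0, 4.0), ("g1", "e2"): (5.0, 7.0),
            ("g2", "e1"): (1.0, 3.0), ("g2", "e2"): (2.0, 4.0)}
    for (gt, env), (v1, v2) in vals.items():
        rows.append((gt, env, 1, "GY", v1))
        rows.append((gt, env, 2, "GY", v2))
    return pd.DataFrame(rows, columns=["genotype", "environment", "replicate",
                                       "trait", "value"])


def make_gemeans(matrix, r=2, trait="GY") -> sg.GEMeans:
    m = np.asarray(matrix, dtype=float)
    return sg.GEMeans(
        values=pd.DataFrame(m, index=[f"g{i+1}" for i in range(m.shape[0])],
                            columns=[f"e{j+1}" for j in range(m.shape[1])]),
        r=r, trait=trait)


@pytest.fixture
def small_panel() -> sg.GenotypeMatrix:
    cfg = sg.SimConfig(n_genotypes=60, group_split=(40, 20), n_markers=200,
                       n_chromosomes=4, seed=123, qtls=[])
    return sg.simulate_genotypes(cfg)


@pytest.fixture
def sim_with_qtls():
    """200-genotype panel + one-trait MET with a dual-effect QTL at marker 55."""
    qtls = [sg.Qtl(55, "GY", beta_main=0.25, beta_sensitivity=0.3)]
    cfg = sg.SimConfig(n_genotypes=200, group_split=(134, 66), n_markers=300,
                       n_chromosomes=3, seed=321, fst_like_divergence=0.1, qtls=qtls,
                       traits=[sg.TraitSpec("GY", 1.8, 0.05, 0.3, 0.05, 0.2, var_s=0.03)])
    g = sg.simulate_genotypes(cfg)
    phen, truth = sg.simulate_phenotypes(g, cfg)
    return cfg, g, phen, truth
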
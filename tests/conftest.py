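import numpy as np
import pandas as pd
import pytest

import mwgwas as mw


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim():
    """Small synthetic scenario shared across tests: tensor + covariates +
    genotypes + gene intervals tied to tensor gene ids."""
    cfg = mw.small_config(seed=7)
    tensor, truth, covariates = mw.simulate_tensor(cfg)
    genotypes, snp_map, gene_intervals = mw.simulate_genotypes(cfg)
    link_rng = np.random.default_rng(cfg.seed)
    gene_intervals = gene_intervals.assign(
        gene_id=link_rng.choice(tensor.gene_ids, size=len(gene_intervals), replace=False)
    )
    return {
        "config": cfg,
        "tensor": tensor,
        "truth": truth,
        "covariates": covariates,
        "genotypes": genotypes,
        "snp_map": snp_map,
        "gene_intervals": gene_intervals,
    }


def make_rank1(shape, lam, seed=0, tissue_sign=1.0):
    """Exact rank-1 tensor with unit-norm factors and single-signed tissue."""
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(shape[0])
    g /= np.linalg.norm(g)
    i = rng.standard_normal(shape[1])
    i /= np.linalg.norm(i)
    t = np.abs(rng.standard_normal(shape[2])) * tissue_sign
    t /= np.linalg.norm(t)
    return lam * np.einsum("g,i,k->gik", g, i, t), (g, i, t)


@pytest.fixture
def toy_events():
    """Ten hand-written feeding events; four violate exactly one rule each."""
    rows = [
        # animal, pen, day, duration_s, amount_kg  (comment: status)
        ("a1", "p1", 1, 120.0, 0.5),    # ok (rate 0.25)
        ("a1", "p1", 1, 300.0, 1.0),    # ok (rate 0.2)
        ("a2", "p1", 1, 3600.0, 1.0),   # duration at upper bound -> removed
        ("a2", "p1", 2, 0.9, 0.021),    # duration below min (rate 1.4 legal)
        ("a3", "p1", 2, 600.0, 0.5),    # ok (rate 0.05)
        ("a3", "p1", 2, 600.0, 3.5),    # amount above max
        ("a4", "p2", 1, 60.0, 2.5),     # rate 2.5 -> removed
        ("a4", "p2", 1, 900.0, 2.0),    # ok (rate 0.133)
        ("a5", "p2", 2, 1800.0, 1.5),   # ok
        ("a5", "p2", 2, 45.0, 1.4),     # rate 1.867 -> ok (strictly below 2)
    ]
    return pd.DataFrame(rows, columns=["animal_id", "pen_id", "day", "duration_s", "amount_kg"])
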
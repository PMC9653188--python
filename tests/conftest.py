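import numpy as np
import pandas as pd
import pytest

import corepanel as cp


@pytest.fixture(scope="session")
def small_population():
    """A 200-accession barley-like population with two traits and ground truth."""
    cfg = cp.barley_like(n_accessions=200, seed=42)
    gm, truth = cp.simulate_population(cfg)
    pheno = cp.simulate_phenotypes(truth, gm, cfg)
    return cfg, gm, truth, pheno


@pytest.fixture(scope="session")
def dense_catalog():
    """A 5,000-candidate marker catalog on the barley-like genome."""
    cfg = cp.barley_like(seed=5)
    catalog = cp.simulate_markers(cfg, n_markers=5000)
    sizes = pd.DataFrame({"chrom": cfg.chrom_names, "size_mb": cfg.chrom_sizes_mb})
    return catalog, sizes


def trait_vector(gm, pheno, trait):
    """Trait values aligned to the genotype-matrix accession order."""
    sub = pheno[pheno["trait"] == trait].set_index("accession_id")
    return sub.loc[gm.accession_meta["accession_id"]]["value"].to_numpy()


@pytest.fixture(scope="session")
def plain_trait_population():
    """Structure-free population with traits at h2 = 0, 0.5, 1 (no group shifts)."""
    traits = tuple(
        cp.TraitSpec(f"h{int(h2 * 100):03d}", n_qtl=100, h2=h2,
                     station_effect_sd=0.0, year_effect_sd=0.0)
        for h2 in (0.0, 0.5, 1.0)
    )
    cfg = cp.barley_like(
        n_accessions=600, n_stations=1, group_scale_sd=0.0, missing_rate=0.0,
        seed=7, traits=traits,
    )
    gm, truth = cp.simulate_population(cfg)
    pheno = cp.simulate_phenotypes(truth, gm, cfg)
    return cfg, gm, truth, pheno


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
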
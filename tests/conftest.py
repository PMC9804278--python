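import numpy as np
import pandas as pd
import pytest

from conunit.genotypes import GenotypeMatrix, SampleMetadata


def build_gm(genotypes, site_ids, locus_ids=None, pos=None, mean_depth=None):
    """Construct a GenotypeMatrix from a plain genotype array and per-
    individual site labels."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_snp = g.shape
    locus_ids = locus_ids or [f"loc{j}" for j in range(n_snp)]
    snp_meta = pd.DataFrame(
        dict(
            snp_id=[f"snp{j}" for j in range(n_snp)],
            locus_id=locus_ids,
            pos=pos if pos is not None else np.arange(1, n_snp + 1),
            ref="A",
            alt="T",
            mean_depth=mean_depth if mean_depth is not None else np.full(n_snp, np.nan),
        )
    )
    ind_meta = pd.DataFrame(
        dict(ind_id=[f"i{k}" for k in range(n_ind)], site_id=list(site_ids))
    )
    sites = {s: SampleMetadata(site_id=s) for s in dict.fromkeys(site_ids)}
    return GenotypeMatrix(g, snp_meta, ind_meta, sites)


@pytest.fixture
def make_gm():
    return build_gm


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured simulated data set shared across tests."""
    from conunit.synth import SimConfig, simulate_genotypes

    cfg = SimConfig(seed=7, n_sites=10, n_ind_per_site=10, n_neutral=400,
                    n_adaptive=10, missing_rate=0.05,
                    landscape_extent=6000, cell_size=60)
    gm, truth = simulate_genotypes(cfg)
    return cfg, gm, truth
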
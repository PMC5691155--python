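import numpy as np
import pytest

import pathpgs as pg


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with strong signals, shared by read-only tests."""
    cfg = pg.SimulationConfig(
        n_individuals=3000,
        n_snps_autosomal=120,
        n_snps_x=20,
        n_loci=5,
        h2_autosomal=0.5,
        h2_x=0.1,
        seed=11,
    )
    panel = pg.simulate_panel(cfg)
    pheno, truth = pg.simulate_traits(panel, cfg)
    return cfg, panel, pheno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def toy_panel(dosages, chrom="1", positions=None, sex=None):
    """Build a small GenotypePanel from an explicit dosage matrix."""
    import pandas as pd

    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    positions = positions if positions is not None else (np.arange(m) + 1) * 1000
    p = dosages.mean(axis=0) / 2
    meta = pd.DataFrame(
        {
            "snp": [f"s{j + 1}" for j in range(m)],
            "chr": chrom if isinstance(chrom, list) else [chrom] * m,
            "pos": positions,
            "a1": "A",
            "a2": "G",
            "maf": np.minimum(p, 1 - p),
        }
    )
    sex = np.ones(n, dtype=int) if sex is None else sex
    return pg.GenotypePanel(dosages=dosages, snp_meta=meta, sex=sex)
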
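"""Shared study definition for the numbered analysis scripts.

One deterministic synthetic cohort is used throughout: a male cohort of
6,000 with a liability-threshold baldness-like trait (prevalence 0.59,
heritability 0.82 autosomal + 0.12 X-linked across 12 loci) and two
secondary traits: "lifespan" receives opposite-signed genetic input from two
pathway groups (the cancellation design) and "height" a diffuse input from
one six-locus pathway.
"""

from pathlib import Path

import pathpgs as pg

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

SEED = 20_170_214
N = 6_000
# strong enough that single loci within the groups reach the regional
# pleiotropy thresholds, yet exactly cancelling in the overall score
EFFECT = 10.0 / (N**0.5)

PATHWAYS = (
    pg.PathwaySpec("wnt_like", (1, 2, 3), {"lifespan": -EFFECT}),
    pg.PathwaySpec("apoptosis_like", (4, 5, 6), {"lifespan": +EFFECT}),
    pg.PathwaySpec("diffuse_growth", (7, 8, 9, 10, 11, 12), {"height": 4.0 / (N**0.5)}),
)

CONFIG = pg.SimulationConfig(
    n_individuals=N,
    n_snps_autosomal=240,
    n_snps_x=20,
    n_loci=13,  # 12 autosomal + 1 X-linked (the AR-like locus)
    h2_autosomal=0.82,
    h2_x=0.12,
    prevalence=0.59,
    pathways=PATHWAYS,
    seed=SEED,
)

PATHWAY_MAP = {pw.name: pw.loci for pw in PATHWAYS}
COVARIATES = ["age", "pc1", "pc2", "pc3"]


def build_cohort():
    panel = pg.simulate_panel(CONFIG)
    pheno, truth = pg.simulate_traits(panel, CONFIG)
    return panel, pheno, truth


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
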
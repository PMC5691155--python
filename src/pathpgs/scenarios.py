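"""Ready-made study scenarios on the synthetic cohort.

These functions wire the generator to the downstream machinery for the
recurring designs: the pathway-cancellation and diffuse-pathway genetic
correlation scenarios, heritability parameter recovery, null calibration of
the genomic-control factor and of the score-trait scan, and the worked
examples built from the packaged locus/pathway tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import tables
from .assoc import inflation_lambda, run_screen
from .config import PathwaySpec, SimulationConfig
from .heritability import build_grm, fit_aireml, score_variance_explained
from .loci import Locus, replicate_filter
from .panel import GenotypePanel
from .scores import (
    PolygenicScoreSet,
    aggregate_scores,
    associate_score_with_trait,
    compute_locus_scores,
    reestimate_joint_betas,
)
from .simulate import simulate_panel, simulate_traits


# ------------------------------------------------------------------ fixtures

def fixture_locus_objects() -> list[Locus]:
    """Locus objects rebuilt from the packaged 71-locus table, with
    placeholder distinct-SNP ids sized by the table's distinct counts."""
    rows = tables.load_locus_table()
    loci = []
    for _, r in rows.iterrows():
        snps = [f"L{r['locus']}_snp{j + 1}" for j in range(int(r["n_distinct_snps"]))]
        loci.append(
            Locus(
                id=int(r["locus"]), chrom=str(r["chr"]), start=int(r["start"]),
                end=int(r["end"]), member_snps=snps, distinct_snps=snps,
                novel=r["replicated"] == "N",
            )
        )
    return loci


def fixture_score_set(seed: int = 0, n_individuals: int = 50) -> PolygenicScoreSet:
    """A score set over the packaged 71 loci (107 distinct SNPs) on a small
    random panel, aggregated with the study's explicit pathway merges."""
    rng = np.random.default_rng(seed)
    loci = fixture_locus_objects()
    snp_ids = [s for l in loci for s in l.distinct_snps]
    m = len(snp_ids)
    dosages = rng.binomial(2, 0.3, size=(n_individuals, m)).astype(float)
    # one synthetic chromosome axis so positions stay strictly increasing
    meta = pd.DataFrame(
        {
            "snp": snp_ids,
            "chr": "1",
            "pos": np.arange(1, m + 1) * 1_000_000,
            "a1": "A", "a2": "G",
            "maf": 0.3,
        }
    )
    panel = GenotypePanel(dosages=dosages, snp_meta=meta, sex=np.ones(n_individuals, int))
    weights = pd.Series(rng.normal(0, 0.1, size=m), index=snp_ids)
    score_set = compute_locus_scores(panel, weights, loci)
    return aggregate_scores(
        score_set,
        tables.pathway_loci_mapping(),
        merge_rule="explicit",
        explicit_merges=tables.EXPLICIT_PATHWAY_MERGES,
    )


def replication_fixture_tables(
    n_discovery: int = 12_192, n_replicated: int = 11_624, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discovery and replication summary tables sized to the study's printed
    counts: every discovery SNP genome-wide significant, of which
    ``n_replicated`` replicate at p < 0.05 with concordant direction."""
    rng = np.random.default_rng(seed)
    snps = [f"rs{i}" for i in range(n_discovery)]
    disc = pd.DataFrame(
        {
            "SNP": snps, "CHR": "1", "BP": np.arange(1, n_discovery + 1),
            "A1": "A", "A2": "G",
            "BETA": rng.choice([-0.1, 0.1], size=n_discovery),
            "SE": 0.01, "P": 1e-9, "N": 43_590,
        }
    )
    rep = disc.copy()
    rep["N"] = 31_112
    rep_p = np.concatenate(
        [
            rng.uniform(1e-6, 0.05, size=n_replicated),
            rng.uniform(0.05, 1.0, size=n_discovery - n_replicated),
        ]
    )
    rep["P"] = rep_p
    return disc, rep


def replication_rate_percent() -> float:
    disc, rep = replication_fixture_tables()
    _, fraction, _ = replicate_filter(disc, rep, p_rep=0.05)
    return round(100.0 * fraction, 1)


# ------------------------------------------------------- pathway scenarios

def _pipeline_scores(panel, pheno, truth, pathway_map):
    """Joint-weight locus scores from the ground-truth distinct SNPs."""
    cov = pheno[["age", "pc1", "pc2"]]
    distinct = [s for v in truth.locus_causal.values() for s in v]
    weights = reestimate_joint_betas(panel, pheno["mpb"].to_numpy(), cov, distinct)
    loci = [
        Locus(id=k, chrom="1", start=1, end=2, member_snps=v, distinct_snps=v)
        for k, v in truth.locus_causal.items()
    ]
    ss = compute_locus_scores(panel, weights, loci)
    return aggregate_scores(ss, pathway_map), cov


def cancellation_replicate(
    seed: int, n: int = 2000, effect: float | None = None
) -> dict[str, float]:
    """Two six-locus pathway groups with opposite-signed slopes of equal
    magnitude on a secondary trait. Returns the z-scores of the overall and
    the two pathway polygenic scores against that trait."""
    effect = 6.0 / np.sqrt(n) if effect is None else effect
    pws = (
        PathwaySpec("pathway_up", (1, 2, 3), {"secondary": +effect}),
        PathwaySpec("pathway_down", (4, 5, 6), {"secondary": -effect}),
    )
    cfg = SimulationConfig(
        n_individuals=n, n_snps_autosomal=120, n_snps_x=0, n_loci=12,
        h2_autosomal=0.5, h2_x=0.0, pathways=pws, seed=seed,
    )
    panel = simulate_panel(cfg)
    pheno, truth = simulate_traits(panel, cfg)
    ss, cov = _pipeline_scores(
        panel, pheno, truth, {"pathway_up": (1, 2, 3), "pathway_down": (4, 5, 6)}
    )
    out = {}
    for name, vec in (
        ("overall", ss.overall),
        ("pathway_up", ss.pathway_scores["pathway_up"]),
        ("pathway_down", ss.pathway_scores["pathway_down"]),
    ):
        out[name] = associate_score_with_trait(
            vec, pheno["secondary"], "quantitative", cov, score_name=name
        ).z
    return out


def diffuse_pathway_replicate(
    seed: int, n: int = 2000, k: int = 16, effect: float | None = None
) -> dict:
    """A pathway-wide effect spread evenly over k loci, each too weak to be
    significant on its own. Returns the pathway z and every locus z."""
    effect = 5.0 / np.sqrt(n) if effect is None else effect
    pw_loci = tuple(range(1, k + 1))
    pws = (PathwaySpec("diffuse", pw_loci, {"secondary": effect}),)
    cfg = SimulationConfig(
        n_individuals=n, n_snps_autosomal=10 * (k + 4), n_snps_x=0, n_loci=k + 4,
        h2_autosomal=0.5, h2_x=0.0, pathways=pws, seed=seed,
    )
    panel = simulate_panel(cfg)
    pheno, truth = simulate_traits(panel, cfg)
    ss, cov = _pipeline_scores(panel, pheno, truth, {"diffuse": pw_loci})
    z_path = associate_score_with_trait(
        ss.pathway_scores["diffuse"], pheno["secondary"], "quantitative", cov
    ).z
    z_loci = [
        associate_score_with_trait(
            ss.locus_scores[f"locus{l}"], pheno["secondary"], "quantitative", cov
        ).z
        for l in pw_loci
    ]
    return {"pathway_z": z_path, "locus_z": z_loci}


# ------------------------------------------------------ parameter recovery

def h2_recovery_single(seed: int, n: int = 2000, m: int = 1000, h2: float = 0.5) -> dict:
    """Fully polygenic quantitative trait (all m SNPs causal); single-GRM
    REML fit. Returns the estimate, its SE and the 2-SE coverage indicator."""
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(
        n_individuals=n, n_snps_autosomal=m, n_snps_x=0, n_loci=2,
        h2_x=0.0, ld_decay=0.0, ld_block_size=m, seed=seed,
    )
    panel = simulate_panel(cfg)
    W = panel.dosages
    W = (W - W.mean(0)) / W.std(0)
    g = W @ rng.standard_normal(m)
    g *= np.sqrt(h2) / g.std()
    y = g + rng.standard_normal(n) * np.sqrt(1 - h2)
    vc = fit_aireml(y, None, [build_grm(panel)])
    est, se = float(vc.h2_observed[0]), float(vc.h2_observed_se[0])
    return {"estimate": est, "se": se, "covered": abs(est - h2) < 2 * se, "truth": h2}


def h2_recovery_two_component(
    seed: int, n: int = 2000, h2_autosomal: float = 0.6, h2_x: float = 0.2
) -> dict:
    """Two-GRM (autosomal + X) REML recovery on the liability scale."""
    cfg = SimulationConfig(
        n_individuals=n, n_snps_autosomal=500, n_snps_x=100, n_loci=8,
        h2_autosomal=h2_autosomal, h2_x=h2_x, seed=seed,
    )
    panel = simulate_panel(cfg)
    pheno, _ = simulate_traits(panel, cfg)
    meta = panel.snp_meta
    grm_a = build_grm(panel, meta.loc[meta["chr"] != "X", "snp"])
    grm_x = build_grm(panel, meta.loc[meta["chr"] == "X", "snp"])
    vc = fit_aireml(pheno["liability"].to_numpy(), None, [grm_a, grm_x], names=["autosomal", "x"])
    cov_a = abs(vc.h2_observed[0] - h2_autosomal) < 2 * vc.h2_observed_se[0]
    cov_x = abs(vc.h2_observed[1] - h2_x) < 2 * vc.h2_observed_se[1]
    return {
        "autosomal": float(vc.h2_observed[0]), "x": float(vc.h2_observed[1]),
        "se_autosomal": float(vc.h2_observed_se[0]), "se_x": float(vc.h2_observed_se[1]),
        "covered": bool(cov_a and cov_x),
    }


def score_variance_recovery(seed: int, n: int = 1000, m: int = 300, h2: float = 0.5) -> dict:
    """Score built from half the causal variance: the REML fixed-effect
    decrease should recover about half the genetic fraction."""
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(
        n_individuals=n, n_snps_autosomal=m, n_snps_x=0, n_loci=2,
        h2_x=0.0, ld_decay=0.0, ld_block_size=m, seed=seed,
    )
    panel = simulate_panel(cfg)
    W = panel.dosages
    W = (W - W.mean(0)) / W.std(0)
    beta = rng.standard_normal(m)
    g = W @ beta
    g *= np.sqrt(h2) / g.std()
    y = g + rng.standard_normal(n) * np.sqrt(1 - h2)
    half = W[:, : m // 2] @ beta[: m // 2]  # half the causal variance
    out = score_variance_explained(y, None, [build_grm(panel)], half)
    base = out["without_score"]
    return {
        "decrease": out["observed"],
        "target": h2 / 2,
        "baseline": base.total_h2_observed,
        "se": float(base.h2_observed_se[0]),
    }


# ------------------------------------------------------------- calibration

def null_gwas_lambda(seed: int, n: int = 1000, m: int = 60_000) -> float:
    """Genomic-control lambda of a linear screen on a permuted (null) binary
    phenotype over m independent SNPs."""
    cfg = SimulationConfig(
        n_individuals=n, n_snps_autosomal=m, n_snps_x=0, n_loci=0,
        h2_autosomal=0.0, h2_x=0.0, ld_decay=0.0, ld_block_size=10, seed=seed,
    )
    panel = simulate_panel(cfg)
    rng = np.random.default_rng(seed + 1)
    y = (rng.uniform(size=n) < 0.59).astype(float)
    stats_df = run_screen(panel, y, mac_min=1)
    return inflation_lambda(stats_df)


def permutation_type1_rate(
    seed: int, n: int = 2000, n_permutations: int = 1000, alpha: float = 0.05
) -> float:
    """Empirical type-I error of the score-trait association at level alpha,
    by permuting the trait against a fixed score."""
    rng = np.random.default_rng(seed)
    score = rng.standard_normal(n)
    trait = 0.3 * score + rng.standard_normal(n)
    cov = pd.DataFrame({"age": rng.uniform(40, 70, n), "pc1": rng.standard_normal(n)})
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(trait)
        r = associate_score_with_trait(score, perm, "quantitative", cov)
        hits += r.p < alpha
    return hits / n_permutations
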
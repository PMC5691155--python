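"""Synthetic GWAS cohort generator with known ground truth.

Genotypes are produced by a Gaussian-copula model: within each LD block a
latent standard-normal AR(1) process with lag-one correlation ``ld_decay`` is
thresholded, haplotype by haplotype, at the quantile implied by the allele
frequency, so blocks have a closed-form adjacent-SNP correlation target and
sites are in Hardy-Weinberg equilibrium. Blocks are independent of each other
and separated by >500 kb so each causal block is one association locus.

The primary trait follows a liability-threshold model: liability = autosomal
genetic value + X genetic value + normal noise, dichotomised at the standard
normal quantile of (1 - prevalence). Secondary traits receive genetic input
only through configured pathway subsets of the loci, which is what makes
pathway-partitioned score correlations testable against ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError, SimulationConfig
from .panel import GenotypePanel, TruthRecord

_WITHIN_BLOCK_BP = 5_000
_BETWEEN_BLOCK_BP = 600_001  # keeps distinct blocks > 500 kb apart


def _ar1_latent(rng: np.random.Generator, n: int, block_sizes: list[int], rho: float) -> np.ndarray:
    """Latent N(0,1) matrix (n x total SNPs), AR(1) within each block."""
    total = sum(block_sizes)
    z = np.empty((n, total))
    col = 0
    for size in block_sizes:
        e = rng.standard_normal((n, size))
        block = np.empty_like(e)
        block[:, 0] = e[:, 0]
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, size):
            block[:, j] = rho * block[:, j - 1] + scale * e[:, j]
        z[:, col : col + size] = block
        col += size
    return z


def _block_sizes(n_snps: int, block_size: int) -> list[int]:
    sizes = [block_size] * (n_snps // block_size)
    if n_snps % block_size:
        sizes.append(n_snps % block_size)
    return sizes


def _positions(block_sizes: list[int]) -> np.ndarray:
    pos = []
    cur = 1
    for b, size in enumerate(block_sizes):
        if b > 0:
            cur += _BETWEEN_BLOCK_BP
        for _ in range(size):
            pos.append(cur)
            cur += _WITHIN_BLOCK_BP
    return np.asarray(pos, dtype=np.int64)


def latent_threshold(freq: np.ndarray | float) -> np.ndarray | float:
    """Latent threshold t such that P(Z < t) = allele frequency."""
    return stats.norm.ppf(freq)


def allele_indicator_correlation(p1: float, p2: float, rho: float) -> float:
    """Closed-form Pearson correlation of two thresholded-Gaussian allele
    indicators with frequencies ``p1``, ``p2`` and latent correlation ``rho``.

    Genotype dosages (sums of two independent haplotypes) have the same
    correlation, so this is the generator's adjacent-SNP correlation target.
    """
    if rho == 0.0:
        return 0.0
    t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    joint = stats.multivariate_normal.cdf(
        [t1, t2], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
    )
    return (joint - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


def simulate_panel(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenotypePanel:
    """Generate an all-male genotype panel per the block-copula model.

    Deterministic given ``config.seed`` (or an explicitly supplied generator).
    Autosomal SNPs sit on chromosome "1"; X SNPs on "X" with male dosages in
    {0, 2} (a single thresholded haplotype, doubled).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_individuals
    lo, hi = config.maf_range

    blocks_a = _block_sizes(config.n_snps_autosomal, config.ld_block_size)
    blocks_x = _block_sizes(config.n_snps_x, config.ld_block_size)

    freqs = rng.uniform(lo, hi, size=config.n_snps)
    thresholds = latent_threshold(freqs)

    parts = []
    if config.n_snps_autosomal:
        t_a = thresholds[: config.n_snps_autosomal]
        hap1 = (_ar1_latent(rng, n, blocks_a, config.ld_decay) < t_a).astype(float)
        hap2 = (_ar1_latent(rng, n, blocks_a, config.ld_decay) < t_a).astype(float)
        parts.append(hap1 + hap2)
    if config.n_snps_x:
        t_x = thresholds[config.n_snps_autosomal :]
        hap = _ar1_latent(rng, n, blocks_x, config.ld_decay) < t_x
        parts.append(2.0 * hap.astype(float))
    dosages = np.hstack(parts) if parts else np.empty((n, 0))

    chroms = ["1"] * config.n_snps_autosomal + ["X"] * config.n_snps_x
    pos = np.concatenate(
        [
            _positions(blocks_a) if blocks_a else np.empty(0, dtype=np.int64),
            _positions(blocks_x) if blocks_x else np.empty(0, dtype=np.int64),
        ]
    )
    block_ids = np.concatenate(
        [
            np.repeat(np.arange(len(blocks_a)), blocks_a) if blocks_a else np.empty(0, int),
            np.repeat(np.arange(len(blocks_a), len(blocks_a) + len(blocks_x)), blocks_x)
            if blocks_x
            else np.empty(0, int),
        ]
    ).astype(int)
    meta = pd.DataFrame(
        {
            "snp": [f"snp{i + 1}" for i in range(config.n_snps)],
            "chr": chroms,
            "pos": pos,
            "a1": "A",
            "a2": "G",
            "maf": freqs,
            "block": block_ids,
        }
    )
    sex = np.ones(n, dtype=int)  # male cohort
    return GenotypePanel(dosages=dosages, snp_meta=meta, sex=sex)


def _locus_blocks(config: SimulationConfig, meta: pd.DataFrame) -> dict[int, int]:
    """Assign locus ids 1..n_loci to LD blocks.

    If the configuration carries X heritability and X SNPs, the last locus is
    placed on the X chromosome (one X-linked locus, like the androgen-receptor
    locus in a baldness cohort); the rest are spread evenly over the autosomal
    blocks.
    """
    auto_blocks = sorted(meta.loc[meta["chr"] != "X", "block"].unique())
    x_blocks = sorted(meta.loc[meta["chr"] == "X", "block"].unique())
    want_x = config.h2_x > 0 and len(x_blocks) > 0
    n_auto_loci = config.n_loci - (1 if want_x else 0)
    if n_auto_loci > len(auto_blocks):
        raise ConfigurationError(
            f"{n_auto_loci} autosomal loci requested but only {len(auto_blocks)} LD blocks available"
        )
    chosen = np.linspace(0, len(auto_blocks) - 1, n_auto_loci).round().astype(int) if n_auto_loci else []
    if n_auto_loci and len(set(chosen)) != n_auto_loci:
        raise ConfigurationError("too few autosomal blocks to host distinct loci")
    mapping = {i + 1: auto_blocks[b] for i, b in enumerate(chosen)}
    if want_x:
        mapping[config.n_loci] = x_blocks[len(x_blocks) // 2]
    return mapping


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def simulate_traits(
    panel: GenotypePanel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate the primary liability-threshold trait and pathway-restricted
    secondary traits; returns (phenotype table, ground truth).

    Genetic values are rescaled in-sample so the realised variance of each
    component equals its configured h² exactly; the residual liability noise
    is likewise rescaled to 1 - h², making the realised liability-scale h²
    equal to the configured one by construction.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if panel.n_snps != config.n_snps:
        raise ConfigurationError("panel and config dimensions disagree")
    n = panel.n_individuals
    meta = panel.snp_meta
    if "block" not in meta.columns:
        raise ConfigurationError("panel lacks LD-block annotation; was it built by simulate_panel?")

    locus_block = _locus_blocks(config, meta)
    a_lo, a_hi = config.distinct_per_locus_range

    locus_snps: dict[int, list[str]] = {}
    locus_causal: dict[int, list[str]] = {}
    causal_rows = []
    for locus_id, block in sorted(locus_block.items()):
        members = meta.index[meta["block"] == block].to_numpy()
        locus_snps[locus_id] = meta.loc[members, "snp"].tolist()
        k = int(rng.integers(a_lo, a_hi + 1))
        k = min(k, len(members))
        picks = members[np.unique(np.round(np.linspace(0, len(members) - 1, k)).astype(int))]
        locus_causal[locus_id] = meta.loc[picks, "snp"].tolist()
        for s in locus_causal[locus_id]:
            causal_rows.append({"snp": s, "locus": locus_id, "beta": rng.standard_normal()})
    causal = pd.DataFrame(causal_rows, columns=["snp", "locus", "beta"])

    chr_of = dict(zip(meta["snp"], meta["chr"]))
    locus_is_x = {lid: chr_of[snps[0]] == "X" for lid, snps in locus_causal.items() if snps}

    def component_value(on_x: bool, target_h2: float) -> np.ndarray:
        lids = [lid for lid, isx in locus_is_x.items() if isx == on_x]
        mask = causal["locus"].isin(lids)
        if target_h2 <= 0 or not lids:
            if mask.any():
                causal.loc[mask, "beta"] = 0.0
            return np.zeros(n)
        if config.equalise_locus_h2:
            # every locus carries the same genetic variance within its component
            per_locus = target_h2 / len(lids)
            for lid in lids:
                lmask = causal["locus"] == lid
                sub = causal[lmask]
                w = _standardise(panel.dosage_of(sub["snp"]))
                g_l = w @ sub["beta"].to_numpy()
                sd = g_l.std()
                causal.loc[lmask, "beta"] *= np.sqrt(per_locus) / sd if sd > 0 else 0.0
        sub = causal[mask]
        w = _standardise(panel.dosage_of(sub["snp"]))
        g = w @ sub["beta"].to_numpy()
        sd = g.std()
        scale = np.sqrt(target_h2) / sd if sd > 0 else 0.0
        causal.loc[mask, "beta"] = causal.loc[mask, "beta"] * scale
        return g * scale

    g_auto = component_value(False, config.h2_autosomal)
    g_x = component_value(True, config.h2_x)
    g_total = g_auto + g_x

    h2 = config.h2_autosomal + config.h2_x
    noise = rng.standard_normal(n)
    noise = _standardise(noise[:, None])[:, 0] * np.sqrt(1.0 - h2)
    liability = g_total + noise
    threshold = stats.norm.ppf(1.0 - config.prevalence)
    case = (liability > threshold).astype(int)

    # per-locus genetic values (sums of that locus's weighted causal SNPs)
    locus_g: dict[int, np.ndarray] = {}
    for locus_id, snps in locus_causal.items():
        sub = causal[causal["locus"] == locus_id]
        w = _standardise(panel.dosage_of(sub["snp"]))
        locus_g[locus_id] = w @ sub["beta"].to_numpy()

    pheno = pd.DataFrame({"iid": panel.iids, "mpb": case, "liability": liability})
    pheno["age"] = rng.uniform(40, 70, size=n).round(1)
    for j in range(1, 6):
        pheno[f"pc{j}"] = rng.standard_normal(n)

    pathway_slopes: dict[str, dict[str, float]] = {}
    genetic_values: dict[str, np.ndarray] = {"mpb": g_total, "autosomal": g_auto, "x": g_x}
    trait_names = sorted({t for pw in config.pathways for t in pw.slopes})
    for trait in trait_names:
        y_gen = np.zeros(n)
        for pw in config.pathways:
            slope = pw.slopes.get(trait, 0.0)
            if slope == 0.0:
                continue
            g_pw = np.sum([locus_g[l] for l in pw.loci], axis=0)
            sd = g_pw.std()
            if sd > 0:
                y_gen = y_gen + slope * (g_pw - g_pw.mean()) / sd
            pathway_slopes.setdefault(pw.name, {})[trait] = slope
        genetic_values[trait] = y_gen
        pheno[trait] = y_gen + config.secondary_trait_noise * rng.standard_normal(n)

    truth = TruthRecord(
        causal_effects=causal,
        locus_snps=locus_snps,
        locus_causal=locus_causal,
        h2_autosomal=config.h2_autosomal,
        h2_x=config.h2_x,
        liability_threshold=threshold,
        pathway_slopes=pathway_slopes,
        genetic_values=genetic_values,
        locus_genetic_values=locus_g,
    )
    truth.validate_against(panel)
    return pheno, truth
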
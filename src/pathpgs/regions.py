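"""Regional genotypic scores for locus-level pleiotropy.

For each trait, associated regions are seeded by SNPs with p below the seed
threshold (1e-7) and extended to all SNPs below the extension threshold
(1e-6) reachable without a gap of 1 Mb or more between consecutive such
SNPs; regions sharing extension SNPs through sub-1-Mb gaps merge. Regional
scores are dosage-weighted effect-size sums over the region's SNPs after a
p-value filter, and cross-trait pleiotropy is flagged where two regional
scores share at least half their variance (r^2 >= 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

P_SEED = 1e-7
P_EXTEND = 1e-6
GAP_BP = 1_000_000
R2_FLAG = 0.5


@dataclass
class TraitRegion:
    trait: str
    chrom: str
    start: int
    end: int
    snps: pd.DataFrame  # columns SNP, BP, BETA, P

    @property
    def n_snps(self) -> int:
        return len(self.snps)


def define_trait_regions(
    stats_df: pd.DataFrame,
    trait: str = "trait",
    p_seed: float = P_SEED,
    p_extend: float = P_EXTEND,
    gap_bp: int = GAP_BP,
) -> list[TraitRegion]:
    """Gap-scan region definition over extension SNPs, keeping only runs
    containing at least one seed SNP. Boundaries are the min/max positions of
    the included SNPs (no padding)."""
    ext = stats_df[stats_df["P"] < p_extend]
    regions: list[TraitRegion] = []
    for chrom in ext["CHR"].unique():
        grp = ext[ext["CHR"] == chrom].sort_values("BP")
        pos = grp["BP"].to_numpy()
        breaks = np.nonzero(np.diff(pos) >= gap_bp)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(pos)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            chunk = grp.iloc[int(a) : int(b)]
            if not (chunk["P"] < p_seed).any():
                continue  # no seed SNP -> discarded
            regions.append(
                TraitRegion(
                    trait=trait,
                    chrom=str(chrom),
                    start=int(chunk["BP"].min()),
                    end=int(chunk["BP"].max()),
                    snps=chunk[["SNP", "BP", "BETA", "P"]].reset_index(drop=True),
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def regional_scores(
    panel,
    regions: list[TraitRegion],
    p_filter: float = P_EXTEND,
) -> pd.DataFrame:
    """Per-individual, per-region score: sum over the region's SNPs passing
    the p filter of dosage x effect-size weight. Regions left with no SNP
    after filtering are dropped (logged)."""
    cols = {}
    for k, region in enumerate(regions, start=1):
        kept = region.snps[region.snps["P"] < p_filter]
        kept = kept[kept["SNP"].isin(panel.snp_ids)]
        if kept.empty:
            log.info("regional_scores: region %s:%d-%d dropped (no SNPs pass filter)",
                     region.chrom, region.start, region.end)
            continue
        G = panel.dosage_of(kept["SNP"].tolist())
        name = f"{region.trait}_{region.chrom}_{region.start}"
        cols[name] = G @ kept["BETA"].to_numpy()
    return pd.DataFrame(cols, index=pd.Index(panel.iids, name="iid"))


def cross_trait_correlation(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    r2_flag: float = R2_FLAG,
) -> pd.DataFrame:
    """Pairwise squared Pearson correlations between two regional score
    matrices over shared individuals; rows with r^2 >= ``r2_flag`` carry
    flagged=True. Constant score columns yield r2 = NaN and are reported."""
    common = scores_a.index.intersection(scores_b.index)
    if len(common) == 0:
        raise ValueError("score matrices share no individuals")
    A = scores_a.loc[common]
    B = scores_b.loc[common]
    rows = []
    for ca in A.columns:
        for cb in B.columns:
            x, y = A[ca].to_numpy(), B[cb].to_numpy()
            if x.std() == 0 or y.std() == 0:
                r2 = np.nan
            else:
                r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
            rows.append(
                {
                    "score_a": ca,
                    "score_b": cb,
                    "r2": r2,
                    "flagged": bool(r2 >= r2_flag) if np.isfinite(r2) else False,
                }
            )
    return pd.DataFrame(rows, columns=["score_a", "score_b", "r2", "flagged"])
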
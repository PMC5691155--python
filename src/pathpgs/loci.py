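"""Locus definition, conditionally distinct SNP selection and replication.

A locus is a run of selected SNPs on one chromosome in which no two
consecutive selected SNPs are more than ``gap_bp`` apart (strictly more than
500 kb by default; a gap of exactly 500,000 bp keeps the run together).
Within a locus, conditionally distinct SNPs are chosen by stepwise
conditional regression on individual-level genotypes: add the top SNP as a
covariate, refit the rest, and repeat while any conditional p-value stays
below the genome-wide threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_GAP_BP = 500_000
GENOME_WIDE_P = 5e-8
COLLINEARITY_R2_GUARD = 0.9


@dataclass
class Locus:
    """A contiguous interval of associated SNPs (1-based inclusive)."""

    id: int
    chrom: str
    start: int
    end: int
    member_snps: list[str]
    distinct_snps: list[str] = field(default_factory=list)
    novel: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("locus start must be <= end")

    @property
    def n_distinct(self) -> int:
        return len(self.distinct_snps)

    def to_bed_interval(self) -> tuple[str, int, int]:
        """0-based half-open BED interval."""
        return (self.chrom, self.start - 1, self.end)


def define_loci(
    stats_df: pd.DataFrame,
    p_select: float = 1e-5,
    gap_bp: int = DEFAULT_GAP_BP,
) -> list[Locus]:
    """Partition SNPs with p < ``p_select`` into loci by single-linkage
    distance clustering: consecutive selected SNPs on the same chromosome
    stay in one locus unless their gap exceeds ``gap_bp`` (strict >).

    Loci are numbered 1..L in (chromosome, position) order. The
    at-least-one-distinct-SNP pruning is applied afterwards by
    :func:`prune_loci`, once distinct SNPs are known.
    """
    sel = stats_df[stats_df["P"] < p_select].copy()
    loci: list[Locus] = []
    if sel.empty:
        return loci
    for chrom in sel["CHR"].unique():
        grp = sel[sel["CHR"] == chrom]
        pos = grp["BP"].to_numpy()
        if np.any(np.diff(pos) < 0):
            log.warning("define_loci: unsorted positions on chromosome %s; sorting", chrom)
            grp = grp.sort_values("BP")
            pos = grp["BP"].to_numpy()
        breaks = np.nonzero(np.diff(pos) > gap_bp)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(pos)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            chunk = grp.iloc[int(a) : int(b)]
            loci.append(
                Locus(
                    id=0,
                    chrom=str(chrom),
                    start=int(chunk["BP"].min()),
                    end=int(chunk["BP"].max()),
                    member_snps=chunk["SNP"].tolist(),
                )
            )
    loci.sort(key=lambda l: (_chrom_key(l.chrom), l.start))
    for i, locus in enumerate(loci, start=1):
        locus.id = i
    return loci


def _chrom_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (1000, str(chrom))  # X and friends sort after autosomes


def _conditional_scan(
    y_r: np.ndarray, G_r: np.ndarray, dof: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP OLS of residualised phenotype on residualised dosage."""
    gg = (G_r * G_r).sum(axis=0)
    valid = gg > 1e-12
    beta = np.full(G_r.shape[1], np.nan)
    se = np.full_like(beta, np.nan)
    logp = np.zeros_like(beta)
    gy = G_r.T @ y_r
    beta[valid] = gy[valid] / gg[valid]
    rss = (y_r * y_r).sum() - beta[valid] * gy[valid]
    sigma2 = np.maximum(rss, 0.0) / dof
    se[valid] = np.sqrt(sigma2 / gg[valid])
    t = np.abs(beta[valid] / se[valid])
    logp_valid = np.log(2.0) + stats.t.logsf(t, dof)
    logp = np.full(G_r.shape[1], 0.0)
    logp[valid] = logp_valid
    logp[~valid] = 0.0  # collinear with conditioning set -> p = 1
    return beta, se, logp


def select_distinct_snps(
    panel,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None,
    locus: Locus,
    p_gw: float = GENOME_WIDE_P,
    r2_guard: float = COLLINEARITY_R2_GUARD,
) -> list[str]:
    """Stepwise conditional selection of distinct SNPs within one locus.

    At each round, the locus member with the smallest conditional p-value
    (given the already-selected SNPs as covariates) enters the set if its
    p < ``p_gw``; candidates with r² above ``r2_guard`` against the selected
    set are skipped. Ties break on smallest p, then smallest bp, then
    lexicographic SNP id. Returns SNP ids in order of entry.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]
    members = sorted(
        locus.member_snps,
        key=lambda s: (
            int(panel.snp_meta.set_index("snp").loc[s, "pos"]),
            s,
        ),
    )
    G = panel.dosage_of(members)
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)

    selected: list[str] = []
    pos_of = dict(zip(panel.snp_meta["snp"], panel.snp_meta["pos"]))
    while True:
        sel_idx = [members.index(s) for s in selected]
        cond = np.column_stack([np.ones(n), C] + [G[:, j] for j in sel_idx])
        Q, _ = np.linalg.qr(cond)
        y_r = y - Q @ (Q.T @ y)
        G_r = G - Q @ (Q.T @ G)
        dof = n - cond.shape[1] - 1
        beta, se, logp = _conditional_scan(y_r, G_r, dof)

        # collinearity guard: r^2 of candidate with span of selected set
        var0 = G.var(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2_with_sel = 1.0 - G_r.var(axis=0) / np.where(var0 > 0, var0, np.nan)
        candidates = []
        for j, snp in enumerate(members):
            if snp in selected:
                continue
            if selected and r2_with_sel[j] > r2_guard:
                log.info("select_distinct_snps: %s skipped (r2=%.3f with selected set)", snp, r2_with_sel[j])
                continue
            if np.isfinite(logp[j]) and logp[j] < np.log(p_gw):
                candidates.append((logp[j], pos_of[snp], snp))
        if not candidates:
            break
        candidates.sort()
        selected.append(candidates[0][2])
    return selected


def prune_loci(loci: list[Locus]) -> list[Locus]:
    """Keep only loci with at least one distinct SNP and renumber 1..L."""
    kept = [l for l in loci if l.n_distinct >= 1]
    for i, locus in enumerate(kept, start=1):
        locus.id = i
    return kept


def merge_loci(loci: list[Locus], merge_groups: list[list[int]]) -> list[Locus]:
    """Merge explicitly listed same-chromosome locus groups (by current id),
    e.g. when conditional analysis links neighbouring X loci into one. The
    merged locus keeps the smallest id's position in the renumbered list."""
    by_id = {l.id: l for l in loci}
    merged_away: set[int] = set()
    for group in merge_groups:
        ids = sorted(group)
        head = by_id[ids[0]]
        chroms = {by_id[i].chrom for i in ids}
        if len(chroms) > 1:
            raise ValueError(f"cannot merge loci on different chromosomes: {ids}")
        for other_id in ids[1:]:
            other = by_id[other_id]
            head.start = min(head.start, other.start)
            head.end = max(head.end, other.end)
            head.member_snps = head.member_snps + [s for s in other.member_snps if s not in head.member_snps]
            head.distinct_snps = head.distinct_snps + [s for s in other.distinct_snps if s not in head.distinct_snps]
            merged_away.add(other_id)
    out = [l for l in loci if l.id not in merged_away]
    for i, locus in enumerate(out, start=1):
        locus.id = i
    return out


def replicate_filter(
    discovery: pd.DataFrame,
    replication_meta: pd.DataFrame,
    p_rep: float = 0.05,
    require_direction: bool = True,
) -> tuple[pd.DataFrame, float | None, list[str]]:
    """Keep discovery SNPs whose replication meta-analysis p < ``p_rep``
    (strict) and, by default, whose effect direction agrees with discovery.

    Returns (replicated subset of the discovery table, replicated fraction —
    None when the discovery set is empty — and the list of unreplicated or
    missing SNPs).
    """
    if discovery.empty:
        return discovery.copy(), None, []
    rep = replication_meta.drop_duplicates("SNP").set_index("SNP")
    rep_p = rep["P"].reindex(discovery["SNP"]).to_numpy()
    rep_b = rep["BETA"].reindex(discovery["SNP"]).to_numpy()
    present = ~np.isnan(rep_p)
    ok = present & (rep_p < p_rep)
    if require_direction:
        ok &= np.sign(rep_b) == np.sign(discovery["BETA"].to_numpy())
    kept = discovery[ok].reset_index(drop=True)
    failed = discovery.loc[~ok, "SNP"].tolist()
    fraction = len(kept) / len(discovery)
    return kept, fraction, failed


def locus_table(loci: list[Locus]) -> pd.DataFrame:
    """Locus summary table (1-based inclusive coordinates)."""
    return pd.DataFrame(
        {
            "locus": [l.id for l in loci],
            "chr": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "replicated": ["N" if l.novel else "Y" for l in loci],
            "n_distinct_snps": [l.n_distinct for l in loci],
            "n_significant_snps": [len(l.member_snps) for l in loci],
        }
    )


def write_bed(loci: list[Locus], path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            chrom, start, end = l.to_bed_interval()
            fh.write(f"{chrom}\t{start}\t{end}\tlocus{l.id}\n")
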
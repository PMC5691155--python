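"""Locus definition, conditional SNP selection, replication filtering."""

import numpy as np
import pandas as pd
import pytest

import pathpgs as pg

import oracles
from conftest import toy_panel


def stats_table(positions, pvals, chrom="1", betas=None):
    m = len(positions)
    return pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(m)],
            "CHR": chrom,
            "BP": positions,
            "A1": "A",
            "A2": "G",
            "BETA": betas if betas is not None else 0.1,
            "SE": 0.02,
            "P": pvals,
            "N": 1000,
        }
    )


class TestDefineLoci:
    def test_gap_rule_is_strictly_greater_than(self):
        one = pg.define_loci(stats_table([1, 500_001], [1e-9, 1e-9]))
        assert len(one) == 1
        two = pg.define_loci(stats_table([1, 500_002], [1e-9, 1e-9]))
        assert len(two) == 2

    def test_matches_brute_force_single_linkage(self, rng):
        pos = np.sort(rng.choice(50_000_000, size=200, replace=False))
        tbl = stats_table(pos, 1e-9)
        loci = pg.define_loci(tbl)
        expected = oracles.single_linkage_loci(pos, 500_000)
        got = [[int(np.where(pos == p)[0][0]) for p in
                tbl.set_index("SNP").loc[l.member_snps, "BP"]] for l in loci]
        assert sorted(map(sorted, got)) == sorted(map(sorted, expected))

    def test_partition_property(self, rng):
        pos = np.sort(rng.choice(10_000_000, size=80, replace=False))
        pvals = rng.uniform(size=80) * 1e-4  # some above, some below 1e-5
        tbl = stats_table(pos, pvals)
        loci = pg.define_loci(tbl, p_select=1e-5)
        selected = set(tbl.loc[tbl["P"] < 1e-5, "SNP"])
        members = [s for l in loci for s in l.member_snps]
        assert len(members) == len(set(members))  # no SNP in two loci
        assert set(members) == selected

    def test_chromosomes_do_not_merge_and_numbering_is_genomic(self):
        tbl = pd.concat(
            [
                stats_table([1000], [1e-9], chrom="2"),
                stats_table([500], [1e-9], chrom="X"),
                stats_table([900], [1e-9], chrom="1"),
            ],
            ignore_index=True,
        )
        loci = pg.define_loci(tbl)
        assert [(l.id, l.chrom) for l in loci] == [(1, "1"), (2, "2"), (3, "X")]

    def test_unsorted_input_is_sorted_with_warning(self, caplog):
        tbl = stats_table([900_000, 100], [1e-9, 1e-9])
        with caplog.at_level("WARNING"):
            loci = pg.define_loci(tbl)
        assert len(loci) == 2
        assert any("unsorted" in r.message for r in caplog.records)


def planted_locus_panel(rng, n, k, h2_per_snp=0.004, m=10, ld=0.0):
    """One LD block of m SNPs with k orthogonal planted causal SNPs."""
    cfg = pg.SimulationConfig(
        n_individuals=n, n_snps_autosomal=m, n_snps_x=0, n_loci=1,
        ld_block_size=m, ld_decay=ld, h2_autosomal=0.0, h2_x=0.0,
        maf_range=(0.2, 0.4), seed=int(rng.integers(2**31)),
    )
    panel = pg.simulate_panel(cfg)
    causal_idx = np.linspace(0, m - 1, k).round().astype(int)
    W = panel.dosages[:, causal_idx]
    W = (W - W.mean(0)) / W.std(0)
    g = W @ np.full(k, np.sqrt(h2_per_snp))
    y = g + rng.standard_normal(n) * np.sqrt(1 - k * h2_per_snp)
    locus = pg.Locus(
        id=1, chrom="1",
        start=int(panel.snp_meta["pos"].min()), end=int(panel.snp_meta["pos"].max()),
        member_snps=list(panel.snp_ids),
    )
    causal_ids = [panel.snp_ids[i] for i in causal_idx]
    return panel, y, locus, causal_ids


class TestSelectDistinct:
    def test_single_significant_member(self, rng):
        panel, y, locus, causal = planted_locus_panel(rng, 8000, k=1, h2_per_snp=0.02)
        got = pg.select_distinct_snps(panel, y, None, locus)
        assert got == causal

    def test_perfect_ld_collapses_to_one(self, rng):
        x = rng.binomial(2, 0.3, 5000).astype(float)
        y = (x - x.mean()) * 0.15 + rng.standard_normal(5000)
        panel = toy_panel(np.column_stack([x, x]))
        locus = pg.Locus(id=1, chrom="1", start=1000, end=2000, member_snps=["s1", "s2"])
        got = pg.select_distinct_snps(panel, y, None, locus)
        assert len(got) == 1

    def test_three_orthogonal_signals_match_exhaustive_search(self, rng):
        panel, y, locus, causal = planted_locus_panel(rng, 20_000, k=3, h2_per_snp=0.01, m=5)
        got = pg.select_distinct_snps(panel, y, None, locus)
        assert sorted(got) == sorted(causal)
        oracle = oracles.exhaustive_conditional_sets(panel.dosages, y, 5e-8)
        oracle_ids = {panel.snp_ids[j] for j in oracle}
        assert set(got) == oracle_ids

    def test_member_order_invariance(self, rng):
        panel, y, locus, _ = planted_locus_panel(rng, 10_000, k=2, h2_per_snp=0.01)
        forward = pg.select_distinct_snps(panel, y, None, locus)
        locus_rev = pg.Locus(
            id=1, chrom=locus.chrom, start=locus.start, end=locus.end,
            member_snps=locus.member_snps[::-1],
        )
        assert pg.select_distinct_snps(panel, y, None, locus_rev) == forward

    def test_planted_count_recovered_across_replicates(self):
        """With k <= 5 planted orthogonal causal SNPs at n = 20,000, the
        stepwise procedure selects exactly k in >= 95% of 200 replicates."""
        rng = np.random.default_rng(31)
        hits = 0
        reps = 200
        for _ in range(reps):
            k = int(rng.integers(1, 6))
            panel, y, locus, _ = planted_locus_panel(rng, 20_000, k=k, h2_per_snp=0.004)
            got = pg.select_distinct_snps(panel, y, None, locus)
            hits += len(got) == k
        assert hits / reps >= 0.95

    def test_selected_stay_significant_in_joint_model(self, rng):
        panel, y, locus, _ = planted_locus_panel(rng, 20_000, k=4, h2_per_snp=0.006)
        got = pg.select_distinct_snps(panel, y, None, locus)
        assert len(got) <= len(locus.member_snps)
        G = panel.dosage_of(got)
        n = len(y)
        for j in range(G.shape[1]):
            others = np.column_stack([np.ones(n)] + [G[:, i] for i in range(G.shape[1]) if i != j])
            Q, _ = np.linalg.qr(others)
            y_r = y - Q @ (Q.T @ y)
            x_r = G[:, j] - Q @ (Q.T @ G[:, j])
            beta = x_r @ y_r / (x_r @ x_r)
            se = np.sqrt(((y_r - beta * x_r) @ (y_r - beta * x_r)) / (n - others.shape[1] - 1) / (x_r @ x_r))
            from scipy import stats as st

            assert 2 * st.norm.sf(abs(beta / se)) < 5e-8


class TestReplicationAndMerge:
    def test_boundary_p_excluded(self):
        disc = stats_table([100], [1e-9], betas=[0.5])
        rep = stats_table([100], [0.05], betas=[0.5])
        kept, frac, failed = pg.replicate_filter(disc, rep)
        assert kept.empty and frac == 0.0 and failed == ["rs0"]

    def test_direction_concordance_flag(self):
        disc = stats_table([100], [1e-9], betas=[0.5])
        rep = stats_table([100], [0.001], betas=[-0.5])
        kept, _, _ = pg.replicate_filter(disc, rep, require_direction=True)
        assert kept.empty
        kept_lit, _, _ = pg.replicate_filter(disc, rep, require_direction=False)
        assert len(kept_lit) == 1  # the literal p-only rule

    def test_missing_snp_counts_as_unreplicated(self):
        disc = stats_table([100, 200], [1e-9, 1e-9], betas=[0.5, 0.5])
        rep = stats_table([100], [0.001], betas=[0.5])
        kept, frac, failed = pg.replicate_filter(disc, rep)
        assert len(kept) == 1 and frac == 0.5 and failed == ["rs1"]

    def test_empty_discovery_reports_na(self):
        disc = stats_table([], [])
        kept, frac, failed = pg.replicate_filter(disc, disc)
        assert kept.empty and frac is None and failed == []

    def test_prune_drops_loci_without_distinct_snps(self):
        l1 = pg.Locus(id=1, chrom="1", start=1, end=10, member_snps=["a"], distinct_snps=["a"])
        l2 = pg.Locus(id=2, chrom="1", start=20, end=30, member_snps=["b"], distinct_snps=[])
        l3 = pg.Locus(id=3, chrom="2", start=1, end=10, member_snps=["c"], distinct_snps=["c"])
        kept = pg.prune_loci([l1, l2, l3])
        assert [(l.id, l.chrom) for l in kept] == [(1, "1"), (2, "2")]

    def test_explicit_merge_of_same_chromosome_loci(self):
        lx1 = pg.Locus(id=1, chrom="X", start=100, end=200, member_snps=["a"], distinct_snps=["a"])
        lx2 = pg.Locus(id=2, chrom="X", start=900, end=950, member_snps=["b"], distinct_snps=["b"])
        merged = pg.merge_loci([lx1, lx2], [[1, 2]])
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 950)
        assert merged[0].distinct_snps == ["a", "b"]
        with pytest.raises(ValueError):
            pg.merge_loci(
                [
                    pg.Locus(id=1, chrom="1", start=1, end=2, member_snps=["a"], distinct_snps=["a"]),
                    pg.Locus(id=2, chrom="2", start=1, end=2, member_snps=["b"], distinct_snps=["b"]),
                ],
                [[1, 2]],
            )

    def test_bed_export_is_zero_based_half_open(self):
        l1 = pg.Locus(id=1, chrom="1", start=100, end=200, member_snps=["a"], distinct_snps=["a"])
        assert l1.to_bed_interval() == ("1", 99, 200)
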
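"""Polygenic scores: joint weights, aggregation, trait scans, q-values."""

import numpy as np
import pandas as pd
import pytest

import pathpgs as pg
from pathpgs.assoc import CollinearityError
from pathpgs.scores import estimate_pi0

import oracles
from conftest import toy_panel


def make_loci(locus_snps: dict[int, list[str]]):
    return [
        pg.Locus(id=k, chrom="1", start=1, end=2, member_snps=v, distinct_snps=v)
        for k, v in locus_snps.items()
    ]


class TestJointBetas:
    def test_toy_fit_matches_independent_newton_solver(self, rng):
        n = 8
        G = np.array(
            [[0, 1], [2, 0], [1, 1], [0, 0], [2, 2], [1, 0], [0, 2], [1, 2]], dtype=float
        )
        y = np.array([0, 0, 0, 1, 0, 1, 1, 0], dtype=float)
        panel = toy_panel(G)
        betas = pg.reestimate_joint_betas(panel, y, None, ["s1", "s2"])
        X = np.column_stack([np.ones(n), G])
        oracle = oracles.newton_logistic(X, y)
        np.testing.assert_allclose(betas.to_numpy(), oracle[1:], atol=1e-8)

    def test_orthogonal_snps_joint_equals_marginal(self, rng):
        n = 6000
        G = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        logit = -0.2 + G @ np.array([0.3, -0.25, 0.2])
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(float)
        panel = toy_panel(G)
        joint = pg.reestimate_joint_betas(panel, y, None, ["s1", "s2", "s3"])
        marg = pg.refit_logistic(panel, y)
        for snp in ["s1", "s2", "s3"]:
            m = marg.set_index("SNP").loc[snp]
            assert abs(joint[snp] - m["BETA"]) < 2 * m["SE"]

    def test_duplicated_snp_columns_rejected(self, rng):
        x = rng.binomial(2, 0.3, 500).astype(float)
        panel = toy_panel(np.column_stack([x, x]))
        y = rng.integers(0, 2, 500).astype(float)
        with pytest.raises(CollinearityError):
            pg.reestimate_joint_betas(panel, y, None, ["s1", "s2"])


class TestLocusScores:
    def test_single_term(self):
        panel = toy_panel(np.array([[2.0]]))
        w = pd.Series([0.5], index=["s1"])
        ss = pg.compute_locus_scores(panel, w, make_loci({1: ["s1"]}))
        assert ss.locus_scores["locus1"].iloc[0] == pytest.approx(1.0)

    def test_null_weights_give_null_scores(self, rng):
        panel = toy_panel(rng.integers(0, 3, (10, 4)).astype(float))
        w = pd.Series(0.0, index=panel.snp_ids)
        ss = pg.compute_locus_scores(panel, w, make_loci({1: ["s1", "s2"], 2: ["s3", "s4"]}))
        assert (ss.locus_scores.to_numpy() == 0).all()

    def test_toy_matrix_product(self):
        G = np.array([[0, 1, 2], [2, 2, 0], [1, 0, 1], [0, 0, 0]], dtype=float)
        w = pd.Series([0.5, -1.0, 0.25], index=["s1", "s2", "s3"])
        panel = toy_panel(G)
        ss = pg.compute_locus_scores(panel, w, make_loci({1: ["s1", "s2", "s3"]}))
        np.testing.assert_allclose(ss.locus_scores["locus1"], G @ w.to_numpy(), atol=1e-12)

    def test_conservation_invariants(self, rng):
        panel = toy_panel(rng.integers(0, 3, (50, 6)).astype(float))
        w = pd.Series(rng.standard_normal(6), index=panel.snp_ids)
        loci = make_loci({1: ["s1", "s2"], 2: ["s3"], 3: ["s4", "s5", "s6"]})
        ss = pg.compute_locus_scores(panel, w, loci)
        ss = pg.aggregate_scores(ss, {"pwA": (1, 3), "pwB": (2,)})
        ss.validate(atol=1e-9)

    def test_missing_weight_is_an_error(self, rng):
        panel = toy_panel(rng.integers(0, 3, (5, 2)).astype(float))
        w = pd.Series([0.1], index=["s1"])
        with pytest.raises(KeyError):
            pg.compute_locus_scores(panel, w, make_loci({1: ["s1", "s2"]}))


class TestAggregation:
    def test_unknown_locus_rejected(self, rng):
        panel = toy_panel(rng.integers(0, 3, (5, 2)).astype(float))
        w = pd.Series([0.1, 0.2], index=["s1", "s2"])
        ss = pg.compute_locus_scores(panel, w, make_loci({1: ["s1"], 2: ["s2"]}))
        with pytest.raises(KeyError, match="unknown loci"):
            pg.aggregate_scores(ss, {"pw": (9,)})

    def test_explicit_vs_all_identical_merge(self, rng):
        panel = toy_panel(rng.integers(0, 3, (20, 4)).astype(float))
        w = pd.Series(rng.standard_normal(4), index=panel.snp_ids)
        loci = make_loci({1: ["s1"], 2: ["s2"], 3: ["s3"], 4: ["s4"]})
        mapping = {"a": (1, 2), "b": (1, 2), "c": (3,), "d": (3,), "e": (4,)}
        ss = pg.compute_locus_scores(panel, w, loci)
        explicit = pg.aggregate_scores(ss, mapping, "explicit", [["a", "b"]])
        assert set(explicit.pathway_scores.columns) == {"a / b", "c", "d", "e"}
        ss2 = pg.compute_locus_scores(panel, w, loci)
        allid = pg.aggregate_scores(ss2, mapping, "all-identical")
        assert set(allid.pathway_scores.columns) == {"a / b", "c / d", "e"}

    def test_explicit_merge_requires_identical_locus_sets(self, rng):
        panel = toy_panel(rng.integers(0, 3, (10, 2)).astype(float))
        w = pd.Series([0.1, 0.2], index=panel.snp_ids)
        ss = pg.compute_locus_scores(panel, w, make_loci({1: ["s1"], 2: ["s2"]}))
        with pytest.raises(ValueError, match="different locus sets"):
            pg.aggregate_scores(ss, {"a": (1,), "b": (2,)}, "explicit", [["a", "b"]])


class TestTraitAssociation:
    def test_linear_recovery_of_known_effect(self, rng):
        n = 4000
        score = rng.standard_normal(n)
        trait = 2.0 * score + rng.standard_normal(n)
        r = pg.associate_score_with_trait(score, trait, "quantitative")
        assert abs(r.effect - 2.0) < 2 * r.se
        assert r.p < 1e-10

    def test_binary_null_z_is_standard_normal(self, rng):
        zs = []
        for _ in range(60):
            score = rng.standard_normal(3000)
            trait = rng.integers(0, 2, 3000).astype(float)
            zs.append(pg.associate_score_with_trait(score, trait, "binary").z)
        inside = np.mean(np.abs(zs) < 1.96)
        assert 0.85 <= inside <= 1.0

    def test_cox_family_detects_survival_effect(self, rng):
        n = 3000
        score = rng.standard_normal(n)
        # higher score -> higher hazard -> shorter time
        time = rng.exponential(np.exp(-0.5 * score))
        status = np.ones(n)
        trait = np.column_stack([time, status])
        r = pg.associate_score_with_trait(score, trait, "parental-survival")
        assert r.z > 5
        assert abs(r.effect - 0.5) < 3 * r.se

    def test_degenerate_inputs_rejected(self, rng):
        score = rng.standard_normal(100)
        with pytest.raises(ValueError, match="constant"):
            pg.associate_score_with_trait(score, np.ones(100), "quantitative")
        with pytest.raises(ValueError, match="events"):
            trait = np.column_stack([rng.uniform(size=100), np.zeros(100)])
            pg.associate_score_with_trait(score, trait, "parental-survival")
        with pytest.raises(ValueError, match="family"):
            pg.associate_score_with_trait(score, score, "ordinal")


class TestStoreyQ:
    def test_single_p_with_pi0_one(self):
        np.testing.assert_allclose(pg.storey_qvalues(np.array([0.03]), pi0=1.0), [0.03])

    def test_four_value_hand_oracle(self):
        p = np.array([0.01, 0.02, 0.9, 0.95])
        got = pg.storey_qvalues(p, pi0=1.0)
        expected = oracles.stepdown_qvalues(p, pi0=1.0)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        # hand calculation: q = (0.04, 0.04, 0.95, 0.95)
        np.testing.assert_allclose(got, [0.04, 0.04, 0.95, 0.95], atol=1e-12)

    def test_random_p_matches_stepdown_oracle(self, rng):
        p = rng.uniform(0.001, 1.0, size=37)
        np.testing.assert_allclose(
            pg.storey_qvalues(p, pi0=0.8), oracles.stepdown_qvalues(p, pi0=0.8), atol=1e-12
        )

    def test_pi0_estimate_under_uniform_null(self, rng):
        p = rng.uniform(size=10_000)
        assert 0.9 <= estimate_pi0(p) <= 1.05

    def test_q_monotone_in_p_and_bounded(self, rng):
        p = rng.uniform(0.001, 1, size=500)
        q = pg.storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0) and np.all(q >= 0.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            pg.storey_qvalues(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            pg.storey_qvalues(np.array([0.5, 1.2]))

    def test_scan_q_nondecreasing_in_p(self, rng):
        scores = pd.DataFrame({"a": rng.standard_normal(800), "b": rng.standard_normal(800)})
        traits = {
            "t1": (rng.standard_normal(800), "quantitative"),
            "t2": (rng.integers(0, 2, 800).astype(float), "binary"),
        }
        table = pg.scan_scores_against_traits(scores, traits)
        srt = table.sort_values("p")
        assert np.all(np.diff(srt["q"].to_numpy()) >= -1e-12)
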
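"""Core sMFE math: hand-derived values, the literal-formula oracle, and
the score's structural invariants."""

import math

import numpy as np
import pandas as pd
import pytest

import _oracle
from smfe import (
    DirectedNetwork,
    ExpressionMatrix,
    LocalNetwork,
    fit_normalizer,
    local_mfe,
    local_smfe,
    score_cohort,
    score_sample,
    transition_probs,
)
from smfe.core import TransitionVector, _select_signaling

from conftest import random_expression


class TestNormalizer:
    def test_minmax_maps_reference_to_unit_interval(self):
        ref = ExpressionMatrix(pd.DataFrame(
            {"r1": [2.0], "r2": [4.0], "r3": [6.0]}, index=["g1"]))
        norm = fit_normalizer(ref)
        out = norm.transform(ref.data)
        assert np.allclose(out.loc["g1"], [0.0, 0.5, 1.0])

    def test_case_value_beyond_range_clips(self):
        ref = ExpressionMatrix(pd.DataFrame(
            {"r1": [2.0], "r2": [4.0], "r3": [6.0]}, index=["g1"]))
        norm = fit_normalizer(ref)
        case = norm.transform(pd.Series({"g1": 10.0}))
        assert case["g1"] == 1.0

    def test_constant_gene_maps_to_zero(self):
        ref = ExpressionMatrix(pd.DataFrame(
            {"r1": [5.0], "r2": [5.0], "r3": [5.0]}, index=["g1"]))
        norm = fit_normalizer(ref)
        assert (norm.transform(ref.data).loc["g1"] == 0.0).all()
        assert norm.transform(pd.Series({"g1": 7.0}))["g1"] == 0.0

    def test_single_reference_sample_rejected(self):
        ref = ExpressionMatrix(pd.DataFrame({"r1": [1.0]}, index=["g1"]))
        with pytest.raises(ValueError, match="2 reference samples"):
            fit_normalizer(ref)


class TestTransitionProbs:
    def test_hand_value_half_half(self):
        # |PCC| = (0.5, 0.5) -> p = (0.25, 0.25): denominator 1 + 0.5 + 0.5
        p = np.array([0.5, 0.5]) / (1.0 + 1.0)
        assert np.allclose(p, [0.25, 0.25])

    def test_perfect_correlations_give_one_third(self):
        # neighbors perfectly correlated with the center: p_i = 1/3
        cohort = pd.DataFrame(
            {"s1": [1.0, 1.0, 0.0], "s2": [2.0, 2.0, 1.0], "s3": [3.0, 3.0, 2.0]},
            index=["c", "n1", "n2"],
        )
        tv = transition_probs(cohort, LocalNetwork("c", ("n1", "n2")))
        assert np.allclose(tv.p, [1 / 3, 1 / 3])
        assert tv.S == pytest.approx(2.0)

    def test_zero_variance_neighbor_contributes_zero(self):
        cohort = pd.DataFrame(
            {"s1": [1.0, 5.0, 0.0], "s2": [2.0, 5.0, 1.0], "s3": [3.0, 5.0, 2.0]},
            index=["c", "flat", "n2"],
        )
        tv = transition_probs(cohort, LocalNetwork("c", ("flat", "n2")))
        assert tv.p[0] == 0.0

    def test_probabilities_sum_to_s_over_one_plus_s(self, rng):
        cohort = pd.DataFrame(rng.random((4, 6)), index=["c", "a", "b", "d"])
        tv = transition_probs(cohort, LocalNetwork("c", ("a", "b", "d")))
        assert tv.p.sum() == pytest.approx(tv.S / (1.0 + tv.S))
        assert np.all(tv.p >= 0) and np.all(tv.p < 1)

    def test_m_zero_rejected(self):
        cohort = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["c"])
        with pytest.raises(ValueError, match="no neighbors"):
            transition_probs(cohort, LocalNetwork("c", ()))


class TestLocalMfe:
    def test_zero_expression_gives_zero(self):
        assert local_mfe(0.0, np.array([0.3, 0.3])) == 0.0

    def test_hand_value(self):
        # xbar = 0.5, p = (1/3, 1/3): 2 * (1/6) ln 6
        expected = 2 * (1 / 6) * math.log(6)
        assert local_mfe(0.5, np.array([1 / 3, 1 / 3])) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.5973, abs=5e-5)

    def test_all_zero_probs_give_zero(self):
        assert local_mfe(0.7, np.zeros(5)) == 0.0

    def test_accepts_transition_vector(self):
        tv = TransitionVector("c", np.array([0.25, 0.25]), 1.0)
        assert local_mfe(0.5, tv) == local_mfe(0.5, np.array([0.25, 0.25]))


class TestLocalSmfe:
    def test_nonnegative_for_random_inputs(self, rng):
        genes = [f"g{i}" for i in range(6)]
        ref = random_expression(rng, genes, 8)
        case = pd.Series(rng.gamma(2.0, 2.0, 6), index=genes)
        ln = LocalNetwork("g0", ("g1", "g2", "g3"))
        for sd_on in ("raw", "normalized"):
            assert local_smfe(ref, case, ln, sd_on=sd_on) >= 0.0

    def test_constant_center_gene_scores_zero(self, rng):
        genes = ["c", "n1", "n2"]
        data = rng.random((3, 5))
        data[0] = 4.0  # center flat in reference
        ref = ExpressionMatrix(pd.DataFrame(data, index=genes))
        case = pd.Series({"c": 4.0, "n1": 0.5, "n2": 0.2})
        ln = LocalNetwork("c", ("n1", "n2"))
        # SD^n = SD^{n+1} = 0 and xbar = 0 after constant-gene normalization
        assert local_smfe(ref, case, ln) == 0.0

    def test_m_below_two_rejected(self, toy5):
        ref, case, _ = toy5
        with pytest.raises(ValueError, match="not scoreable"):
            local_smfe(ref, case, LocalNetwork("gD", ("gA",)))

    @pytest.mark.parametrize("sd_on", ["raw", "normalized"])
    @pytest.mark.parametrize("eq6_form", ["product", "literal"])
    def test_toy5_matches_literal_oracle(self, toy5, sd_on, eq6_form):
        """Fixed 5-gene toy: every center agrees with the independent
        step-by-step evaluation of the normalization, PCC, transition,
        entropy and differential formulas."""
        ref, case, net = toy5
        ref_dict = {g: list(ref.data.loc[g]) for g in ref.gene_ids}
        case_dict = dict(case)
        for center in ["gA", "gB", "gC", "gE"]:
            nbs = net.out_neighbors(center)
            expected = _oracle.local_smfe(
                ref_dict, case_dict, center, list(nbs), sd_on=sd_on, eq6_form=eq6_form)
            got = local_smfe(ref, case, LocalNetwork(center, nbs),
                             eq6_form=eq6_form, sd_on=sd_on)
            assert got == pytest.approx(expected, abs=1e-12)


class TestScoreSample:
    @pytest.mark.parametrize("L,expected_q", [(100, 5), (20, 1), (41, 3)])
    def test_top_fraction_count_uses_ceiling(self, L, expected_q):
        genes = np.array([f"g{i:03d}" for i in range(L)])
        scores = np.linspace(1.0, 2.0, L)
        global_score, signaling = _select_signaling(genes, scores, 0.05)
        assert len(signaling) == expected_q

    def test_q1_global_score_is_max(self):
        genes = np.array([f"g{i}" for i in range(20)])
        scores = np.arange(20, dtype=float)[::-1].copy()  # 19, 18, ..., 0
        global_score, signaling = _select_signaling(genes, scores, 0.05)
        assert global_score == 19.0
        assert signaling == ("g0",)

    def test_ties_at_cutoff_break_by_gene_id(self):
        genes = np.array(["a", "b", "c", "d"])
        scores = np.array([1.0, 1.0, 1.0, 0.5])
        _, signaling = _select_signaling(genes, scores, 0.5)  # Q = 2
        assert signaling == ("a", "b")

    def test_matches_oracle_end_to_end(self, toy5):
        ref, case, net = toy5
        got = score_sample(net, ref, case, fraction=0.5)
        ref_dict = {g: list(ref.data.loc[g]) for g in ref.gene_ids}
        nbhd = {g: list(net.out_neighbors(g)) for g in net.nodes}
        local, global_score, ranked = _oracle.score_sample(
            ref_dict, dict(case), nbhd, fraction=0.5)
        assert got.global_score == pytest.approx(global_score, abs=1e-12)
        assert got.signaling_genes == tuple(ranked)
        for g, v in local.items():
            assert got.local_scores[g] == pytest.approx(v, abs=1e-12)

    def test_score_cohort_equals_score_sample(self, toy5, rng):
        ref, _, net = toy5
        cases = random_expression(rng, ref.gene_ids, 3, prefix="c")
        cohort_scores = score_cohort(net, ref, cases, fraction=0.5)
        for s in cohort_scores:
            single = score_sample(net, ref, cases.data[s.sample_id],
                                  fraction=0.5, sample_id=s.sample_id)
            assert single.global_score == pytest.approx(s.global_score, abs=1e-14)
            assert single.signaling_genes == s.signaling_genes

    def test_missing_network_gene_dropped_with_scores_still_produced(self, toy5):
        ref, case, net = toy5
        bigger = DirectedNetwork(list(net.edges) + [("gA", "zz"), ("zz", "gA"), ("zz", "gB")])
        got = score_sample(bigger, ref, case, fraction=0.5)
        assert "zz" not in got.local_scores


class TestInvariants:
    def test_sample_permutation_leaves_scores_unchanged(self, toy5, rng):
        ref, case, net = toy5
        perm = rng.permutation(ref.sample_ids)
        ref_perm = ExpressionMatrix(ref.data[list(perm)])
        a = score_sample(net, ref, case, fraction=0.5)
        b = score_sample(net, ref_perm, case, fraction=0.5)
        for g in a.local_scores:
            assert abs(a.local_scores[g] - b.local_scores[g]) < 1e-12

    def test_gene_row_permutation_leaves_scores_unchanged(self, toy5, rng):
        ref, case, net = toy5
        perm = rng.permutation(ref.gene_ids)
        ref_perm = ExpressionMatrix(ref.data.loc[list(perm)])
        a = score_sample(net, ref, case, fraction=0.5)
        b = score_sample(net, ref_perm, case.loc[list(perm)], fraction=0.5)
        assert a.global_score == pytest.approx(b.global_score, abs=1e-12)

    def test_uniform_probabilities_maximize_entropy(self, rng):
        """At fixed xbar and fixed total transition mass, the entropy is
        largest when the mass is spread evenly over the neighbors."""
        for _ in range(200):
            m = int(rng.integers(2, 8))
            total = float(rng.uniform(0.05, 0.95))
            xbar = float(rng.uniform(0.05, 1.0))
            p_rand = rng.dirichlet(np.ones(m)) * total
            p_unif = np.full(m, total / m)
            assert local_mfe(xbar, p_unif) >= local_mfe(xbar, p_rand) - 1e-12

    def test_single_dominant_neighbor_is_entropy_minimum(self):
        """One neighbor taking all the flow gives the single-term value,
        below the uniform spread."""
        xbar, total, m = 0.6, 0.9, 4
        p_concentrated = np.zeros(m)
        p_concentrated[0] = total
        p_unif = np.full(m, total / m)
        lo = local_mfe(xbar, p_concentrated)
        hi = local_mfe(xbar, p_unif)
        assert lo == pytest.approx(-(xbar * total) * math.log(xbar * total))
        assert lo <= hi
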
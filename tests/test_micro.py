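"""Micro dynamics: entropy, transition estimation, bootstrap delta maps."""

import json

import numpy as np
import pytest

from inquiryflow.agent import _matrix
from inquiryflow.coding import MicroCode
from inquiryflow.micro import (
    SOURCES,
    TARGETS,
    TransitionMatrix,
    bootstrap_deltas,
    build_process_graph,
    count_transitions,
    entropy_group_comparison,
    estimate_transitions,
    graph_from_dot,
    graph_from_json,
    graph_to_dot,
    graph_to_json,
    normalized_entropy,
)
from tests.conftest import sample_chain

ST, AG, AD, RT = (
    MicroCode.START_TASK,
    MicroCode.ADJUST_GATE,
    MicroCode.ADJUST_DIAMETER,
    MicroCode.RUN_TRIAL,
)
IA, RA, RR, ET = (
    MicroCode.INITIAL_ANSWER,
    MicroCode.REVISE_ANSWER,
    MicroCode.REMOVE_RECORD,
    MicroCode.END_TASK,
)


class TestEntropy:
    def test_uniform_repertoire_is_maximal(self):
        seq = list(MicroCode) * 3
        h, norm = normalized_entropy(seq)
        assert h == pytest.approx(3.0)
        assert norm == pytest.approx(1.0)

    def test_single_code_is_zero(self):
        assert normalized_entropy([RT] * 10) == (0.0, 0.0)

    def test_two_equal_codes_give_one_bit(self):
        h, norm = normalized_entropy([AG, RT] * 5)
        assert h == pytest.approx(1.0)
        assert norm == pytest.approx(1 / 3)

    def test_invariant_to_order_and_relabeling(self):
        rng = np.random.default_rng(0)
        codes = list(MicroCode)
        seq = [codes[i] for i in rng.integers(0, 8, 30)]
        shuffled = [seq[i] for i in rng.permutation(len(seq))]
        assert normalized_entropy(seq) == normalized_entropy(shuffled)
        # relabel by a fixed permutation of the alphabet
        perm = dict(zip(codes, codes[1:] + codes[:1]))
        relabeled = [perm[c] for c in seq]
        assert normalized_entropy(seq)[1] == pytest.approx(normalized_entropy(relabeled)[1])

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            normalized_entropy([])


class TestEntropyComparison:
    @staticmethod
    def _cells(rng, shift=0.0, n=50):
        values, eff, effi = [], [], []
        for e in ("Effective", "Ineffective"):
            for f in ("Efficient", "Inefficient"):
                mu = 0.8 + (shift if (e, f) == ("Effective", "Efficient") else 0.0)
                values.extend(rng.normal(mu, 0.05, n))
                eff.extend([e] * n)
                effi.extend([f] * n)
        return values, eff, effi

    def test_null_simulation_gives_small_effects(self):
        values, eff, effi = self._cells(np.random.default_rng(0))
        out = entropy_group_comparison(values, eff, effi, B=200, seed=0)
        anova = out["anova"]
        effects = anova.drop(index="Residual")
        assert (effects["partial_eta_sq"] < 0.05).all()
        interaction = anova.loc["C(effectiveness):C(efficiency)"]
        assert interaction["PR(>F)"] > 0.01
        # partial eta squared recomputed from the sums of squares directly
        ss_err = anova.loc["Residual", "sum_sq"]
        for name, row in effects.iterrows():
            assert row["partial_eta_sq"] == pytest.approx(
                row["sum_sq"] / (row["sum_sq"] + ss_err)
            )

    def test_shifted_cell_detected(self):
        values, eff, effi = self._cells(np.random.default_rng(0), shift=0.25)
        out = entropy_group_comparison(values, eff, effi, B=200, seed=0)
        assert out["anova"].loc["C(effectiveness)", "PR(>F)"] < 0.001

    def test_bootstrap_reproducible(self):
        values, eff, effi = self._cells(np.random.default_rng(1))
        a = entropy_group_comparison(values, eff, effi, B=2000, seed=0)
        b = entropy_group_comparison(values, eff, effi, B=2000, seed=0)
        assert a["subgroups"].equals(b["subgroups"])

    def test_ci_contains_mean(self):
        values, eff, effi = self._cells(np.random.default_rng(2))
        out = entropy_group_comparison(values, eff, effi, B=500, seed=0)
        for _, row in out["subgroups"].iterrows():
            assert row["ci_low"] <= row["mean"] <= row["ci_high"]

    def test_empty_cell_refuses_anova_but_reports_means(self):
        rng = np.random.default_rng(3)
        values = list(rng.normal(0.8, 0.05, 20))
        out = entropy_group_comparison(
            values, ["Effective"] * 20, ["Efficient"] * 10 + ["Inefficient"] * 10, B=100, seed=0
        )
        assert out["anova"] is None
        assert len(out["subgroups"]) == 2


class TestTransitionEstimation:
    def test_pair_count_conservation(self):
        seqs = [[ST, AG, RT, ET], [ST, IA, ET]]
        counts = count_transitions(seqs)
        assert counts.sum() == (4 - 1) + (3 - 1)

    def test_equal_counts_give_half(self):
        seqs = [[AG, RT, AG, AD, AG, RT, AG, AD]]
        est = estimate_transitions(seqs)
        i = SOURCES.index(AG)
        assert est.probs[i, TARGETS.index(RT)] == pytest.approx(0.5)
        assert est.probs[i, TARGETS.index(AD)] == pytest.approx(0.5)

    def test_defined_rows_sum_to_one(self, demo_coded):
        coded, _ = demo_coded
        est = estimate_transitions([s.micro for s in coded])
        for i in range(len(SOURCES)):
            if not np.all(np.isnan(est.probs[i])):
                assert est.probs[i].sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_count_row_with_prior_returns_prior(self):
        prior_probs = np.full((len(SOURCES), len(TARGETS)), np.nan)
        i = SOURCES.index(RR)
        prior_probs[i] = 0.0
        prior_probs[i, TARGETS.index(RT)] = 0.8
        prior_probs[i, TARGETS.index(AG)] = 0.2
        prior = TransitionMatrix(counts=np.zeros((7, 7)), probs=prior_probs)
        est = estimate_transitions([[ST, AG, ET]], prior=prior, alpha=0.5)
        np.testing.assert_allclose(est.probs[i], prior_probs[i])

    def test_hand_computed_posterior_mean(self):
        """counts (1, 0), prior (0.8, 0.2), alpha 0.5 -> (1.4, 0.1)/1.5."""
        prior_probs = np.full((len(SOURCES), len(TARGETS)), np.nan)
        i = SOURCES.index(AG)
        prior_probs[i] = 0.0
        prior_probs[i, TARGETS.index(RT)] = 0.8
        prior_probs[i, TARGETS.index(AD)] = 0.2
        prior = TransitionMatrix(counts=np.zeros((7, 7)), probs=prior_probs)
        est = estimate_transitions([[AG, RT]], prior=prior, alpha=0.5)
        assert est.probs[i, TARGETS.index(RT)] == pytest.approx(1.4 / 1.5)
        assert est.probs[i, TARGETS.index(AD)] == pytest.approx(0.1 / 1.5)

    def test_alpha_limits(self, demo_coded):
        coded, _ = demo_coded
        seqs = [s.micro for s in coded]
        prior = estimate_transitions(seqs)
        sub = seqs[:10]
        mle = estimate_transitions(sub)
        tiny = estimate_transitions(sub, prior=prior, alpha=1e-9)
        huge = estimate_transitions(sub, prior=prior, alpha=1e9)
        defined = ~np.isnan(mle.probs)
        np.testing.assert_allclose(tiny.probs[defined], mle.probs[defined], atol=1e-9)
        defined_prior = ~np.isnan(prior.probs)
        np.testing.assert_allclose(huge.probs[defined_prior], prior.probs[defined_prior], atol=1e-6)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            estimate_transitions([[ST, ET]], alpha=-0.1)

    def test_smoothing_beats_mle_at_small_n_when_prior_true(self):
        """Shrinkage toward the true matrix lowers error for n=10 vs n=500."""
        truth = _matrix(
            {
                "ST": {"IA": 1.0},
                "IA": {"AG": 0.5, "RT": 0.5},
                "AG": {"RT": 1.0},
                "RT": {"AG": 0.3, "RA": 0.5, "RT": 0.2},
                "RA": {"ET": 0.6, "RT": 0.4},
            }
        )
        truth_arr = np.zeros((7, 7))
        for src, row in truth.items():
            for tgt, p in row.items():
                truth_arr[SOURCES.index(src), TARGETS.index(tgt)] = p
        prior_probs = np.where(truth_arr.sum(axis=1, keepdims=True) > 0, truth_arr, np.nan)
        prior = TransitionMatrix(counts=np.zeros((7, 7)), probs=prior_probs)
        rng = np.random.default_rng(0)
        errors = {}
        for n in (10, 500):
            seqs = [sample_chain(truth, rng) for _ in range(n)]
            mle = estimate_transitions(seqs)
            smoothed = estimate_transitions(seqs, prior=prior, alpha=0.5)
            defined = ~np.isnan(prior_probs)
            errors[n] = (
                np.nanmean(np.abs(mle.probs - truth_arr)[defined]),
                np.nanmean(np.abs(smoothed.probs - truth_arr)[defined]),
            )
        assert errors[10][1] < errors[10][0]          # shrinkage helps at n=10
        assert errors[500][0] < errors[10][0]         # MLE converges with n
        assert errors[500][1] < errors[10][1]


class TestBootstrapDeltas:
    def test_identical_subgroups_silent(self, demo_coded):
        coded, _ = demo_coded
        seqs = [s.micro for s in coded[:20]]
        prior = estimate_transitions(seqs)
        delta, _, _ = bootstrap_deltas(seqs, seqs, prior=prior, B=200, seed=0)
        defined = ~np.isnan(delta.delta)
        np.testing.assert_allclose(delta.delta[defined], 0.0, atol=1e-12)
        assert not delta.significant.any()

    def test_reproducible_with_seed(self, demo_coded):
        coded, _ = demo_coded
        seqs_a = [s.micro for s in coded[:15]]
        seqs_b = [s.micro for s in coded[15:30]]
        prior = estimate_transitions(seqs_a + seqs_b)
        d1, m1, _ = bootstrap_deltas(seqs_a, seqs_b, prior=prior, B=150, seed=0)
        d2, m2, _ = bootstrap_deltas(seqs_a, seqs_b, prior=prior, B=150, seed=0)
        np.testing.assert_array_equal(d1.ci_low, d2.ci_low)
        np.testing.assert_array_equal(m1.ci_low, m2.ci_low)

    def test_singleton_subgroup_refused(self):
        seqs = [[ST, IA, ET]]
        prior = estimate_transitions(seqs)
        with pytest.raises(ValueError):
            bootstrap_deltas(seqs, seqs * 3, prior=prior, B=10, seed=0)

    def test_significance_flag_consistent_with_ci(self, demo_coded):
        coded, _ = demo_coded
        seqs_a = [s.micro for s in coded[:20]]
        seqs_b = [s.micro for s in coded[20:40]]
        prior = estimate_transitions(seqs_a + seqs_b)
        delta, _, _ = bootstrap_deltas(seqs_a, seqs_b, prior=prior, B=200, seed=0)
        flagged = (delta.ci_low > 0) | (delta.ci_high < 0)
        defined = ~np.isnan(delta.delta)
        np.testing.assert_array_equal(delta.significant[defined], flagged[defined])
        assert np.all(np.abs(delta.delta[defined]) <= 1.0)


class TestProcessGraph:
    def _matrix_from_rows(self, rows):
        probs = np.full((len(SOURCES), len(TARGETS)), np.nan)
        for src, row in rows.items():
            probs[SOURCES.index(src)] = 0.0
            for tgt, p in row.items():
                probs[SOURCES.index(src), TARGETS.index(tgt)] = p
        return TransitionMatrix(counts=np.zeros((7, 7)), probs=probs)

    def test_threshold_semantics(self):
        mat = self._matrix_from_rows({RT: {AG: 0.35, AD: 0.29, RA: 0.36}})
        graph = build_process_graph(mat, threshold=0.30)
        assert set(graph.edges) == {
            (RT.value, AG.value),
            (RT.value, RA.value),
        }

    def test_threshold_one_keeps_only_certain_edges(self):
        mat = self._matrix_from_rows({ST: {IA: 1.0}, RT: {AG: 0.5, AD: 0.5}})
        graph = build_process_graph(mat, threshold=1.0)
        assert set(graph.edges) == {(ST.value, IA.value)}

    def test_invalid_threshold_rejected(self):
        mat = self._matrix_from_rows({ST: {IA: 1.0}})
        with pytest.raises(ValueError):
            build_process_graph(mat, threshold=0.0)
        with pytest.raises(ValueError):
            build_process_graph(mat, threshold=1.5)

    def test_dot_and_json_round_trip_same_edge_set(self, demo_coded):
        coded, _ = demo_coded
        est = estimate_transitions([s.micro for s in coded])
        graph = build_process_graph(est, threshold=0.30)
        via_dot = graph_from_dot(graph_to_dot(graph))
        via_json = graph_from_json(json.loads(json.dumps(graph_to_json(graph))))
        assert set(via_dot.edges) == set(graph.edges) == set(via_json.edges)
        for s, t in graph.edges:
            assert via_dot[s][t]["weight"] == pytest.approx(graph[s][t]["weight"])
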
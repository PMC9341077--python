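"""Rule extraction, pruning, rendering and crisp coverage."""

import re

import numpy as np
import pytest

from tfnn import network as net
from tfnn import rules as rl
from tfnn import synthetic as syn


def state_with(A, M, W, seed=0):
    """Build a state whose constrained A, M, W equal the given targets."""
    H, D, K = A.shape
    C = W.shape[1]
    s = net.init_model(H, D, K, C, seed=seed)
    s.raw_attention = np.arctanh(np.clip(A, 0, 1 - 1e-12))
    s.raw_connection = np.arctanh(np.clip(M, 0, 1 - 1e-12))
    s.raw_inference = np.log(np.expm1(np.maximum(W, 1e-9)))
    return s


class TestContributionTensor:
    def test_elementwise_product(self):
        A = np.zeros((2, 3, 1))
        A[0, 1, 0] = 0.8
        M = np.zeros((2, 1))
        M[0, 0] = 0.5
        s = state_with(A, M, np.ones((1, 2)))
        S = rl.contribution_tensor(s)
        assert S[0, 1, 0] == pytest.approx(0.4, abs=1e-9)

    def test_zero_connection_annihilates_row(self, rng):
        A = rng.uniform(0, 0.9, (3, 3, 2))
        M = rng.uniform(0.1, 0.9, (3, 2))
        M[1, :] = 0.0
        s = state_with(A, M, np.ones((2, 2)))
        assert np.allclose(rl.contribution_tensor(s)[1], 0.0)

    def test_matches_triple_loop(self, rng):
        s = net.init_model(4, 3, 5, 2, seed=9)
        S = rl.contribution_tensor(s)
        w = net.constrain_weights(s)
        for i in range(4):
            for d in range(3):
                for k in range(5):
                    assert S[i, d, k] == pytest.approx(
                        w["A"][i, d, k] * w["M"][i, k], abs=1e-12)


def two_rule_state():
    """Rule 0: x0 high & x1 low (W=2); rule 1: x2 medium (W=1)."""
    A = np.zeros((3, 3, 2))
    M = np.zeros((3, 2))
    A[0, 2, 0] = 0.9
    A[1, 0, 0] = 0.8
    M[0, 0] = 0.9
    M[1, 0] = 0.9
    A[2, 1, 1] = 0.9
    M[2, 1] = 0.9
    W = np.array([[0.1, 2.0], [0.1, 1.0]])
    return state_with(A, M, W)


class TestExtractRules:
    def test_two_planted_weight_patterns_recovered(self):
        report = rl.extract_rules(two_rule_state(), target_class=1)
        assert [r.index for r in report.rules] == [0, 1]
        assert report.rules[0].concept_set() == {(0, "high"), (1, "low")}
        assert report.rules[1].concept_set() == {(2, "medium")}
        assert report.rules[0].importance > report.rules[1].importance

    def test_duplicate_rules_pruned_by_correlation(self):
        A = np.zeros((2, 3, 2))
        M = np.zeros((2, 2))
        for k in range(2):
            A[0, 2, k] = 0.9
            M[0, k] = 0.9
        W = np.array([[0.0, 1.0], [0.0, 3.0]])
        report = rl.extract_rules(state_with(A, M, W), target_class=1)
        assert len(report.rules) == 1
        assert report.rules[0].index == 1  # the higher-importance copy

    def test_low_contribution_concepts_dropped(self):
        A = np.zeros((2, 3, 1))
        A[0, 2, 0] = 0.9
        A[1, 0, 0] = 0.05  # below theta_concept * max
        M = np.full((2, 1), 0.9)
        report = rl.extract_rules(state_with(A, M, np.ones((1, 2))))
        assert report.rules[0].concept_set() == {(0, "high")}

    def test_medium_high_merge_to_not_low(self):
        A = np.zeros((1, 3, 1))
        A[0, 1, 0] = 0.85
        A[0, 2, 0] = 0.9
        M = np.full((1, 1), 0.9)
        report = rl.extract_rules(state_with(A, M, np.ones((1, 2))))
        (concept,) = report.rules[0].concepts
        assert concept.concept == "not low"
        assert concept.threshold.comparator == ">"

    def test_pruning_monotonicity(self, trained_fixture_model):
        counts = []
        for theta in (0.05, 0.2, 0.5):
            rep = rl.extract_rules(trained_fixture_model, target_class=1,
                                   prune=rl.PruneConfig(theta_concept=theta),
                                   attach_thresholds=False)
            counts.append({r.index: len(r.concepts) for r in rep.rules})
        for loose, tight in zip(counts, counts[1:]):
            for k, n in tight.items():
                assert n <= loose[k]
        n_rules = [
            len(rl.extract_rules(trained_fixture_model, target_class=1,
                                 prune=rl.PruneConfig(theta_corr=t),
                                 attach_thresholds=False).rules)
            for t in (0.5, 0.9, 1.01)
        ]
        assert n_rules == sorted(n_rules)

    def test_nonfinite_state_rejected(self, small_state):
        small_state.raw_attention[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            rl.extract_rules(small_state)


class TestRender:
    def test_format_and_roundtrip(self):
        report = rl.extract_rules(two_rule_state(), target_class=1)
        names = ["ivh", "eye_opening", "compression"]
        text = rl.render_rule(report.rules[0], names)
        assert text.startswith("IF ")
        # parse back feature/concept/comparator
        m = re.findall(r"(\w+) (low|medium|high|not low|not high) \(([<>])", text)
        parsed = {(names.index(f), c) for f, c, _ in m}
        assert parsed == {(0, "high"), (1, "low")}
        directions = {f: d for f, c, d in m}
        assert directions["ivh"] == ">" and directions["eye_opening"] == "<"

    def test_concept_order_by_contribution_then_feature(self):
        c1 = rl.RuleConcept(2, "high", 0.5)
        c2 = rl.RuleConcept(0, "low", 0.5)
        c3 = rl.RuleConcept(1, "high", 0.9)
        rule = rl.Rule(0, 1, 1.0, sorted([c1, c2, c3],
                                         key=lambda c: (-c.contribution, c.feature)))
        assert [c.feature for c in rule.concepts] == [1, 0, 2]

    def test_empty_rule_rejected(self):
        with pytest.raises(ValueError):
            rl.render_rule(rl.Rule(0, 1, 1.0, []), ["a"])

    def test_unknown_feature_rejected(self):
        rule = rl.Rule(0, 1, 1.0, [rl.RuleConcept(5, "high", 0.5)])
        with pytest.raises(IndexError):
            rl.render_rule(rule, ["a", "b"])


class TestCoverage:
    def test_saturated_rule_covers_everything(self):
        rule = rl.Rule(0, 1, 1.0, [rl.RuleConcept(0, "high", 0.9,
                                                  rl.fc.ThresholdSpec(">", (10.0,)))])
        X = np.full((7, 1), 50.0)
        n, per = rl.rule_coverage(rule, X, np.array([1, 1, 0, 0, 0, 1, 1]))
        assert n == 7
        assert per == {0: 3, 1: 4}

    def test_contradictory_rule_covers_nothing(self):
        rule = rl.Rule(0, 1, 1.0, [
            rl.RuleConcept(0, "low", 0.9, rl.fc.ThresholdSpec("<", (2.0,))),
            rl.RuleConcept(0, "high", 0.9, rl.fc.ThresholdSpec(">", (8.0,))),
        ])
        # conjunction on the same feature with disjoint cuts
        rule2 = rl.Rule(0, 1, 1.0, list(reversed(rule.concepts)))
        X = np.linspace(0, 10, 50)[:, None]
        assert rl.rule_coverage(rule, X)[0] == 0
        assert rl.rule_coverage(rule2, X)[0] == 0

    def test_counts_match_independent_crisp_evaluation(self, default_cohort):
        c = default_cohort
        spec = c.spec
        # express planted rule 2 (lab_value high & severity high) as a Rule
        lab = spec.marginals[2]
        sev = spec.marginals[3]
        rule = rl.Rule(0, 1, 1.0, [
            rl.RuleConcept(2, "high", 0.9,
                           rl.fc.ThresholdSpec(">", (lab.offset + lab.scale * 0.4,))),
            rl.RuleConcept(3, "high", 0.9,
                           rl.fc.ThresholdSpec(">", (sev.offset + sev.scale * 0.5,))),
        ])
        n, per = rl.rule_coverage(rule, c.X, c.y)
        expected = spec.rules[1].satisfied(c.Z)
        assert n == int(expected.sum())
        assert per[0] + per[1] == n
        assert per[1] == int((expected & (c.y == 1)).sum())

    def test_missing_threshold_rejected(self):
        rule = rl.Rule(0, 1, 1.0, [rl.RuleConcept(0, "high", 0.9, None)])
        with pytest.raises(ValueError):
            rl.rule_coverage(rule, np.ones((3, 1)))


class TestJaccard:
    def test_not_low_counts_as_above_cut(self):
        extracted = [(2, "not low"), (3, "not low")]
        planted = [(2, "high"), (3, "high")]
        assert rl.rule_jaccard(extracted, planted) == 1.0

    def test_partial_overlap(self):
        assert rl.rule_jaccard([(0, "high"), (1, "low")],
                               [(0, "high"), (2, "low")]) == pytest.approx(1 / 3)

    def test_planted_rule_recovery_on_trained_model(self, trained_fixture_model,
                                                    default_cohort):
        report = rl.extract_rules(trained_fixture_model, target_class=1)
        planted = [
            [(f, c) for f, c, _ in rule.clauses]
            for rule in default_cohort.spec.rules
        ]
        top2 = report.rules[:2]
        best = [max(rl.rule_jaccard(r, p) for r in top2) for p in planted]
        assert min(best) >= 0.8


def test_report_serialization(tmp_path):
    report = rl.extract_rules(two_rule_state(), target_class=1)
    d = rl.report_to_dict(report)
    assert d["rules"][0]["concepts"][0]["threshold"]["comparator"] in "<>"
    rl.save_report(report, tmp_path / "r.json")
    text = rl.report_to_text(report)
    assert "IF" in text and "THEN class 1" in text
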
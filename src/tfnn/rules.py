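"""Turning trained weights into human-readable IF-THEN rules.

The k-th rule is fully captured by the contribution slice
``S_{:,:,k} = A_{:,:,k} * M_{:,k}`` (how much each feature/concept feeds the
rule) together with its class importances ``W_{k,:}``.  Extraction:

1. rank rules for the target class by ``W_{k,target}``;
2. drop concepts whose contribution falls below a threshold relative to
   the rule's strongest concept;
3. among near-duplicate rules (cosine similarity of flattened slices above
   a threshold) keep the more important one;
4. merge adjacent surviving concepts on one feature into union concepts —
   medium+high becomes "not low", low+medium becomes "not high";
5. attach the learned 0.5-crossing thresholds in original feature units.

Coverage verification is crisp: a subject satisfies a rule iff every
retained concept's threshold condition holds (strict inequalities), which
mirrors how extracted rules are audited against a cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fuzzy_core as fc
from .network import ModelState, constrain_weights

__all__ = ["PruneConfig", "RuleConcept", "Rule", "RuleReport",
           "contribution_tensor", "extract_rules", "render_rule",
           "rule_coverage", "rule_jaccard", "rule_region_set",
           "report_to_text", "report_to_dict"]


@dataclass
class PruneConfig:
    theta_concept: float = 0.2   # relative to the rule's max contribution
    theta_corr: float = 0.9      # cosine similarity between rule slices
    max_rules: int | None = None


@dataclass(frozen=True)
class RuleConcept:
    feature: int
    concept: str                 # 'low', 'medium', 'high', 'not low', 'not high', ...
    contribution: float
    threshold: fc.ThresholdSpec | None = None


@dataclass
class Rule:
    index: int
    target_class: int
    importance: float
    concepts: list[RuleConcept] = field(default_factory=list)

    def concept_set(self) -> set[tuple[int, str]]:
        return {(c.feature, c.concept) for c in self.concepts}


@dataclass
class RuleReport:
    rules: list[Rule]
    prune_config: PruneConfig
    target_class: int
    feature_names: list[str]
    coverage: list[dict] = field(default_factory=list)


def contribution_tensor(state: ModelState) -> np.ndarray:
    """S_{i,d,k} = A_{i,d,k} * M_{i,k} (exact elementwise product)."""
    w = constrain_weights(state)
    return w["A"] * w["M"][:, None, :]


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def _union_label(labels: list[str], d_pair: tuple[int, int], D: int) -> str | None:
    """Union name for two adjacent concepts covering all but one shoulder."""
    if D != 3:
        return None
    if d_pair == (1, 2):
        return "not low"
    if d_pair == (0, 1):
        return "not high"
    return None


def extract_rules(state: ModelState, target_class: int = 1,
                  prune: PruneConfig | None = None,
                  attach_thresholds: bool = True) -> RuleReport:
    """Extract the pruned, ordered rule list for one class."""
    prune = prune or PruneConfig()
    S = contribution_tensor(state)
    if not np.isfinite(S).all():
        raise ValueError("cannot extract rules from non-finite weights")
    w = constrain_weights(state)
    W = w["W"][:, target_class]
    D = state.n_concepts
    labels = fc.concept_labels(D)
    order = np.argsort(-W, kind="stable")
    if prune.max_rules is not None:
        order = order[: prune.max_rules]
    # correlation pruning: keep the higher-importance rule of any
    # near-duplicate pair (order is importance-descending)
    kept: list[int] = []
    for k in order:
        if all(_cosine(S[:, :, k].ravel(), S[:, :, j].ravel()) <= prune.theta_corr
               for j in kept):
            kept.append(int(k))
    params = state.membership_params()
    rules = []
    for k in kept:
        slice_k = S[:, :, k]
        cutoff = prune.theta_concept * slice_k.max()
        concepts: list[RuleConcept] = []
        for i in range(state.n_features):
            ds = [d for d in range(D) if slice_k[i, d] >= cutoff and slice_k[i, d] > 0]
            merged = None
            if len(ds) == 2:
                merged = _union_label(labels, (ds[0], ds[1]), D)
            if merged is not None:
                contrib = float(slice_k[i, ds].max())
                # union of medium+high is bounded below by the shoulder it
                # excludes: report the complement cut of that shoulder
                excluded = 0 if merged == "not low" else D - 1
                thr = _complement_threshold(params, i, excluded, state) \
                    if attach_thresholds else None
                concepts.append(RuleConcept(i, merged, contrib, thr))
            else:
                for d in ds:
                    thr = concept_threshold_for(state, params, i, d) \
                        if attach_thresholds else None
                    concepts.append(RuleConcept(i, labels[d], float(slice_k[i, d]), thr))
        concepts.sort(key=lambda c: (-c.contribution, c.feature))
        rules.append(Rule(index=k, target_class=target_class,
                          importance=float(W[k]), concepts=concepts))
    return RuleReport(rules=rules, prune_config=prune, target_class=target_class,
                      feature_names=state.feature_names)


def concept_threshold_for(state: ModelState, params: fc.MembershipParams,
                          feature: int, concept: int) -> fc.ThresholdSpec:
    stats = (float(state.feature_min[feature]), float(state.feature_max[feature]))
    return fc.concept_threshold(params, feature, concept, stats=stats)


def _complement_threshold(params: fc.MembershipParams, feature: int,
                          excluded_concept: int, state: ModelState) -> fc.ThresholdSpec:
    shoulder = concept_threshold_for(state, params, feature, excluded_concept)
    flipped = ">" if shoulder.comparator == "<" else "<"
    return fc.ThresholdSpec(flipped, shoulder.values)


REGION_OF_CONCEPT = {
    "low": "below-cut", "not high": "below-cut",
    "high": "above-cut", "not low": "above-cut",
    "medium": "interval",
    "very low": "below-cut", "very high": "above-cut",
}


def rule_region_set(concepts) -> set[tuple[int, str]]:
    """Map a rule's concepts to (feature, crisp-region-type) pairs.

    'high' and 'not low' both denote a one-sided region above a learned
    cut (dually 'low' and 'not high'), so recovery of a planted one-sided
    condition is judged by the region type, not the surface label.
    """
    out = set()
    for c in concepts:
        feature, label = (c.feature, c.concept) if isinstance(c, RuleConcept) else c
        out.add((feature, REGION_OF_CONCEPT.get(label, label)))
    return out


def rule_jaccard(rule_a, rule_b) -> float:
    """Jaccard overlap of the crisp-region concept sets of two rules.

    Arguments may be :class:`Rule` objects or iterables of
    (feature, concept-label) pairs (e.g. planted-rule clauses).
    """
    sa = rule_region_set(rule_a.concepts if isinstance(rule_a, Rule) else rule_a)
    sb = rule_region_set(rule_b.concepts if isinstance(rule_b, Rule) else rule_b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def render_rule(rule: Rule, feature_names: list[str]) -> str:
    """Paper-style listing: IF f1 high (>0.59) AND f2 low (<1.6) THEN ..."""
    if not rule.concepts:
        raise ValueError("cannot render a rule with no concepts")
    parts = []
    for c in rule.concepts:
        if c.feature >= len(feature_names):
            raise IndexError(f"unknown feature index {c.feature}")
        text = f"{feature_names[c.feature]} {c.concept}"
        if c.threshold is not None:
            text += f" ({c.threshold.describe()})"
        parts.append(text)
    return (f"IF {' AND '.join(parts)} THEN class {rule.target_class} "
            f"(importance {rule.importance:.3f})")


def rule_satisfied(rule: Rule, X_orig: np.ndarray) -> np.ndarray:
    """Boolean crisp satisfaction per row of an (n,H) original-unit matrix."""
    X_orig = np.atleast_2d(np.asarray(X_orig, dtype=float))
    mask = np.ones(X_orig.shape[0], dtype=bool)
    for c in rule.concepts:
        if c.threshold is None:
            raise ValueError("rule has concepts without attached thresholds")
        if c.feature >= X_orig.shape[1]:
            raise KeyError(f"dataset lacks feature column {c.feature}")
        mask &= c.threshold.satisfied(X_orig[:, c.feature])
    return mask


def rule_coverage(rule: Rule, X_orig, y=None) -> tuple[int, dict[int, int]]:
    """Count subjects satisfying a rule, overall and per class."""
    mask = rule_satisfied(rule, X_orig)
    per_class: dict[int, int] = {}
    if y is not None:
        y = np.asarray(y, dtype=int)
        for cls in np.unique(y):
            per_class[int(cls)] = int((mask & (y == cls)).sum())
    return int(mask.sum()), per_class


def attach_coverage(report: RuleReport, X_orig, y=None) -> RuleReport:
    report.coverage = []
    for rule in report.rules:
        n_sat, per_class = rule_coverage(rule, X_orig, y)
        report.coverage.append({"rule_index": rule.index, "n_satisfying": n_sat,
                                "per_class": per_class})
    return report


def report_to_text(report: RuleReport) -> str:
    lines = []
    for pos, rule in enumerate(report.rules, start=1):
        lines.append(f"Rule {pos}: {render_rule(rule, report.feature_names)}")
    for cov in report.coverage:
        per = ", ".join(f"class {c}: {n}" for c, n in sorted(cov["per_class"].items()))
        lines.append(f"Coverage of rule k={cov['rule_index']}: "
                     f"{cov['n_satisfying']} subjects ({per})")
    return "\n".join(lines)


def report_to_dict(report: RuleReport) -> dict:
    return {
        "target_class": report.target_class,
        "prune": {"theta_concept": report.prune_config.theta_concept,
                  "theta_corr": report.prune_config.theta_corr,
                  "max_rules": report.prune_config.max_rules},
        "rules": [
            {
                "index": r.index,
                "importance": r.importance,
                "concepts": [
                    {
                        "feature": c.feature,
                        "feature_name": report.feature_names[c.feature],
                        "concept": c.concept,
                        "contribution": c.contribution,
                        "threshold": None if c.threshold is None else
                        {"comparator": c.threshold.comparator,
                         "values": list(c.threshold.values)},
                    }
                    for c in r.concepts
                ],
            }
            for r in report.rules
        ],
        "coverage": report.coverage,
    }


def save_report(report: RuleReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report_to_dict(report), indent=2))
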
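"""Synthetic tabular cohorts with planted conjunctive rules.

The generator emulates the structure of an admission-time clinical table:
mixed-scale non-negative features (ages, ordinal scores, counts, lab
values), a binary outcome driven by a small set of crisp conjunctive rules
over "low/medium/high" feature regions, symmetric label-flip noise, and
label-independent distractor columns.  Because the generating rules are
known, both discrimination and rule recovery can be tested without any
external data.

Conventions: rules are evaluated on the normalized [0,1] scale with strict
inequalities (a row exactly at a threshold does not satisfy it — a
measure-zero event for continuous marginals); the noiseless label is the
disjunction of the planted rules; the observed label flips with
probability ``noise_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["Marginal", "PlantedRule", "PlantedRuleSpec", "SyntheticCohort",
           "generate", "crisp_rule_eval", "default_fixture_spec",
           "write_cohort", "read_cohort"]

DEFAULT_FIXTURE_SEED = 20220801


@dataclass(frozen=True)
class Marginal:
    """Per-feature marginal family with an affine map to original units.

    family 'uniform' -> U(0,1); 'beta' -> Beta(a,b); 'count' -> uniform
    integers 0..levels scaled to [0,1].  Original units are
    ``offset + scale * z`` with z the normalized draw.
    """

    family: str = "uniform"
    a: float = 2.0
    b: float = 2.0
    levels: int = 10
    scale: float = 1.0
    offset: float = 0.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "uniform":
            return rng.uniform(0.0, 1.0, n)
        if self.family == "beta":
            return rng.beta(self.a, self.b, n)
        if self.family == "count":
            return rng.integers(0, self.levels + 1, n) / self.levels
        raise ValueError(f"unknown marginal family '{self.family}'")

    def to_original(self, z: np.ndarray) -> np.ndarray:
        return self.offset + self.scale * np.asarray(z, dtype=float)


@dataclass(frozen=True)
class PlantedRule:
    """Conjunction of (feature, concept, threshold-on-[0,1]) clauses.

    'low' means x < t, 'high' means x > t, 'medium' means t[0] < x < t[1].
    """

    clauses: tuple[tuple[int, str, float | tuple[float, float]], ...]
    weight: float = 1.0

    def __post_init__(self):
        feats = [c[0] for c in self.clauses]
        if len(set(feats)) != len(feats):
            raise ValueError("feature indices must be distinct within a rule")
        for _, concept, t in self.clauses:
            if concept not in ("low", "medium", "high"):
                raise ValueError(f"unknown concept '{concept}'")
            ts = t if isinstance(t, tuple) else (t,)
            if not all(0.0 < v < 1.0 for v in ts):
                raise ValueError("thresholds must lie strictly inside (0, 1)")

    def satisfied(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(Z)
        mask = np.ones(Z.shape[0], dtype=bool)
        for feat, concept, t in self.clauses:
            x = Z[:, feat]
            if concept == "low":
                mask &= x < t
            elif concept == "high":
                mask &= x > t
            else:
                lo, hi = t
                mask &= (x > lo) & (x < hi)
        return mask


@dataclass
class PlantedRuleSpec:
    rules: list[PlantedRule]
    n: int = 2000
    noise_rate: float = 0.1
    marginals: list[Marginal] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    seed: int = DEFAULT_FIXTURE_SEED

    def __post_init__(self):
        if not (0.0 <= self.noise_rate < 0.5):
            raise ValueError("label-noise rate must lie in [0, 0.5)")
        if not self.marginals:
            raise ValueError("at least one feature marginal is required")
        H = len(self.marginals)
        for rule in self.rules:
            for feat, _, _ in rule.clauses:
                if feat >= H:
                    raise ValueError(f"rule references feature {feat} but H={H}")
        if not self.feature_names:
            self.feature_names = [f"x{i}" for i in range(H)]

    @property
    def n_features(self) -> int:
        return len(self.marginals)

    def informative_features(self) -> set[int]:
        return {feat for rule in self.rules for feat, _, _ in rule.clauses}


@dataclass
class SyntheticCohort:
    frame: pd.DataFrame          # features in original units + 'outcome'
    y: np.ndarray                # observed labels (with noise)
    y_true: np.ndarray           # noiseless rule labels
    Z: np.ndarray                # normalized [0,1] features
    spec: PlantedRuleSpec

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.spec.feature_names].to_numpy(dtype=float)


def crisp_rule_eval(spec: PlantedRuleSpec, Z) -> np.ndarray:
    """Noiseless labels: disjunction over rules of crisp conjunctions.

    ``Z`` is one row or an (n,H) matrix on the normalized scale.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    label = np.zeros(Z.shape[0], dtype=bool)
    for rule in spec.rules:
        label |= rule.satisfied(Z)
    return label.astype(int)


def generate(spec: PlantedRuleSpec) -> SyntheticCohort:
    """Draw a cohort; deterministic given (spec, spec.seed)."""
    rng = np.random.default_rng(spec.seed)
    H = spec.n_features
    Z = np.column_stack([m.sample(spec.n, rng) for m in spec.marginals])
    y_true = crisp_rule_eval(spec, Z)
    if y_true.all() or not y_true.any():
        raise ValueError("planted rules produce a single-class cohort; "
                         "check that the satisfying region is non-trivial")
    flips = rng.uniform(size=spec.n) < spec.noise_rate
    y = np.where(flips, 1 - y_true, y_true)
    X = np.column_stack([m.to_original(Z[:, j]) for j, m in enumerate(spec.marginals)])
    frame = pd.DataFrame(X, columns=spec.feature_names)
    frame["outcome"] = y
    return SyntheticCohort(frame=frame, y=y, y_true=y_true, Z=Z, spec=spec)


def default_fixture_spec(n: int = 2000, noise_rate: float = 0.1,
                         seed: int = DEFAULT_FIXTURE_SEED) -> PlantedRuleSpec:
    """The default benchmark cohort: 8 mixed-scale features, two planted
    two-concept rules over features 0-3, four distractors, ~50% prevalence
    (balanced classes maximize the noise-limited AUC ceiling)."""
    marginals = [
        Marginal("uniform", scale=72.0, offset=18.0),     # age-like, years
        Marginal("count", levels=10, scale=10.0),         # ordinal score 0-10
        Marginal("beta", a=2.0, b=2.0, scale=13.0, offset=5.0),  # lab value
        Marginal("uniform", scale=4.0),                   # ordinal scale 0-4
        Marginal("beta", a=2.0, b=5.0, scale=6.0),        # skewed count-ish distractor
        Marginal("uniform", scale=100.0),                 # distractor
        Marginal("count", levels=5, scale=5.0),           # distractor
        Marginal("beta", a=5.0, b=2.0, scale=1.0),        # distractor
    ]
    rules = [
        PlantedRule(((0, "high", 0.5), (1, "low", 0.5))),
        PlantedRule(((2, "high", 0.4), (3, "high", 0.5))),
    ]
    names = ["age", "motor_score", "lab_value", "severity_scale",
             "marker_a", "marker_b", "marker_c", "marker_d"]
    return PlantedRuleSpec(rules=rules, n=n, noise_rate=noise_rate,
                           marginals=marginals, feature_names=names, seed=seed)


def write_cohort(cohort: SyntheticCohort, csv_path: str | Path,
                 spec_path: str | Path | None = None) -> None:
    cohort.frame.to_csv(csv_path, index=False)
    if spec_path is not None:
        spec = cohort.spec
        payload = {
            "n": spec.n,
            "noise_rate": spec.noise_rate,
            "seed": spec.seed,
            "feature_names": spec.feature_names,
            "marginals": [vars(m).copy() for m in spec.marginals],
            "rules": [
                {"weight": r.weight,
                 "clauses": [{"feature": f, "concept": c,
                              "threshold": list(t) if isinstance(t, tuple) else t}
                             for f, c, t in r.clauses]}
                for r in spec.rules
            ],
        }
        Path(spec_path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_spec(spec_path: str | Path) -> PlantedRuleSpec:
    payload = yaml.safe_load(Path(spec_path).read_text())
    rules = [
        PlantedRule(tuple(
            (c["feature"], c["concept"],
             tuple(c["threshold"]) if isinstance(c["threshold"], list) else c["threshold"])
            for c in r["clauses"]), weight=r.get("weight", 1.0))
        for r in payload["rules"]
    ]
    marginals = [Marginal(**m) for m in payload["marginals"]]
    return PlantedRuleSpec(rules=rules, n=payload["n"],
                           noise_rate=payload["noise_rate"],
                           marginals=marginals,
                           feature_names=payload.get("feature_names", []),
                           seed=payload["seed"])


def read_cohort(csv_path: str | Path, spec_path: str | Path) -> SyntheticCohort:
    spec = read_spec(spec_path)
    frame = pd.read_csv(csv_path)
    X = frame[spec.feature_names].to_numpy(dtype=float)
    Z = np.column_stack([
        (X[:, j] - m.offset) / m.scale for j, m in enumerate(spec.marginals)
    ])
    y = frame["outcome"].to_numpy(dtype=int)
    return SyntheticCohort(frame=frame, y=y,
                           y_true=crisp_rule_eval(spec, Z), Z=Z, spec=spec)
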
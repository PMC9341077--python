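"""The three-layer fuzzy inference network as one differentiable computation.

Layers
------
1. *Encoding*: each normalized feature is turned into D concept membership
   degrees (see :mod:`tfnn.fuzzy_core`).
2. *Rule module*: an attention tensor ``A`` (feature, concept, rule) unions
   the concept degrees of each feature with the parametrized conorm
   (clamped at 1, so "medium OR high" can express "not low"), then a
   connection matrix ``M`` (feature, rule) conjoins the per-feature
   activations with the parametrized t-norm into rule activations
   ``r_1..r_K``.  A feature with ``M = 0`` contributes the conjunction
   identity 1, i.e. it does not take part in the rule.
3. *Inference*: non-negative weights ``W`` (rule, class) aggregate rule
   activations into class scores ``o_1..o_C`` with the parametrized conorm.

``A`` and ``M`` are constrained to [0,1) through ``|tanh|`` of raw weights;
``W`` through a softplus.  Class probabilities for the loss are the scores
normalized to sum 1 (equivalently a softmax on ``log(o + 1e-12)``), which
keeps the scale of ``W`` interpretable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fuzzy_core as fc
from .autodiff import Tensor, as_tensor

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
PROB_FLOOR = 1e-12

__all__ = ["ModelState", "ForwardTrace", "init_model", "constrain_weights",
           "forward", "normalize", "save_model", "load_model"]


@dataclass
class ModelState:
    """All trainable quantities plus the normalization statistics.

    Raw (unconstrained) parameters are stored; the constrained weights the
    science talks about (A, M, W, breakpoints, eps) are derived views.
    """

    raw_gaps: np.ndarray        # (H, D) positive-gap parametrization of breakpoints
    raw_attention: np.ndarray   # (H, D, K)
    raw_connection: np.ndarray  # (H, K)
    raw_inference: np.ndarray   # (K, C)
    raw_eps: np.ndarray         # (3,) encoding, rule t-norm, inference conorm
    feature_min: np.ndarray     # (H,)
    feature_max: np.ndarray     # (H,)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        H, D, K = self.raw_attention.shape
        if self.raw_gaps.shape != (H, D):
            raise ValueError("raw_gaps shape inconsistent with attention")
        if self.raw_connection.shape != (H, K):
            raise ValueError("raw_connection shape inconsistent with attention")
        if self.raw_inference.shape[0] != K:
            raise ValueError("raw_inference shape inconsistent with attention")
        if not self.feature_names:
            self.feature_names = [f"x{i}" for i in range(H)]

    @property
    def n_features(self) -> int:
        return self.raw_attention.shape[0]

    @property
    def n_concepts(self) -> int:
        return self.raw_attention.shape[1]

    @property
    def n_rules(self) -> int:
        return self.raw_attention.shape[2]

    @property
    def n_classes(self) -> int:
        return self.raw_inference.shape[1]

    def membership_params(self) -> fc.MembershipParams:
        w = constrain_weights(self)
        return fc.MembershipParams(w["breakpoints"], eps=float(w["eps"][0]),
                                   n_concepts=self.n_concepts)

    def parameter_blocks(self) -> dict[str, np.ndarray]:
        return {
            "raw_gaps": self.raw_gaps,
            "raw_attention": self.raw_attention,
            "raw_connection": self.raw_connection,
            "raw_inference": self.raw_inference,
            "raw_eps": self.raw_eps,
        }


@dataclass
class ForwardTrace:
    """All intermediate activations of one forward pass (numpy views)."""

    encoding: np.ndarray            # (n, H, D)
    concept_activation: np.ndarray  # (n, H, K) a_{i,k}
    rule_activation: np.ndarray     # (n, K)    r_k
    class_score: np.ndarray         # (n, C)    o_c
    probabilities: np.ndarray       # (n, C)


def _softplus(x):
    return np.logaddexp(0.0, x)


def _inv_softplus(y):
    y = np.asarray(y, dtype=float)
    return y + np.log1p(-np.exp(-y))


def init_model(H: int, D: int, K: int, C: int, seed: int,
               X_norm: np.ndarray | None = None,
               feature_min: np.ndarray | None = None,
               feature_max: np.ndarray | None = None,
               feature_names: list[str] | None = None) -> ModelState:
    """Reproducibly initialize a model.

    Raw attention/connection weights start small-uniform so the constrained
    weights begin around 0.1-0.5 (no dead rules); breakpoints start at the
    empirical quantiles of ``X_norm`` when provided, else evenly spaced.
    """
    if H < 1 or K < 1 or C < 1 or D < 2:
        raise ValueError(f"invalid architecture sizes H={H}, D={D}, K={K}, C={C}")
    rng = np.random.default_rng(seed)
    if X_norm is not None:
        qs = np.quantile(np.clip(X_norm, 0, 1), np.linspace(0, 1, D + 1)[1:-1], axis=0).T
    else:
        qs = np.tile(np.linspace(0, 1, D + 1)[1:-1], (H, 1))
    qs = np.clip(qs, 0.05, 0.95)
    # enforce a minimal gap so degenerate (e.g. heavily tied) features
    # still start with an ordered partition
    bounded = np.concatenate([np.zeros((H, 1)), qs, np.ones((H, 1))], axis=1)
    gaps = np.maximum(np.diff(bounded, axis=1), 0.05)
    raw_gaps = _inv_softplus(gaps)
    state = ModelState(
        raw_gaps=raw_gaps,
        raw_attention=rng.uniform(0.1, 0.55, size=(H, D, K)),
        raw_connection=rng.uniform(0.1, 0.55, size=(H, K)),
        raw_inference=rng.uniform(-0.8, 0.2, size=(K, C)),
        raw_eps=np.zeros(3),
        feature_min=np.zeros(H) if feature_min is None else np.asarray(feature_min, float),
        feature_max=np.ones(H) if feature_max is None else np.asarray(feature_max, float),
        feature_names=list(feature_names) if feature_names else [],
    )
    return state


def _constrain_graph(params: dict[str, Tensor]) -> dict[str, Tensor]:
    """Constrained weights as autodiff graph nodes."""
    A = params["raw_attention"].tanh().abs()
    M = params["raw_connection"].tanh().abs()
    W = params["raw_inference"].softplus()
    gaps = params["raw_gaps"].softplus()
    cum = gaps.cumsum(axis=1)
    H, D = gaps.shape
    total = cum[:, D - 1:D]
    breakpoints = cum[:, 0:D - 1] / total
    eps_enc = fc.eps_from_raw(params["raw_eps"][0:1]).reshape(())
    eps_rule = fc.eps_from_raw(params["raw_eps"][1:2]).reshape(())
    eps_inf = fc.eps_from_raw(params["raw_eps"][2:3]).reshape(())
    return {"A": A, "M": M, "W": W, "breakpoints": breakpoints,
            "eps_enc": eps_enc, "eps_rule": eps_rule, "eps_inf": eps_inf}


def constrain_weights(state: ModelState) -> dict[str, np.ndarray]:
    """Numpy view of the constrained weights of a state."""
    params = {k: as_tensor(v) for k, v in state.parameter_blocks().items()}
    g = _constrain_graph(params)
    out = {k: (v.data.copy() if isinstance(v, Tensor) else v) for k, v in g.items()}
    out["eps"] = np.array([out.pop("eps_enc"), out.pop("eps_rule"), out.pop("eps_inf")])
    return out


def forward_graph(X: np.ndarray, params: dict[str, Tensor]) -> dict[str, Tensor]:
    """Differentiable forward pass; X is an (n,H) normalized constant."""
    w = _constrain_graph(params)
    n, H = X.shape
    mu = fc._memberships_graph(as_tensor(X), w["breakpoints"], w["eps_enc"])  # (n,H,D)
    D = mu.shape[2]
    K = w["A"].shape[2]
    # concept union within each feature: conorm over d of A[i,d,k]*mu[n,i,d]
    mu_e = mu.reshape(n, H, D, 1)
    A_e = w["A"].reshape(1, H, D, K)
    a = fc.conorm(mu_e, A_e, w["eps_enc"], axis=2).clamp_max(1.0)   # (n,H,K)
    # rule conjunction over features
    r = fc.tnorm(a, w["M"].reshape(1, H, K), w["eps_rule"], axis=1)  # (n,K)
    # class aggregation over rules
    r_e = r.reshape(n, K, 1)
    W_e = w["W"].reshape(1, K, w["W"].shape[1])
    o = fc.conorm(r_e, W_e, w["eps_inf"], axis=1)                    # (n,C)
    shifted = o + PROB_FLOOR
    probs = shifted / shifted.sum(axis=1, keepdims=True)
    return {"mu": mu, "a": a, "r": r, "o": o, "probs": probs, **w}


def forward(X_norm: np.ndarray, state: ModelState) -> ForwardTrace:
    """Run the network on an (n,H) normalized batch and return all traces."""
    X_norm = np.atleast_2d(np.asarray(X_norm, dtype=float))
    if X_norm.shape[1] != state.n_features:
        raise ValueError(
            f"encoding layer: expected {state.n_features} features, got {X_norm.shape[1]}"
        )
    params = {k: as_tensor(v) for k, v in state.parameter_blocks().items()}
    g = forward_graph(X_norm, params)
    for name in ("mu", "a", "r", "o"):
        if not np.isfinite(g[name].data).all():
            raise FloatingPointError(f"non-finite activations in layer '{name}'")
    return ForwardTrace(
        encoding=g["mu"].data,
        concept_activation=g["a"].data,
        rule_activation=g["r"].data,
        class_score=g["o"].data,
        probabilities=g["probs"].data,
    )


def normalize(X, state: ModelState, clip: bool = True) -> np.ndarray:
    """Min-max normalize with the state's stored (training-fold) statistics."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    span = np.where(state.feature_max > state.feature_min,
                    state.feature_max - state.feature_min, 1.0)
    Z = (X - state.feature_min) / span
    if clip:
        out_of_range = ((Z < 0) | (Z > 1)).mean()
        if out_of_range > 0:
            logger.debug("normalize: clamped %.2f%% of cells into [0,1]", 100 * out_of_range)
        Z = np.clip(Z, 0.0, 1.0)
    return Z


def predict_proba(X_orig, state: ModelState) -> np.ndarray:
    """Class probabilities for data in original units."""
    return forward(normalize(X_orig, state), state).probabilities


def membership_curve_samples(state: ModelState, feature: int,
                             n_points: int = 201):
    """Sample the learned membership curves of one feature for plotting.

    Returns a DataFrame with the feature value in original units and one
    column per concept label.
    """
    import pandas as pd

    from . import fuzzy_core as fc_mod

    params = state.membership_params()
    grid = np.linspace(0.0, 1.0, n_points)
    X = np.zeros((n_points, state.n_features))
    X[:, feature] = grid
    mu = fc_mod.membership_encode(X, params)[:, feature, :]
    lo, hi = state.feature_min[feature], state.feature_max[feature]
    frame = pd.DataFrame({state.feature_names[feature]: lo + grid * (hi - lo)})
    for d, label in enumerate(fc_mod.concept_labels(state.n_concepts)):
        frame[label] = mu[:, d]
    return frame


def save_model(state: ModelState, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "shapes": {"H": state.n_features, "D": state.n_concepts,
                   "K": state.n_rules, "C": state.n_classes},
        "feature_names": state.feature_names,
        "feature_min": state.feature_min.tolist(),
        "feature_max": state.feature_max.tolist(),
        **{k: v.tolist() for k, v in state.parameter_blocks().items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ModelState:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema: {payload.get('schema_version')}")
    return ModelState(
        raw_gaps=np.array(payload["raw_gaps"], dtype=float),
        raw_attention=np.array(payload["raw_attention"], dtype=float),
        raw_connection=np.array(payload["raw_connection"], dtype=float),
        raw_inference=np.array(payload["raw_inference"], dtype=float),
        raw_eps=np.array(payload["raw_eps"], dtype=float),
        feature_min=np.array(payload["feature_min"], dtype=float),
        feature_max=np.array(payload["feature_max"], dtype=float),
        feature_names=list(payload["feature_names"]),
    )
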
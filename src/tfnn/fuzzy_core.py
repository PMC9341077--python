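"""Parametrized fuzzy memberships and tropical norm/conorm aggregations.

The building blocks of the network are families of operations indexed by a
smoothness parameter ``eps`` in ``(EPS_MIN, 1]``:

* **membership functions** — each feature on the min-max normalized [0,1]
  scale is mapped to degrees of D ordered linguistic concepts
  (low / medium / high for D=3).  They are smoothed trapezoid/triangle
  shapes built from logistic flanks of slope ``1/(TAU*eps)``; as ``eps``
  shrinks the curves sharpen towards their piecewise-linear limits.
* **t-norm** (fuzzy AND) — a weighted Aczel-Alsina style aggregation
  ``exp(-(sum_i w_i * (-ln v_i)^(1/eps))^eps)``.  At ``eps=1`` it is the
  weighted geometric product ``prod v_i^w_i``; as ``eps -> 0`` it tends to
  the minimum over the active (positive-weight) values.
* **t-conorm** (fuzzy OR) — a Maslov power sum
  ``(sum_i (w_i*v_i)^(1/eps))^eps``: the weighted sum at ``eps=1`` and the
  weighted maximum in the tropical limit.

Both aggregations are computed in the log domain with a max shift so that
the ``1/eps`` powers never overflow, and both accept either plain numpy
arrays or autodiff :class:`~tfnn.autodiff.Tensor` leaves (training uses the
latter).  Zero weights remove a value exactly: the family is discontinuous
in ``w`` at 0 for small ``eps`` (``w^eps -> 1``), so gating must be crisp.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .autodiff import Tensor, as_tensor, stack

logger = logging.getLogger(__name__)

EPS_MIN = 1e-3
TAU = 0.1
VALUE_FLOOR = 1e-12

__all__ = [
    "EPS_MIN",
    "TAU",
    "MembershipParams",
    "DegenerateConceptError",
    "eps_from_raw",
    "raw_from_eps",
    "concept_labels",
    "membership_encode",
    "tnorm",
    "conorm",
    "concept_threshold",
    "ThresholdSpec",
]


class DegenerateConceptError(ValueError):
    """A concept's membership never crosses 0.5 on [0,1]."""


def eps_from_raw(raw):
    """Map an unconstrained raw value into the admissible range (EPS_MIN, 1]."""
    return EPS_MIN + (1.0 - EPS_MIN) * as_tensor(raw).sigmoid() if isinstance(raw, Tensor) \
        else EPS_MIN + (1.0 - EPS_MIN) / (1.0 + np.exp(-np.asarray(raw, dtype=float)))


def raw_from_eps(eps: float) -> float:
    p = (eps - EPS_MIN) / (1.0 - EPS_MIN)
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1.0 - p)))


def concept_labels(n_concepts: int) -> list[str]:
    if n_concepts == 2:
        return ["low", "high"]
    if n_concepts == 3:
        return ["low", "medium", "high"]
    if n_concepts == 4:
        return ["very low", "low", "high", "very high"]
    return [f"level {d}" for d in range(n_concepts)]


@dataclass
class MembershipParams:
    """Per-feature breakpoints delimiting the linguistic concepts.

    ``breakpoints`` has shape (H, D-1) with strictly increasing rows inside
    (0, 1); ``eps`` is the shared smoothness of the logistic flanks.
    """

    breakpoints: np.ndarray
    eps: float = 0.5
    n_concepts: int = field(default=3)

    def __post_init__(self):
        self.breakpoints = np.atleast_2d(np.asarray(self.breakpoints, dtype=float))
        if self.breakpoints.shape[1] != self.n_concepts - 1:
            raise ValueError(
                f"need {self.n_concepts - 1} breakpoints per feature, "
                f"got {self.breakpoints.shape[1]}"
            )
        if not (EPS_MIN < self.eps <= 1.0):
            raise ValueError(f"eps must lie in ({EPS_MIN}, 1], got {self.eps}")
        diffs = np.diff(self.breakpoints, axis=1)
        if (self.breakpoints <= 0).any() or (self.breakpoints >= 1).any() or (diffs <= 0).any():
            raise ValueError("breakpoints must be strictly increasing inside (0, 1)")

    @property
    def n_features(self) -> int:
        return self.breakpoints.shape[0]


def _sigmoid_np(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _memberships_graph(x: Tensor, breakpoints: Tensor, eps: Tensor) -> Tensor:
    """Memberships for x (n,H) and breakpoints (H,D-1); returns (n,H,D).

    Each concept is normalized by its own peak value so that it attains
    exactly 1 somewhere in [0,1] (non-degeneracy) for every eps.
    """
    n_cuts = breakpoints.shape[-1]
    D = n_cuts + 1
    s = eps * TAU  # flank scale
    xe = x.reshape(x.shape[0], x.shape[1], 1)
    concepts = []
    for d in range(D):
        if d == 0:
            b = breakpoints[:, 0:1]          # (H,1)
            f = ((b - xe) / s).sigmoid()
            peak = (b / s).sigmoid()         # value at x=0
            mu = f / peak
        elif d == D - 1:
            b = breakpoints[:, n_cuts - 1:n_cuts]
            f = ((xe - b) / s).sigmoid()
            peak = ((1.0 - b) / s).sigmoid()  # value at x=1
            mu = f / peak
        else:
            b_lo = breakpoints[:, d - 1:d]
            b_hi = breakpoints[:, d:d + 1]
            f = ((xe - b_lo) / s).sigmoid() * ((b_hi - xe) / s).sigmoid()
            half = (b_hi - b_lo) * 0.5
            peak = (half / s).sigmoid() * (half / s).sigmoid()
            mu = f / peak
        concepts.append(mu.clamp_max(1.0)[:, :, 0])
    return stack(concepts, axis=2)


def membership_encode(x, params: MembershipParams):
    """Encode normalized features into concept membership degrees.

    Parameters
    ----------
    x : array-like, shape (H,) or (n, H)
        Feature values on the min-max normalized [0,1] scale.
    params : MembershipParams

    Returns
    -------
    ndarray of shape (n, H, D) (or (H, D) for a single row), entries in [0,1].
    """
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if not np.isfinite(arr).all():
        raise ValueError("membership_encode: non-finite input values")
    if (arr < 0).any() or (arr > 1).any():
        warnings.warn("inputs outside [0,1] clamped to the normalized range", stacklevel=2)
        arr = np.clip(arr, 0.0, 1.0)
    out = _memberships_graph(
        as_tensor(arr), as_tensor(params.breakpoints), as_tensor(params.eps)
    ).data
    return out[0] if single else out


def _max_over(data: np.ndarray, mask: np.ndarray, axis: int) -> np.ndarray:
    masked = np.where(mask, data, -np.inf)
    with np.errstate(invalid="ignore"):
        return np.max(masked, axis=axis, keepdims=True)


def tnorm(values, weights, eps, axis: int = -1):
    """Weighted parametrized t-norm interpolating product (eps=1) and min.

    ``exp(-(sum_i w_i * (-ln v_i)^(1/eps))^eps)`` reduced along ``axis``.
    Zero-weight values are removed exactly (conjunction identity 1); an
    all-zero weight slice yields 1 (empty conjunction).
    """
    v = as_tensor(values)
    w = as_tensor(weights)
    e = as_tensor(eps)
    v = v.clamp_min(VALUE_FLOOR).clamp_max(1.0)
    u = -(v.log()) + VALUE_FLOOR          # > 0
    log_u = u.log()
    active = np.broadcast_to(w.data, np.broadcast_shapes(w.shape, u.shape)) > 0.0
    m_hat = _max_over(np.broadcast_to(log_u.data, active.shape), active, axis)
    any_active = np.isfinite(m_hat)
    m_hat = np.where(any_active, m_hat, 0.0)
    shifted = ((log_u - m_hat) / e).where_mask(active, 0.0).exp() * w
    ssum = shifted.sum(axis=axis, keepdims=True)
    inner = (as_tensor(m_hat) + e * (ssum + 1e-300).log()).exp()
    result = (-inner).exp().where_mask(any_active, 1.0)
    if not any_active.all():
        logger.debug("tnorm: empty active set encountered; returning identity 1")
    return _squeeze(result, axis)


def conorm(values, weights, eps, axis: int = -1):
    """Weighted parametrized conorm interpolating sum (eps=1) and max.

    ``(sum_i (w_i*v_i)^(1/eps))^eps`` reduced along ``axis``; all-zero
    input slices yield 0 (empty disjunction).
    """
    v = as_tensor(values)
    w = as_tensor(weights)
    e = as_tensor(eps)
    t = (v * w).clamp_min(0.0)
    log_t = (t + VALUE_FLOOR).log()
    active = np.broadcast_to(t.data, log_t.shape) > 0.0
    m_hat = _max_over(log_t.data, active, axis)
    any_active = np.isfinite(m_hat)
    m_hat = np.where(any_active, m_hat, 0.0)
    shifted = ((log_t - m_hat) / e).where_mask(active, -745.0).exp().where_mask(active, 0.0)
    ssum = shifted.sum(axis=axis, keepdims=True)
    result = (as_tensor(m_hat) + e * (ssum + 1e-300).log()).exp()
    result = result.where_mask(any_active, 0.0)
    return _squeeze(result, axis)


def _squeeze(t: Tensor, axis: int) -> Tensor:
    shape = list(t.shape)
    axis = axis % len(shape)
    del shape[axis]
    return t.reshape(*shape) if shape else t.reshape(1)[0:1].sum()


@dataclass(frozen=True)
class ThresholdSpec:
    """Crisp description of a concept: one cut for shoulders, an interval
    for interior concepts, on the original feature scale."""

    comparator: str               # '<', '>', or 'in'
    values: tuple[float, ...]     # one cut, or (lo, hi) for 'in'

    def describe(self, precision: int = 2) -> str:
        fmt = lambda v: f"{v:.{precision}f}".rstrip("0").rstrip(".")
        if self.comparator == "in":
            return f"in ({fmt(self.values[0])}, {fmt(self.values[1])})"
        return f"{self.comparator}{fmt(self.values[0])}"

    def satisfied(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.comparator == "<":
            return x < self.values[0]
        if self.comparator == ">":
            return x > self.values[0]
        return (x > self.values[0]) & (x < self.values[1])


def _membership_curve(params: MembershipParams, feature: int, concept: int):
    bp = params.breakpoints[feature:feature + 1]

    def mu(x: float) -> float:
        enc = _memberships_graph(
            as_tensor(np.array([[x]], dtype=float)),
            as_tensor(bp),
            as_tensor(params.eps),
        ).data
        return float(enc[0, 0, concept])

    return mu


def concept_threshold(
    params: MembershipParams,
    feature: int,
    concept: int | str,
    stats: tuple[float, float] | None = None,
    tol: float = 1e-6,
) -> ThresholdSpec:
    """Solve mu_concept(x) = 0.5 by bisection and report the crisp cut(s).

    Shoulder concepts yield a single cut ('<' for the lowest concept, '>'
    for the highest); interior concepts yield an interval.  ``stats`` is
    the (min, max) pair of the feature in original units; when given, cuts
    are mapped back to that scale.
    """
    D = params.n_concepts
    if isinstance(concept, str):
        concept = concept_labels(D).index(concept)
    mu = _membership_curve(params, feature, concept)
    lo, hi = params.breakpoints[feature, 0], params.breakpoints[feature, -1]

    def solve(a: float, b: float) -> float:
        fa, fb = mu(a) - 0.5, mu(b) - 0.5
        if fa * fb > 0:
            raise DegenerateConceptError(
                f"concept {concept} of feature {feature} never crosses 0.5"
            )
        return brentq(lambda x: mu(x) - 0.5, a, b, xtol=tol)

    def unmap(x: float) -> float:
        if stats is None:
            return x
        lo_s, hi_s = stats
        return lo_s + x * (hi_s - lo_s)

    if concept == 0:
        return ThresholdSpec("<", (unmap(solve(0.0, 1.0)),))
    if concept == D - 1:
        return ThresholdSpec(">", (unmap(solve(0.0, 1.0)),))
    b_lo = params.breakpoints[feature, concept - 1]
    b_hi = params.breakpoints[feature, concept]
    peak = 0.5 * (b_lo + b_hi)
    left = solve(0.0, peak)
    right = solve(peak, 1.0)
    return ThresholdSpec("in", (unmap(left), unmap(right)))
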
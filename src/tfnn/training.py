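"""Composite loss and the gradient-descent training loop.

The total loss is ``loss_ce + lambda1 * loss_sparse + lambda2 * loss_corr``
(optionally plus a smoothness annealing term ``lambda_eps * sum(eps)``):

* ``loss_ce`` — mean cross-entropy on the normalized class scores;
* ``loss_sparse`` — an l1 or l0 penalty on the constrained attention and
  connection weights, ``||vec(A)||_i + ||vec(M)||_i``, discouraging rules
  with many variables.  The l0 count is non-differentiable, so the loss
  uses the surrogate ``sum(1 - exp(-w/gamma))`` which tends to the exact
  count as ``gamma -> 0``; exact counts are only used for reporting.
* ``loss_corr`` — redundancy penalty: the sum over unordered rule pairs of
  the inner products of flattened contribution slices
  ``vec(S_:,:,k) . vec(S_:,:,k')``, zero iff rules have disjoint support.

All raw parameters (weights, breakpoint gaps, smoothness raws) are trained
jointly with Adam; runs are deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import train_test_split

from . import network as net
from .autodiff import Adam, Tensor, as_tensor
from .network import ModelState

logger = logging.getLogger(__name__)

__all__ = ["LossConfig", "ModelConfig", "TrainingHistory", "sparsity_loss",
           "correlation_loss", "total_loss", "fit", "select_hyperparameters"]


@dataclass
class LossConfig:
    """Loss weights and optimizer settings.

    lambda_sparse, lambda_corr are the lambda_1, lambda_2 multipliers of the
    sparsity and redundancy terms; gamma scales the l0 surrogate; lambda_eps
    optionally anneals the aggregations toward the piecewise-linear regime.
    """

    lambda_sparse: float = 0.0
    lambda_corr: float = 1e-3
    sparsity: str = "none"          # 'none' | 'l1' | 'l0'
    gamma: float = 0.01
    lambda_eps: float = 0.0
    lr: float = 0.01
    epochs: int = 500
    batch_size: int | None = None   # None = full batch for n <= 4000
    seed: int = 0

    def __post_init__(self):
        if self.sparsity not in ("none", "l1", "l0"):
            raise ValueError(f"unknown sparsity kind '{self.sparsity}'")
        if min(self.lambda_sparse, self.lambda_corr, self.lambda_eps) < 0 or self.gamma <= 0:
            raise ValueError("loss weights must be non-negative and gamma positive")


@dataclass
class ModelConfig:
    n_concepts: int = 3
    n_rules: int = 10
    n_classes: int = 2


@dataclass
class TrainingHistory:
    records: list[dict] = field(default_factory=list)
    state: ModelState | None = None

    @property
    def final_loss(self) -> float:
        return self.records[-1]["total"]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)


def sparsity_loss(A, M, kind: str = "l1", gamma: float = 0.01):
    """Sparsity penalty on constrained (non-negative) weight matrices."""
    if kind == "none":
        return as_tensor(0.0) if isinstance(A, Tensor) else 0.0
    if kind == "l1":
        # entries are non-negative, so the l1 norm is the plain sum
        return as_tensor(A).sum() + as_tensor(M).sum() if isinstance(A, Tensor) \
            else float(np.sum(A) + np.sum(M))
    if kind == "l0":
        if isinstance(A, Tensor):
            return (1.0 - (-(A / gamma)).exp()).sum() + (1.0 - (-(M / gamma)).exp()).sum()
        return float(np.sum(1 - np.exp(-np.asarray(A) / gamma))
                     + np.sum(1 - np.exp(-np.asarray(M) / gamma)))
    raise ValueError(f"unknown sparsity kind '{kind}'")


def correlation_loss(S):
    """Sum over unordered rule pairs of <vec(S_k), vec(S_k')>.

    Uses the identity  sum_{k<k'} <v_k, v_k'> = (||sum_k v_k||^2 -
    sum_k ||v_k||^2) / 2  so no pair loop is needed.
    """
    St = as_tensor(S)
    if St.ndim != 3:
        raise ValueError("contribution tensor must have shape (H, D, K)")
    if St.shape[2] < 2:
        return as_tensor(0.0) if isinstance(S, Tensor) else 0.0
    total_vec = St.sum(axis=2)
    val = ((total_vec * total_vec).sum() - (St * St).sum()) * 0.5
    return val if isinstance(S, Tensor) else float(val.data)


def _loss_graph(X: np.ndarray, y: np.ndarray, params: dict[str, Tensor],
                config: LossConfig) -> dict[str, Tensor]:
    g = net.forward_graph(X, params)
    C = g["probs"].shape[1]
    onehot = np.eye(C)[y]
    ce = -((g["probs"] + 0.0).log() * onehot).sum(axis=1).mean()
    sparse = sparsity_loss(g["A"], g["M"], config.sparsity, config.gamma)
    H, D, K = g["A"].shape
    S = g["A"] * g["M"].reshape(H, 1, K)
    corr = correlation_loss(S)
    eps_pen = g["eps_enc"] + g["eps_rule"] + g["eps_inf"]
    total = ce + config.lambda_sparse * sparse + config.lambda_corr * corr \
        + config.lambda_eps * eps_pen
    return {"ce": ce, "sparse": as_tensor(sparse), "corr": as_tensor(corr),
            "eps_penalty": eps_pen, "total": total}


def total_loss(X_norm: np.ndarray, y: np.ndarray, state: ModelState,
               config: LossConfig) -> dict[str, float]:
    """All loss components for a normalized batch (reporting interface)."""
    y = np.asarray(y, dtype=int)
    C = state.n_classes
    if ((y < 0) | (y >= C)).any():
        raise ValueError(f"labels must lie in 0..{C - 1}")
    params = {k: as_tensor(v) for k, v in state.parameter_blocks().items()}
    comps = _loss_graph(np.atleast_2d(X_norm), y, params, config)
    return {k: float(v.data) for k, v in comps.items()}


def fit(X, y, model_config: ModelConfig | None = None,
        loss_config: LossConfig | None = None,
        feature_names: list[str] | None = None,
        init_state: ModelState | None = None) -> TrainingHistory:
    """Train a model on data in original units.

    Normalization statistics are computed from this data (the training
    fold) and stored on the returned state; test rows presented later are
    clamped into the training range.
    """
    model_config = model_config or ModelConfig()
    cfg = loss_config or LossConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain at least two classes")
    n, H = X.shape
    fmin, fmax = X.min(axis=0), X.max(axis=0)
    if init_state is None:
        span = np.where(fmax > fmin, fmax - fmin, 1.0)
        Xn = np.clip((X - fmin) / span, 0, 1)
        state = net.init_model(H, model_config.n_concepts, model_config.n_rules,
                               model_config.n_classes, cfg.seed, X_norm=Xn,
                               feature_min=fmin, feature_max=fmax,
                               feature_names=feature_names)
    else:
        state = init_state
        Xn = net.normalize(X, state)
    params = {k: Tensor(v.copy(), requires_grad=True)
              for k, v in state.parameter_blocks().items()}
    opt = Adam(list(params.values()), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    batch = cfg.batch_size if cfg.batch_size else (n if n <= 4000 else 2048)
    history = TrainingHistory()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if batch < n else np.arange(n)
        comps_sum = {"ce": 0.0, "sparse": 0.0, "corr": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            opt.zero_grad()
            comps = _loss_graph(Xn[idx], y[idx], params, cfg)
            comps["total"].backward()
            opt.step()
            for k in comps_sum:
                comps_sum[k] += float(comps[k].data)
            n_batches += 1
        rec = {k: v / n_batches for k, v in comps_sum.items()}
        rec["epoch"] = epoch
        if not np.isfinite(rec["total"]):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        history.records.append(rec)
    final = ModelState(
        raw_gaps=params["raw_gaps"].data,
        raw_attention=params["raw_attention"].data,
        raw_connection=params["raw_connection"].data,
        raw_inference=params["raw_inference"].data,
        raw_eps=params["raw_eps"].data,
        feature_min=state.feature_min,
        feature_max=state.feature_max,
        feature_names=state.feature_names,
    )
    history.state = final
    return history


def select_hyperparameters(X, y, K_grid, model_config: ModelConfig | None = None,
                           loss_config: LossConfig | None = None,
                           seed: int = 0) -> tuple[int, dict[int, float]]:
    """Pick the rule count K by inner-validation AUC on a stratified 80/20
    split; ties break toward the smaller (more parsimonious) K."""
    from .evaluation import auc_score

    K_grid = sorted(set(int(k) for k in K_grid))
    if not K_grid:
        raise ValueError("K grid must be non-empty")
    if min(K_grid) < 1:
        raise ValueError("rule counts must be >= 1")
    model_config = model_config or ModelConfig()
    cfg = loss_config or LossConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if len(K_grid) == 1:
        return K_grid[0], {K_grid[0]: float("nan")}
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=0.2, stratify=y, random_state=seed)
    scores: dict[int, float] = {}
    best_K, best_auc = K_grid[0], -np.inf
    for K in K_grid:
        hist = fit(X_tr, y_tr, replace(model_config, n_rules=K),
                   replace(cfg, seed=seed))
        proba = net.predict_proba(X_val, hist.state)
        auc = auc_score(y_val, proba[:, 1])
        scores[K] = auc
        logger.info("inner selection: K=%d -> AUC %.4f", K, auc)
        if auc > best_auc + 1e-12:
            best_auc, best_K = auc, K
    return best_K, scores
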
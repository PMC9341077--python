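"""Dataset loading, MRMR feature ranking and cross-validated evaluation.

Evaluation follows the usual clinical-prediction protocol: stratified
k-fold cross-validation with per-fold normalization (min-max statistics
come from the training part only, so no information leaks into the held-out
fold), and accuracy / recall / precision / F1 / AUC reported as mean
(standard deviation) across folds.  The positive class (index 1) is the
unfavorable outcome; AUC uses the rank (concordance) formulation with ties
counted 1/2.

MRMR is the greedy mutual-information-difference variant: at each step the
candidate maximizing MI(feature; label) minus the mean MI(feature;
already-selected) is added.  MI is estimated on quantile-binned features
(5 bins by default), which keeps the ranking deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import mutual_info_score, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from . import network as net
from .training import LossConfig, ModelConfig, fit, select_hyperparameters

logger = logging.getLogger(__name__)

__all__ = ["Dataset", "FoldMetrics", "load_dataset", "mrmr_rank",
           "auc_score", "compute_metrics", "cross_validate"]

METRIC_NAMES = ("accuracy", "recall", "precision", "f1", "auc")


@dataclass
class Dataset:
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    class_names: list[str] = field(default_factory=lambda: ["favorable", "unfavorable"])

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def load_dataset(path, label_column: str, n_classes: int = 2) -> Dataset:
    """Read a delimited table; coerce features to numbers and median-impute.

    Imputation is logged per column.  Label values are mapped to 0..C-1 by
    sorted order.
    """
    frame = pd.read_csv(path)
    if label_column not in frame.columns:
        raise ValueError(f"label column '{label_column}' not found in {path}")
    labels_raw = frame[label_column]
    classes = sorted(labels_raw.dropna().unique().tolist())
    if len(classes) != n_classes:
        raise ValueError(
            f"label column '{label_column}' has {len(classes)} classes, "
            f"expected {n_classes}"
        )
    y = labels_raw.map({c: i for i, c in enumerate(classes)}).to_numpy(dtype=int)
    feats = frame.drop(columns=[label_column])
    X_cols = []
    for col in feats.columns:
        vals = pd.to_numeric(feats[col], errors="coerce")
        if vals.isna().all():
            raise ValueError(f"feature column '{col}' is not numeric")
        n_missing = int(vals.isna().sum())
        if n_missing:
            med = float(vals.median())
            logger.info("imputed %d missing cells in '%s' with median %g",
                        n_missing, col, med)
            vals = vals.fillna(med)
        X_cols.append(vals.to_numpy(dtype=float))
    X = np.column_stack(X_cols)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values remain after imputation")
    return Dataset(X=X, y=y, feature_names=list(feats.columns),
                   class_names=[str(c) for c in classes])


def _quantile_bin(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def mrmr_rank(X, y, n_select: int | None = None, n_bins: int = 5) -> list[tuple[int, float]]:
    """Greedy minimum-redundancy maximum-relevance feature ranking.

    Returns (feature index, score) in selection order, where the score is
    relevance minus mean redundancy at the time of selection; ties break
    toward the smaller feature index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("label is constant; relevance is undefined")
    H = X.shape[1]
    n_select = H if n_select is None else min(n_select, H)
    binned = [_quantile_bin(X[:, j], n_bins) for j in range(H)]
    relevance = np.array([mutual_info_score(b, y) for b in binned])
    selected: list[tuple[int, float]] = []
    chosen: list[int] = []
    remaining = list(range(H))
    red_sum = np.zeros(H)
    while remaining and len(selected) < n_select:
        if not chosen:
            scores = relevance[remaining]
        else:
            scores = np.array([
                relevance[j] - red_sum[j] / len(chosen) for j in remaining
            ])
        best_pos = int(np.argmax(scores))  # argmax takes the first (lowest index) tie
        j = remaining.pop(best_pos)
        selected.append((j, float(scores[best_pos])))
        chosen.append(j)
        for j2 in remaining:
            red_sum[j2] += mutual_info_score(binned[j], binned[j2])
    return selected


def auc_score(y_true, scores) -> float:
    """AUC by the rank formulation; tied scores count one half."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(scores)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(y_true, scores, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy, recall, precision, F1 (positive = class 1) and AUC."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= threshold).astype(int)
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="binary", pos_label=1, zero_division=0)
    return {
        "accuracy": float((y_pred == y_true).mean()),
        "recall": float(recall),
        "precision": float(precision),
        "f1": float(f1),
        "auc": auc_score(y_true, scores),
    }


@dataclass
class FoldMetrics:
    per_fold: pd.DataFrame       # one row per fold, columns METRIC_NAMES
    selected_K: list[int]
    states: list = field(default_factory=list)

    @property
    def mean(self) -> pd.Series:
        return self.per_fold[list(METRIC_NAMES)].mean()

    @property
    def std(self) -> pd.Series:
        return self.per_fold[list(METRIC_NAMES)].std(ddof=1)

    def summary(self) -> str:
        return "  ".join(f"{m}: {self.mean[m]:.3f} ({self.std[m]:.3f})"
                         for m in METRIC_NAMES)


def cross_validate(X, y, model_config: ModelConfig | None = None,
                   loss_config: LossConfig | None = None,
                   folds: int = 10, seed: int = 0,
                   K_grid: list[int] | None = None,
                   feature_names: list[str] | None = None,
                   keep_states: bool = False) -> FoldMetrics:
    """Stratified k-fold evaluation; deterministic given ``seed``.

    Per fold the model is fit on the training part (its min-max statistics
    and any inner K selection use only those rows) and scored on the
    held-out part.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    model_config = model_config or ModelConfig()
    cfg = loss_config or LossConfig()
    if np.bincount(y).min() < folds:
        raise ValueError("smallest class is too small for stratified folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    selected_Ks: list[int] = []
    states = []
    for fold_id, (tr, te) in enumerate(skf.split(X, y)):
        mc = model_config
        if K_grid:
            best_K, _ = select_hyperparameters(
                X[tr], y[tr], K_grid, model_config, cfg, seed=seed + fold_id)
            mc = replace(model_config, n_rules=best_K)
        selected_Ks.append(mc.n_rules)
        hist = fit(X[tr], y[tr], mc, replace(cfg, seed=seed + fold_id),
                   feature_names=feature_names)
        proba = net.predict_proba(X[te], hist.state)
        row = compute_metrics(y[te], proba[:, 1])
        row["fold"] = fold_id
        rows.append(row)
        if keep_states:
            states.append(hist.state)
        logger.info("fold %d: %s", fold_id,
                    "  ".join(f"{k}={v:.3f}" for k, v in row.items() if k != "fold"))
    return FoldMetrics(per_fold=pd.DataFrame(rows), selected_K=selected_Ks,
                       states=states)
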
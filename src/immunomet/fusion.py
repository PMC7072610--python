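"""Two-feature biomarker fusion models.

A weighted linear combination of two standardized features (e.g. a cytokine
and a metabolite), with percentage weights and a Youden-optimal decision
threshold, plus a "logic OR" combination of two binary predictors: a
sample is called positive if either component model calls it positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import auroc, best_threshold

logger = logging.getLogger(__name__)


@dataclass
class FusionModel:
    """w1*z1 + w2*z2 on training-standardized, orientation-corrected features.

    `signs` orient each feature positively toward the positive class (a
    feature whose raw AUROC is below one half enters negated), so the
    weights can be read as positive percentage contributions.
    """

    feature_ids: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    signs: tuple[int, int]
    weights: tuple[float, float]  # |w1| + |w2| = 1
    threshold: float
    positive_class: object
    method: str = "grid"

    def __post_init__(self) -> None:
        w1, w2 = self.weights
        if not np.isclose(abs(w1) + abs(w2), 1.0):
            raise ValueError("weights must satisfy |w1| + |w2| = 1")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


#: Percentage weights printed for the two published two-feature models,
#: usable for scoring without refitting (standardization must be supplied
#: from the data at hand).
PUBLISHED_WEIGHTS = {
    ("TNFa", "valine"): (0.784, 0.216),
    ("IL2", "IL10"): (0.961, 0.039),
}


def _standardize(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return (x - mean) / sd


def fit_linear_combo(
    x1,
    x2,
    labels,
    positive_class,
    method: str = "grid",
    feature_ids: tuple[str, str] = ("feature_1", "feature_2"),
    grid_step: float = 0.001,
) -> FusionModel:
    """Fit the two-feature combination on pairwise-complete training samples.

    method="grid": exhaustive scan of w1 in [0, 1] (step `grid_step`)
    maximizing the training AUROC of w1*s1 + (1-w1)*s2 on the standardized,
    orientation-corrected features.  method="lda": two-feature Fisher
    discriminant coefficients, normalized to |w1| + |w2| = 1.  The decision
    threshold maximizes Youden's J on the combined training scores.
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    ok = np.isfinite(x1) & np.isfinite(x2)
    x1, x2, labels = x1[ok], x2[ok], labels[ok]
    pos = labels == positive_class
    if min(pos.sum(), (~pos).sum()) < 3:
        raise ValueError("need >= 3 pairwise-complete samples per class")
    stats_ = []
    for x in (x1, x2):
        m, s = float(x.mean()), float(x.std(ddof=1))
        if s == 0:
            raise ValueError("degenerate feature with zero variance")
        stats_.append((m, s))
    z1 = _standardize(x1, *stats_[0])
    z2 = _standardize(x2, *stats_[1])
    signs = tuple(
        1 if auroc(z, labels, positive_class) >= 0.5 else -1 for z in (z1, z2)
    )
    s1, s2 = signs[0] * z1, signs[1] * z2

    if method == "grid":
        grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
        aucs = [auroc(w * s1 + (1 - w) * s2, labels, positive_class) for w in grid]
        w1 = float(grid[int(np.argmax(aucs))])
        weights = (w1, 1.0 - w1)
    elif method == "lda":
        Z = np.column_stack([s1, s2])
        mu_d = Z[pos].mean(axis=0) - Z[~pos].mean(axis=0)
        Sw = np.cov(Z[pos], rowvar=False) * (pos.sum() - 1) + np.cov(
            Z[~pos], rowvar=False
        ) * ((~pos).sum() - 1)
        w = np.linalg.pinv(Sw) @ mu_d
        w = w / np.abs(w).sum()
        weights = (float(w[0]), float(w[1]))
    else:
        raise ValueError(f"unknown method {method!r}")

    combined = weights[0] * s1 + weights[1] * s2
    thr, _, _ = best_threshold(combined, labels, positive_class)
    return FusionModel(
        feature_ids=tuple(feature_ids),
        means=(stats_[0][0], stats_[1][0]),
        sds=(stats_[0][1], stats_[1][1]),
        signs=signs,
        weights=weights,
        threshold=thr,
        positive_class=positive_class,
        method=method,
    )


def score_linear_combo(model: FusionModel, x1, x2) -> np.ndarray:
    """Combined score per sample; missing inputs propagate as NaN (logged)."""
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    z1 = model.signs[0] * _standardize(x1, model.means[0], model.sds[0])
    z2 = model.signs[1] * _standardize(x2, model.means[1], model.sds[1])
    score = model.weights[0] * z1 + model.weights[1] * z2
    n_missing = int(np.isnan(score).sum())
    if n_missing:
        logger.info("combined score missing for %d sample(s)", n_missing)
    return score


def predict_linear_combo(model: FusionModel, x1, x2) -> np.ndarray:
    """Binary call per sample: score > threshold; NaN score stays NaN."""
    score = score_linear_combo(model, x1, x2)
    out = np.where(np.isnan(score), np.nan, (score > model.threshold).astype(float))
    return out


def logic_or_predict(pred_a, pred_b) -> pd.Series:
    """Elementwise OR of two aligned binary predictions.

    Accepts pandas Series (aligned on index, outer join) or positionally
    aligned arrays.  A prediction missing in one input counts as a negative
    vote in that input, so a sample covered by only one model can still be
    called; the number of such samples is logged.
    """
    if isinstance(pred_a, pd.Series) or isinstance(pred_b, pd.Series):
        a = pd.Series(pred_a)
        b = pd.Series(pred_b)
        if len(a.index.intersection(b.index)) == 0:
            raise ValueError("prediction sample sets are disjoint")
        idx = a.index.union(b.index)
        a, b = a.reindex(idx), b.reindex(idx)
    else:
        a = pd.Series(np.asarray(pred_a, dtype=float))
        b = pd.Series(np.asarray(pred_b, dtype=float))
        if len(a) != len(b):
            raise ValueError("positionally aligned predictions differ in length")
    n_missing = int(a.isna().sum() + b.isna().sum())
    if n_missing:
        logger.info("%d missing votes treated as negative in logic-OR", n_missing)
    return ((a.fillna(0) > 0) | (b.fillna(0) > 0)).astype(int)


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.sensitivity = self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")
        self.specificity = self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")
        total = self.tp + self.fp + self.tn + self.fn
        self.accuracy = (self.tp + self.tn) / total if total else float("nan")


def confusion(pred, truth, positive_class) -> ConfusionSummary:
    """Confusion counts and the three standard proportions."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.size != truth.size:
        raise ValueError("pred and truth must be aligned")
    labels = set(np.unique(truth).tolist()) | set(np.unique(pred).tolist())
    if len(labels - {positive_class}) > 1:
        raise ValueError(f"labels outside a binary contrast: {sorted(map(str, labels))}")
    p = pred == positive_class
    t = truth == positive_class
    return ConfusionSummary(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )
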
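"""Supervised PCA-CA-kNN classification of binned spectra.

The pipeline reduces the bucket matrix by principal component analysis,
applies canonical (Fisher) analysis on the PC scores to obtain the
supervised separation of the groups, and classifies by k-nearest-neighbour
vote in the canonical score space.  Performance is assessed by
leave-one-out or Monte-Carlo cross-validation, with significance from a
label-permutation test on the cross-validated accuracy.

Every cross-validation fold refits the entire pipeline (centering, PCA, CA)
on the training part only, so the held-out sample never leaks into the
model that predicts it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(X: np.ndarray, n_pc: int):
    """Column-mean-centred SVD-based PCA.

    Returns (column_means, loadings, scores, explained_variance_ratio) with
    loadings of shape (features, n_pc), columns orthonormal and ordered by
    decreasing explained variance; scores = centred X @ loadings.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    max_pc = min(n - 1, p)
    if not 1 <= n_pc <= max_pc:
        raise ValueError(f"n_pc must be in [1, {max_pc}], got {n_pc}")
    means = X.mean(axis=0)
    Xc = X - means
    if np.allclose(Xc, 0):
        raise ValueError("constant feature matrix has no principal components")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    evr = var[:n_pc] / var.sum()
    loadings = Vt[:n_pc].T
    scores = Xc @ loadings
    return means, loadings, scores, evr


# ---------------------------------------------------------------------------
# Canonical (Fisher) analysis
# ---------------------------------------------------------------------------

def _scatter_matrices(scores: np.ndarray, labels: np.ndarray):
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("canonical analysis needs at least two groups")
    if (counts < 2).any():
        small = classes[counts < 2].tolist()
        raise ValueError(f"every group needs >= 2 samples; too small: {small}")
    grand = scores.mean(axis=0)
    p = scores.shape[1]
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    for cls, n_g in zip(classes, counts):
        grp = scores[labels == cls]
        d = grp.mean(axis=0) - grand
        B += n_g * np.outer(d, d)
        R = grp - grp.mean(axis=0)
        W += R.T @ R
    return B, W, classes


def fit_ca(scores: np.ndarray, labels, ridge: float = 1e-8) -> np.ndarray:
    """Canonical variate directions in PC-score space.

    Solves the generalized symmetric eigenproblem B v = lambda (W + eps I) v,
    where B and W are the between- and within-group scatter matrices and
    eps = ridge * trace(W) / p regularizes a (near-)singular W.  Returns the
    (n_pc, n_ca) direction matrix, n_ca = groups - 1, columns ordered by
    decreasing discriminant criterion and scaled to unit norm.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    B, W, classes = _scatter_matrices(scores, labels)
    p = scores.shape[1]
    eps = ridge * max(np.trace(W), 1.0) / p
    evals, evecs = linalg.eigh(B, W + eps * np.eye(p))
    order = np.argsort(evals)[::-1]
    n_ca = min(classes.size - 1, p)
    directions = evecs[:, order[:n_ca]]
    directions /= np.linalg.norm(directions, axis=0, keepdims=True)
    return directions


# ---------------------------------------------------------------------------
# Model container and kNN
# ---------------------------------------------------------------------------

@dataclass
class PcaCaKnnModel:
    column_means: np.ndarray
    pca_loadings: np.ndarray
    n_pc: int
    ca_directions: np.ndarray
    train_scores: np.ndarray  # samples x n_ca, canonical space
    train_labels: np.ndarray
    k: int

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.column_means.size:
            raise ValueError(
                f"expected {self.column_means.size} features, got {X_new.shape[1]}"
            )
        return (X_new - self.column_means) @ self.pca_loadings @ self.ca_directions


def _knn_vote(train_scores, train_labels, query_scores, k) -> np.ndarray:
    """Euclidean kNN majority vote; ties fall back to the single nearest."""
    n_train = len(train_labels)
    k_eff = min(k, n_train)
    if k_eff < k:
        warnings.warn(f"k={k} exceeds training size {n_train}; clipped to {k_eff}")
    preds = []
    for q in np.atleast_2d(query_scores):
        d = np.linalg.norm(train_scores - q, axis=1)
        nearest = np.argsort(d, kind="stable")[:k_eff]
        votes, counts = np.unique(train_labels[nearest], return_counts=True)
        top = votes[counts == counts.max()]
        preds.append(top[0] if top.size == 1 else train_labels[nearest[0]])
    return np.asarray(preds)


def fit(X: np.ndarray, labels, n_pc: int, k: int = 5) -> PcaCaKnnModel:
    """Fit the full PCA-CA-kNN pipeline on a feature matrix."""
    labels = np.asarray(labels)
    means, loadings, pc_scores, _ = fit_pca(X, n_pc)
    directions = fit_ca(pc_scores, labels)
    return PcaCaKnnModel(
        column_means=means,
        pca_loadings=loadings,
        n_pc=n_pc,
        ca_directions=directions,
        train_scores=pc_scores @ directions,
        train_labels=labels,
        k=k,
    )


def predict_knn(model: PcaCaKnnModel, X_new: np.ndarray) -> np.ndarray:
    return _knn_vote(
        model.train_scores, model.train_labels, model.transform(X_new), model.k
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    per_sample_pred: np.ndarray
    sensitivity: float
    specificity: float
    accuracy: float
    scheme: str


@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float


def binary_metrics(pred, truth, positive_class) -> tuple[float, float, float]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    pos = truth == positive_class
    tp = int((pred[pos] == positive_class).sum())
    fn = int(pos.sum()) - tp
    tn = int((pred[~pos] != positive_class).sum())
    fp = int((~pos).sum()) - tn
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / truth.size
    return sens, spec, acc


def _check_two_class(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise ValueError("cross-validated metrics require exactly two classes")
    return labels


def _fold_n_pc(n_pc: int, n_train: int, p: int) -> int:
    return min(n_pc, n_train - 1, p)


def loocv(X, labels, n_pc: int, k: int = 5, positive_class=None) -> CvReport:
    """Leave-one-out CV of the whole pipeline, refit per fold."""
    X = np.asarray(X, dtype=float)
    labels = _check_two_class(labels)
    classes = np.unique(labels)
    if positive_class is None:
        positive_class = classes[-1]
    n = len(labels)
    preds = np.empty(n, dtype=labels.dtype)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.unique(labels[mask]).size < 2:
            raise ValueError("a class is absent from a training fold")
        model = fit(X[mask], labels[mask], _fold_n_pc(n_pc, n - 1, X.shape[1]), k)
        preds[i] = predict_knn(model, X[i])[0]
    sens, spec, acc = binary_metrics(preds, labels, positive_class)
    return CvReport(preds, sens, spec, acc, scheme="loocv")


def mccv(
    X,
    labels,
    n_pc: int,
    k: int = 5,
    train_fraction: float = 0.8,
    n_reps: int = 100,
    seed: int = 0,
    positive_class=None,
) -> CvReport:
    """Monte-Carlo CV: stratified random train/test splits, metrics averaged."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    labels = _check_two_class(labels)
    classes = np.unique(labels)
    if positive_class is None:
        positive_class = classes[-1]
    rng = np.random.default_rng(seed)
    sens_l, spec_l, acc_l = [], [], []
    last_pred = None
    for _ in range(n_reps):
        train_idx = []
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            n_tr = max(2, int(round(train_fraction * idx.size)))
            n_tr = min(n_tr, idx.size - 1)
            train_idx.append(rng.permutation(idx)[:n_tr])
        train_idx = np.concatenate(train_idx)
        test_mask = np.ones(len(labels), dtype=bool)
        test_mask[train_idx] = False
        model = fit(
            X[train_idx],
            labels[train_idx],
            _fold_n_pc(n_pc, train_idx.size, X.shape[1]),
            k,
        )
        pred = predict_knn(model, X[test_mask])
        s, sp, a = binary_metrics(pred, labels[test_mask], positive_class)
        sens_l.append(s)
        spec_l.append(sp)
        acc_l.append(a)
        last_pred = pred
    return CvReport(
        per_sample_pred=last_pred,
        sensitivity=float(np.nanmean(sens_l)),
        specificity=float(np.nanmean(spec_l)),
        accuracy=float(np.mean(acc_l)),
        scheme=f"mccv(train_fraction={train_fraction}, n_reps={n_reps})",
    )


def _loocv_accuracy_cached(X, n_pc: int, k: int):
    """Precompute per-fold PCA; return a closure mapping labels -> LOOCV accuracy.

    PCA is unsupervised, so the fold loadings do not depend on the labels;
    only the CA directions and the kNN vote have to be refit when labels are
    permuted.  This makes the permutation test linear in (folds x perms) CA
    fits instead of full pipeline fits.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    folds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        _, loadings, pc_scores, _ = fit_pca(X[mask], _fold_n_pc(n_pc, n - 1, p))
        held = (X[i] - X[mask].mean(axis=0)) @ loadings
        folds.append((mask, pc_scores, held))

    def accuracy(labels: np.ndarray) -> float:
        preds = np.empty(n, dtype=labels.dtype)
        for i, (mask, pc_scores, held) in enumerate(folds):
            train_lab = labels[mask]
            if np.unique(train_lab).size < 2:
                raise ValueError("a class is absent from a training fold")
            directions = fit_ca(pc_scores, train_lab)
            preds[i] = _knn_vote(
                pc_scores @ directions, train_lab, held @ directions, k
            )[0]
        return float((preds == labels).mean())

    return accuracy


def permutation_test(
    X, labels, n_pc: int, k: int = 5, n_perm: int = 1000, seed: int = 0
) -> PermutationResult:
    """Label-permutation significance of the LOOCV accuracy.

    p = (#{null >= observed} + 1) / (n_perm + 1)  (add-one estimator).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = _check_two_class(labels)
    acc_fn = _loocv_accuracy_cached(X, n_pc, k)
    observed = acc_fn(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        while True:
            perm = rng.permutation(labels)
            try:
                null[b] = acc_fn(perm)
                break
            except ValueError:  # degenerate fold after permutation; redraw
                continue
    p = (int((null >= observed - 1e-12).sum()) + 1) / (n_perm + 1)
    return PermutationResult(observed, null, p)


def select_n_components(X, labels, k: int, candidate_range, positive_class=None) -> int:
    """Smallest component count whose LOOCV accuracy attains the maximum."""
    candidates = sorted(set(int(c) for c in candidate_range))
    if not candidates:
        raise ValueError("empty candidate range")
    accs = [loocv(X, labels, n_pc=c, k=k, positive_class=positive_class).accuracy
            for c in candidates]
    best = max(accs)
    return candidates[int(np.argmax([a >= best for a in accs]))]


def loocv_nested_selection(
    X, labels, k: int, candidate_range, positive_class=None
) -> tuple[CvReport, list[int]]:
    """LOOCV with component count re-selected inside each training fold.

    The honest counterpart of whole-data selection: reports the out-of-fold
    metrics when n_pc is chosen without the held-out sample, plus the per-fold
    choices, so the optimism gap of outer selection can be quantified.
    """
    X = np.asarray(X, dtype=float)
    labels = _check_two_class(labels)
    classes = np.unique(labels)
    if positive_class is None:
        positive_class = classes[-1]
    n = len(labels)
    preds = np.empty(n, dtype=labels.dtype)
    chosen = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        n_pc_i = select_n_components(
            X[mask], labels[mask], k, candidate_range, positive_class
        )
        model = fit(X[mask], labels[mask], n_pc_i, k)
        preds[i] = predict_knn(model, X[i])[0]
        chosen.append(n_pc_i)
    sens, spec, acc = binary_metrics(preds, labels, positive_class)
    return CvReport(preds, sens, spec, acc, scheme="loocv(nested n_pc)"), chosen


# ---------------------------------------------------------------------------
# Loading analysis
# ---------------------------------------------------------------------------

@dataclass
class LoadingReport:
    bin_centers: np.ndarray
    loading_weight: np.ndarray  # signed weight per bin, first canonical axis
    direction_sign: np.ndarray  # which group has the larger mean, per bin
    rank_order: np.ndarray      # bin indices sorted by decreasing |weight|


def loading_analysis(model: PcaCaKnnModel, X, labels, bin_centers=None) -> LoadingReport:
    """Back-project the first canonical axis into bucket space.

    weight = pca_loadings @ first CA direction; bins ranked by |weight|.
    direction_sign reports, per bucket, the group with the larger group mean
    in the (normalized) matrix, i.e. which side of the contrast the bucket's
    intensity favours.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    weights = model.pca_loadings @ model.ca_directions[:, 0]
    classes = np.unique(labels)
    group_means = np.vstack([X[labels == c].mean(axis=0) for c in classes])
    direction_sign = classes[np.argmax(group_means, axis=0)]
    order = np.argsort(-np.abs(weights), kind="stable")
    centers = (
        np.asarray(bin_centers, dtype=float)
        if bin_centers is not None
        else np.arange(X.shape[1], dtype=float)
    )
    if centers.size != weights.size:
        raise ValueError("bin_centers length must match the feature count")
    return LoadingReport(centers, weights, direction_sign, order)
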
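"""Univariate biomarker screening statistics.

Per-feature two-group comparison: Wilcoxon-Mann-Whitney test with
Benjamini-Hochberg FDR control across the tested family, Cliff's delta
effect size with the conventional magnitude labels, rank-based AUROC, a
Youden-optimal decision threshold, and Pearson correlation for checking
that fused features carry independent information.

Missing values are removed per feature (pairwise-complete deletion), so a
marker measured on only part of the cohort is still testable; the
effective group sizes are reported alongside each statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: |delta| cut points for the negligible / small / medium / large labels.
DELTA_THRESHOLDS = (0.147, 0.33, 0.474)


def _clean(a) -> np.ndarray:
    a = np.asarray(a, dtype=float).ravel()
    return a[np.isfinite(a)]


def delta_magnitude(delta: float) -> str:
    d = abs(delta)
    if d < DELTA_THRESHOLDS[0]:
        return "negligible"
    if d < DELTA_THRESHOLDS[1]:
        return "small"
    if d < DELTA_THRESHOLDS[2]:
        return "medium"
    return "large"


def cliffs_delta(x, y) -> tuple[float, str]:
    """Cliff's delta of group x over group y, with its magnitude label.

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (n1 * n2), computed through the
    Mann-Whitney U identity U = #{x > y} + 0.5 * #{x = y}, so ties contribute
    zero net dominance.  Positive delta means x stochastically larger.
    """
    x, y = _clean(x), _clean(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group after missing-value removal")
    u1 = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    delta = 2.0 * u1 / (x.size * y.size) - 1.0
    return float(delta), delta_magnitude(delta)


def auroc(values, binary_labels, positive) -> float:
    """Rank-based area under the ROC curve (ties count one half).

    Equals U / (n1 * n2) with the positive class as group 1: the probability
    that a random positive sample scores above a random negative one.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(binary_labels).ravel()
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    pos = labels == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both label classes must be present")
    ranks = stats.rankdata(values)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def mann_whitney(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test; returns (U of x, p).

    mode="auto" uses the exact null distribution when n1 + n2 <= 20 and the
    data are tie-free, otherwise the normal approximation with tie and
    continuity corrections.  mode="exact"/"asymptotic" force a method.
    """
    x, y = _clean(x), _clean(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    if mode == "auto":
        tie_free = np.unique(np.concatenate([x, y])).size == x.size + y.size
        method = "exact" if tie_free and x.size + y.size <= 20 else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def best_threshold(values, binary_labels, positive) -> tuple[float, float, float]:
    """Decision cut maximizing Youden's J = sensitivity + specificity - 1.

    Samples scoring strictly above the threshold are called positive
    (higher-is-positive orientation).  Candidate cuts are the midpoints of
    consecutive sorted unique values plus the two open ends; ties on J are
    broken toward the higher-specificity (larger) threshold.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(binary_labels).ravel()
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    pos = labels == positive
    if pos.all() or not pos.any():
        raise ValueError("both label classes must be present")
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else np.array([])
    cands = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best = None
    for thr in cands:
        call = values > thr
        sens = (call & pos).sum() / pos.sum()
        spec = (~call & ~pos).sum() / (~pos).sum()
        j = sens + spec - 1
        if best is None or j > best[3] + 1e-12 or (
            abs(j - best[3]) <= 1e-12 and spec > best[2]
        ):
            best = (float(thr), float(sens), float(spec), float(j))
    return best[0], best[1], best[2]


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation on pairwise-complete observations, two-sided p."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class MarkerStats:
    feature_id: str
    n_group1: int
    n_group2: int
    u_statistic: float
    p_value: float
    q_value: float
    cliffs_delta: float
    delta_magnitude: str
    auroc: float


def marker_table(
    features: pd.DataFrame, labels, group1, group2, positive=None
) -> pd.DataFrame:
    """Screen every feature column for a two-group difference.

    `labels` is aligned with the rows of `features`; delta is oriented
    group1 minus group2, AUROC toward `positive` (default group1).  The BH
    family is the full set of columns tested in this call.
    """
    labels = np.asarray(labels)
    if positive is None:
        positive = group1
    rows = []
    for col in features.columns:
        v = features[col].to_numpy(dtype=float)
        x = _clean(v[labels == group1])
        y = _clean(v[labels == group2])
        u, p = mann_whitney(x, y)
        delta, mag = cliffs_delta(x, y)
        mask = np.isfinite(v) & np.isin(labels, [group1, group2])
        a = auroc(v[mask], labels[mask], positive)
        rows.append(
            MarkerStats(str(col), x.size, y.size, u, p, np.nan, delta, mag, a)
        )
    out = pd.DataFrame([vars(r) for r in rows]).set_index("feature_id")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out
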
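"""End-to-end orchestration of the three baseline contrasts.

Given a binned matrix (or spectra), per-sample clinical metadata and a
marker panel, runs

1. the estrogen-receptor contrast on the whole cohort: normalization,
   PCA-CA-kNN with leave-one-out CV, permutation significance and loading
   analysis of the first canonical component;
2. the pathological-response contrast within the ER+ arm: the same
   classifier plus univariate marker screening (Wilcoxon/BH, Cliff's
   delta, AUROC) and the TNF-alpha + valine linear fusion model;
3. the relapse contrast within the ER+ arm: the metabolomics classifier,
   the IL-2 + IL-10 linear combination, and the logic-OR fusion of the
   two, summarized as a confusion table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chemometrics as chemo
from . import fusion as fus
from . import markers as mk
from .binning import (
    BinnedMatrix,
    BinningScheme,
    PLASMA_CPMG_SCHEME,
    exclude_matrix_bins,
    total_integral_normalize,
)

POSITIVE_CLASS = {"er_status": "ER+", "response": "GR", "relapse": "yes"}


@dataclass
class AnalysisConfig:
    label: str
    positive_class: str | None = None
    n_pc: int | str = "auto"
    k: int = 5
    n_perm: int = 1000
    seed: int = 0
    candidate_pcs: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    top_loadings: int = 20

    def resolved_positive(self) -> str:
        return self.positive_class or POSITIVE_CLASS.get(self.label) or ""


def _subset(matrix: BinnedMatrix, meta: pd.DataFrame, mask) -> tuple[np.ndarray, pd.DataFrame]:
    ids = meta.index[mask]
    row = {s: i for i, s in enumerate(matrix.sample_ids)}
    sel = [row[s] for s in ids]
    return matrix.values[sel], meta.loc[ids]


def classify_contrast(matrix: BinnedMatrix, meta: pd.DataFrame, cfg: AnalysisConfig) -> dict:
    """Classifier block: LOOCV report, permutation p, loading analysis."""
    labels = meta[cfg.label].to_numpy()
    classes, counts = np.unique(labels[~pd.isna(labels)], return_counts=True)
    if classes.size != 2 or counts.min() < 3:
        raise ValueError(
            f"contrast {cfg.label!r} needs two classes with >= 3 samples each; "
            f"got {dict(zip(classes.tolist(), counts.tolist()))}"
        )
    if not matrix.normalized:
        matrix = total_integral_normalize(matrix)
    X = matrix.values
    positive = cfg.resolved_positive()
    if cfg.n_pc == "auto":
        n_pc = chemo.select_n_components(
            X, labels, cfg.k, cfg.candidate_pcs, positive_class=positive
        )
    else:
        n_pc = int(cfg.n_pc)
    report = chemo.loocv(X, labels, n_pc=n_pc, k=cfg.k, positive_class=positive)
    perm = chemo.permutation_test(
        X, labels, n_pc=n_pc, k=cfg.k, n_perm=cfg.n_perm, seed=cfg.seed
    )
    model = chemo.fit(X, labels, n_pc=n_pc, k=cfg.k)
    loadings = chemo.loading_analysis(model, X, labels, bin_centers=matrix.bin_centers)
    top = loadings.rank_order[: cfg.top_loadings]
    return {
        "label": cfg.label,
        "positive_class": positive,
        "n_pc": n_pc,
        "k": cfg.k,
        "loocv": {
            "accuracy": report.accuracy,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "scheme": report.scheme,
        },
        "permutation": {
            "p_value": perm.p_value,
            "n_perm": cfg.n_perm,
            "observed_accuracy": perm.observed_accuracy,
        },
        "top_loadings": [
            {
                "bin_center": float(loadings.bin_centers[i]),
                "weight": float(loadings.loading_weight[i]),
                "higher_in": str(loadings.direction_sign[i]),
            }
            for i in top
        ],
        "_model": model,
        "_loocv_pred": report.per_sample_pred,
    }


def univariate_contrast(
    features: pd.DataFrame, meta: pd.DataFrame, label: str, group1: str, group2: str
) -> pd.DataFrame:
    aligned = features.reindex(meta.index)
    return mk.marker_table(aligned, meta[label].to_numpy(), group1, group2)


def run_full_analysis(
    matrix: BinnedMatrix,
    meta: pd.DataFrame,
    markers: pd.DataFrame | None = None,
    seed: int = 0,
    n_perm: int = 1000,
    k: int = 5,
    n_pc: int | str = "auto",
    fusion_pair: tuple[str, str] = ("TNFa", "valine"),
    relapse_pair: tuple[str, str] = ("IL2", "IL10"),
    scheme: BinningScheme | None = PLASMA_CPMG_SCHEME,
) -> dict:
    """Run the three contrasts and return one JSON-serializable bundle.

    Exclusion windows of `scheme` are applied to the matrix columns before
    normalization (a no-op when the matrix is already filtered).
    """
    ids = list(matrix.sample_ids)
    meta = meta.loc[ids]
    if markers is not None:
        markers = markers.reindex(ids)
    if scheme is not None and not matrix.normalized:
        matrix = exclude_matrix_bins(matrix, scheme)
    norm = matrix if matrix.normalized else total_integral_normalize(matrix)
    bundle: dict = {"n_samples": len(ids), "seed": seed}

    # 1. estrogen-receptor contrast, whole cohort
    er_cfg = AnalysisConfig("er_status", n_pc=n_pc, k=k, n_perm=n_perm, seed=seed)
    er = classify_contrast(norm, meta, er_cfg)
    bundle["er_contrast"] = _public(er)

    # 2. pathological response within the ER+ arm
    er_pos = meta["er_status"] == "ER+"
    Xp, meta_p = _subset(norm, meta, er_pos)
    sub = BinnedMatrix(Xp, norm.bin_centers, tuple(meta_p.index), normalized=True)
    resp_cfg = AnalysisConfig("response", n_pc=n_pc, k=k, n_perm=n_perm, seed=seed + 1)
    resp = classify_contrast(sub, meta_p, resp_cfg)
    bundle["response_contrast"] = _public(resp)

    if markers is not None:
        stats_df = univariate_contrast(markers.loc[meta_p.index], meta_p, "response", "GR", "PR")
        bundle["response_univariate"] = stats_df.reset_index().to_dict(orient="records")
        f1, f2 = fusion_pair
        model = fus.fit_linear_combo(
            markers.loc[meta_p.index, f1],
            markers.loc[meta_p.index, f2],
            meta_p["response"].to_numpy(),
            positive_class="GR",
            feature_ids=fusion_pair,
        )
        score = fus.score_linear_combo(
            model, markers.loc[meta_p.index, f1], markers.loc[meta_p.index, f2]
        )
        okf = np.isfinite(score)
        bundle["response_fusion"] = {
            "features": list(fusion_pair),
            "weights_pct": [round(100 * w, 1) for w in model.weights],
            "threshold": model.threshold,
            "auroc_resubstitution": mk.auroc(
                score[okf], meta_p["response"].to_numpy()[okf], "GR"
            ),
        }

        # 3. relapse within the ER+ arm: cytokine combo OR metabolomics model
        rel_cfg = AnalysisConfig("relapse", n_pc=n_pc, k=k, n_perm=n_perm, seed=seed + 2)
        rel = classify_contrast(sub, meta_p, rel_cfg)
        bundle["relapse_contrast"] = _public(rel)
        g1, g2 = relapse_pair
        cyt_model = fus.fit_linear_combo(
            markers.loc[meta_p.index, g1],
            markers.loc[meta_p.index, g2],
            meta_p["relapse"].to_numpy(),
            positive_class="yes",
            feature_ids=relapse_pair,
        )
        cyt_pred = fus.predict_linear_combo(
            cyt_model, markers.loc[meta_p.index, g1], markers.loc[meta_p.index, g2]
        )
        met_pred = (rel["_loocv_pred"] == "yes").astype(float)
        or_pred = fus.logic_or_predict(
            pd.Series(cyt_pred, index=meta_p.index),
            pd.Series(met_pred, index=meta_p.index),
        )
        truth = (meta_p["relapse"] == "yes").astype(int)
        summary = fus.confusion(or_pred.to_numpy(), truth.to_numpy(), 1)
        bundle["relapse_fusion"] = {
            "cytokine_weights_pct": [round(100 * w, 1) for w in cyt_model.weights],
            "logic_or": dataclasses.asdict(summary),
        }
    return bundle


def _public(block: dict) -> dict:
    return {k: v for k, v in block.items() if not k.startswith("_")}
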
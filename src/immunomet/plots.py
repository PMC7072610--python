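"""Score and loading plots for fitted PCA-CA-kNN models."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .chemometrics import LoadingReport, PcaCaKnnModel  # noqa: E402


def score_plot(model: PcaCaKnnModel, X, labels, path=None):
    """Canonical score plot: CV1 against the first residual PC direction.

    For a two-group model there is a single canonical axis; the second
    plotted axis is the leading principal direction of the PC scores after
    orthogonalization against CV1 (display only — classification uses the
    canonical dimensions alone).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    pc = (X - model.column_means) @ model.pca_loadings
    cv1_dir = model.ca_directions[:, 0]
    cv1 = pc @ cv1_dir
    if model.ca_directions.shape[1] > 1:
        second = pc @ model.ca_directions[:, 1]
        ylab = "CV2"
    else:
        resid = pc - np.outer(cv1, cv1_dir) / (cv1_dir @ cv1_dir)
        _, _, vt = np.linalg.svd(resid - resid.mean(axis=0), full_matrices=False)
        second = resid @ vt[0]
        ylab = "residual PC1"
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls in np.unique(labels):
        m = labels == cls
        ax.scatter(cv1[m], second[m], label=str(cls), alpha=0.8)
    ax.set_xlabel("CV1")
    ax.set_ylabel(ylab)
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def loading_plot(report: LoadingReport, path=None, highlight_top: int = 20):
    """First-canonical-component loading weights along the ppm axis."""
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.vlines(report.bin_centers, 0, report.loading_weight, lw=1, color="0.6")
    top = report.rank_order[:highlight_top]
    ax.vlines(report.bin_centers[top], 0, report.loading_weight[top], lw=1.5, color="C3")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("chemical shift (ppm)")
    ax.set_ylabel("CV1 loading")
    ax.invert_xaxis()  # NMR convention: ppm decreasing to the right
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig
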
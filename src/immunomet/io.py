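"""Readers and writers for the pipeline's plain-text formats.

All tables are comma-separated UTF-8 with a header row; the first column is
the sample id; an empty cell means missing.  Binned matrices carry bucket
centers in the header as ``bin_<center>`` formatted to three decimals.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binning import BinnedMatrix, BinningScheme, SCHEME_PROFILES

logger = logging.getLogger(__name__)


def read_spectrum_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (ppm, intensity) text file; whitespace or comma
    delimited, '#' comments allowed."""
    text = Path(path).read_text()
    delim = "," if "," in text.splitlines()[0] else None
    arr = np.loadtxt(path, delimiter=delim, comments="#")
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    return arr[:, 0], arr[:, 1]


def read_feature_table(path) -> pd.DataFrame:
    """Read a samples x features CSV (first column sample_id, '' = missing)."""
    df = pd.read_csv(path, index_col=0, dtype=str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample_id(s): {dups}")
    cols = {}
    for col in df.columns:
        try:
            cols[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric cell in column {col!r}: {exc}") from exc
    out = pd.DataFrame(cols, index=df.index.astype(str))
    n_missing = int(out.isna().sum().sum())
    if n_missing:
        logger.info("%s: %d missing cell(s)", path, n_missing)
    return out


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, index_col=0, dtype=str)
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample_id(s) in metadata")
    meta.index = meta.index.astype(str)
    return meta


def write_binned_matrix(matrix: BinnedMatrix, path) -> None:
    cols = [f"bin_{c:.3f}" for c in matrix.bin_centers]
    df = pd.DataFrame(matrix.values, index=list(matrix.sample_ids), columns=cols)
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.10g")


def read_binned_matrix(path, normalized: bool = False) -> BinnedMatrix:
    df = read_feature_table(path)
    centers = np.array([float(c.removeprefix("bin_")) for c in df.columns])
    return BinnedMatrix(
        values=df.to_numpy(dtype=float),
        bin_centers=centers,
        sample_ids=tuple(df.index),
        normalized=normalized,
    )


def load_scheme(source) -> BinningScheme:
    """Resolve a binning scheme from a profile name or a YAML mapping/file."""
    if isinstance(source, BinningScheme):
        return source
    if isinstance(source, str) and source in SCHEME_PROFILES:
        return SCHEME_PROFILES[source]
    if isinstance(source, (str, Path)):
        source = yaml.safe_load(Path(source).read_text())
    return BinningScheme(
        range_low=float(source["range_low"]),
        range_high=float(source["range_high"]),
        bin_width=float(source["bin_width"]),
        exclusion_regions=tuple(
            tuple(map(float, r)) for r in source.get("exclusion_regions", [])
        ),
    )


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    canon = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_report(report: dict, path, seed=None, config=None) -> None:
    """Write a JSON report with the run manifest (seed, config hash) embedded."""
    bundle = dict(report)
    bundle["manifest"] = {
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "config": config,
    }
    Path(path).write_text(json.dumps(bundle, indent=1, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    return str(obj)
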
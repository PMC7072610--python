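"""Synthetic HER2-positive plasma cohort generator.

Emulates the statistical structure the analysis pipeline assumes, so every
stage can be exercised without patient data:

* binned CPMG-like plasma spectra (0.2-10.0 ppm, 0.02-ppm buckets) built
  from a synthetic template profile (Lorentzian bumps at common plasma
  metabolite shifts) with multiplicative log-normal bucket noise and
  group-dependent fold changes in named lipid/lipoprotein ppm windows;
* log-normal cytokine/metabolite marker panels with class-dependent
  log-shifts and arm-wise block missingness (e.g. TNF-alpha unmeasured in
  38% of one arm);
* clinical labels (estrogen-receptor arm, pathological response, relapse),
  either with fixed per-arm counts (deterministic mode, for golden tests)
  or drawn from a logistic outcome model on the markers (stochastic mode,
  for power studies).

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import (
    BinnedMatrix,
    BinningScheme,
    PLASMA_CPMG_SCHEME,
    bin_centers,
    make_bins,
)

ARM_COL, RESPONSE_COL, RELAPSE_COL = "er_status", "response", "relapse"


@dataclass(frozen=True)
class MarkerSpec:
    """One panel analyte: log-normal baseline plus class-keyed log shifts.

    `effects` entries are (label_column, class_value, shift): the shift is
    added to the log-mean for samples of that class.  `missing` maps an arm
    value to the fraction of that arm left unmeasured.  distribution
    "normal" interprets (log_mean, log_sd) as raw-scale mean/sd instead
    (useful when an exactly Gaussian marker is wanted).
    """

    name: str
    log_mean: float
    log_sd: float
    effects: tuple[tuple[str, str, float], ...] = ()
    missing: tuple[tuple[str, float], ...] = ()
    distribution: str = "lognormal"

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")
        for _, frac in self.missing:
            if not 0 <= frac <= 1:
                raise ValueError("missing fractions must lie in [0, 1]")
        if self.distribution not in ("lognormal", "normal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    n_er_neg: int = 21
    n_er_pos: int = 22
    scheme: BinningScheme = PLASMA_CPMG_SCHEME
    #: (ppm_low, ppm_high, multiplicative fold, label_column, class_value)
    effect_regions: tuple[tuple[float, float, float, str, str], ...] = ()
    bin_noise_cv: float = 0.25
    noise_model: str = "lognormal"  # or "gaussian" (additive)
    markers: tuple[MarkerSpec, ...] = ()
    #: arm -> (n complete responders, n partial responders); must sum to arm n
    response_counts: tuple[tuple[str, tuple[int, int]], ...] = (
        ("ER-", (13, 8)),
        ("ER+", (11, 11)),
    )
    #: arm -> number of relapsers
    relapse_counts: tuple[tuple[str, int], ...] = (("ER-", 3), ("ER+", 8))
    #: optional logistic outcome model: label_col -> (marker names, coefs,
    #: intercept); when present, that label is drawn stochastically from the
    #: markers and any marker effects keyed to it are ignored.
    outcome_model: tuple[tuple[str, tuple[tuple[str, ...], tuple[float, ...], float]], ...] = ()

    def __post_init__(self) -> None:
        if min(self.n_er_neg, self.n_er_pos) < 4:
            raise ValueError("need at least 4 samples per arm")
        if self.bin_noise_cv <= 0:
            raise ValueError("bin_noise_cv must be positive")
        for low, high, fold, _, _ in self.effect_regions:
            if fold <= 0:
                raise ValueError("effect folds must be positive")
            lo, hi = min(low, high), max(low, high)
            if hi <= self.scheme.range_low or lo >= self.scheme.range_high:
                raise ValueError(f"effect region ({low}, {high}) outside binning range")
        counts = dict(self.response_counts)
        sizes = {"ER-": self.n_er_neg, "ER+": self.n_er_pos}
        for arm, (n_gr, n_pr) in counts.items():
            if n_gr + n_pr != sizes[arm]:
                raise ValueError(f"response counts for {arm} must sum to the arm size")
        for arm, n_rel in dict(self.relapse_counts).items():
            if not 0 <= n_rel <= sizes[arm]:
                raise ValueError(f"relapse count for {arm} exceeds the arm size")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scheme"] = dataclasses.asdict(self.scheme)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        sch = d.pop("scheme")
        sch["exclusion_regions"] = tuple(tuple(r) for r in sch["exclusion_regions"])
        markers = tuple(
            MarkerSpec(
                **{
                    **m,
                    "effects": tuple(tuple(e) for e in m["effects"]),
                    "missing": tuple(tuple(x) for x in m["missing"]),
                }
            )
            for m in d.pop("markers")
        )
        return cls(
            scheme=BinningScheme(**sch),
            markers=markers,
            effect_regions=tuple(tuple(r) for r in d.pop("effect_regions")),
            response_counts=tuple((a, tuple(c)) for a, c in d.pop("response_counts")),
            relapse_counts=tuple(tuple(r) for r in d.pop("relapse_counts")),
            outcome_model=tuple(
                (k, (tuple(v[0]), tuple(v[1]), v[2])) for k, v in d.pop("outcome_model")
            ),
            **d,
        )


@dataclass
class SyntheticCohort:
    matrix: BinnedMatrix  # all scheme buckets, pre-exclusion, unnormalized
    meta: pd.DataFrame
    markers: pd.DataFrame
    ground_truth: dict


# ---------------------------------------------------------------------------
# Template profile
# ---------------------------------------------------------------------------

#: (center ppm, half-width ppm, amplitude) of the synthetic plasma template:
#: Lorentzian bumps at common plasma metabolite/lipoprotein shifts (lipid
#: CH3/CH2, lactate, alanine, acetate, glutamine, citrate, creatinine,
#: choline, glucose, anomeric glucose, tyrosine, histidine, formate).
_TEMPLATE_PEAKS = (
    (0.87, 0.030, 8.0),
    (1.28, 0.040, 12.0),
    (1.33, 0.015, 6.0),
    (1.48, 0.015, 2.0),
    (1.92, 0.012, 1.5),
    (2.10, 0.030, 2.0),
    (2.44, 0.020, 1.5),
    (2.55, 0.012, 2.0),
    (2.65, 0.012, 2.0),
    (3.03, 0.012, 2.5),
    (3.20, 0.015, 2.0),
    (3.40, 0.040, 3.0),
    (3.55, 0.030, 3.0),
    (3.75, 0.040, 3.5),
    (3.90, 0.020, 2.0),
    (4.10, 0.015, 1.5),
    (5.24, 0.012, 1.5),
    (6.90, 0.012, 0.4),
    (7.19, 0.012, 0.4),
    (7.80, 0.012, 0.3),
    (8.46, 0.008, 0.2),
)


def template_profile(centers: np.ndarray) -> np.ndarray:
    """Positive per-bucket baseline intensity of the synthetic plasma template."""
    centers = np.asarray(centers, dtype=float)
    out = np.full_like(centers, 0.05)
    for c, w, a in _TEMPLATE_PEAKS:
        out += a * w**2 / (w**2 + (centers - c) ** 2)
    return out


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _assign_counts(rng, index, values_counts):
    """Randomly assign categorical values with exact counts."""
    out = np.empty(len(index), dtype=object)
    order = rng.permutation(len(index))
    start = 0
    for value, count in values_counts:
        out[order[start : start + count]] = value
        start += count
    return out


def _draw_labels(spec: CohortSpec, rng) -> pd.DataFrame:
    arms = ["ER-"] * spec.n_er_neg + ["ER+"] * spec.n_er_pos
    n = len(arms)
    meta = pd.DataFrame(
        {ARM_COL: arms},
        index=pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample_id"),
    )
    logistic = dict(spec.outcome_model)
    resp = pd.Series(index=meta.index, dtype=object)
    rel = pd.Series(index=meta.index, dtype=object)
    for arm, (n_gr, n_pr) in dict(spec.response_counts).items():
        idx = meta.index[meta[ARM_COL] == arm]
        if RESPONSE_COL not in logistic:
            resp.loc[idx] = _assign_counts(rng, idx, [("GR", n_gr), ("PR", n_pr)])
    for arm, n_rel in dict(spec.relapse_counts).items():
        idx = meta.index[meta[ARM_COL] == arm]
        if RELAPSE_COL not in logistic:
            rel.loc[idx] = _assign_counts(
                rng, idx, [("yes", n_rel), ("no", len(idx) - n_rel)]
            )
    meta[RESPONSE_COL] = resp
    meta[RELAPSE_COL] = rel
    return meta


def _draw_markers(spec: CohortSpec, meta: pd.DataFrame, rng) -> pd.DataFrame:
    logistic_labels = set(dict(spec.outcome_model))
    cols = {}
    for m in spec.markers:
        shift = np.zeros(len(meta))
        for label_col, cls, delta in m.effects:
            if label_col in logistic_labels:
                continue  # label is an outcome of the markers in logistic mode
            shift += np.where(meta[label_col].to_numpy() == cls, delta, 0.0)
        noise = rng.normal(0.0, m.log_sd, size=len(meta))
        if m.distribution == "lognormal":
            vals = np.exp(m.log_mean + shift + noise)
        else:
            vals = m.log_mean + shift + noise
        for arm, frac in m.missing:
            in_arm = meta[ARM_COL].to_numpy() == arm
            drop = in_arm & (rng.random(len(meta)) < frac)
            vals = np.where(drop, np.nan, vals)
        cols[m.name] = vals
    return pd.DataFrame(cols, index=meta.index)


def _logistic_outcomes(spec, meta, markers, rng) -> None:
    pos_value = {RESPONSE_COL: "GR", RELAPSE_COL: "yes"}
    neg_value = {RESPONSE_COL: "PR", RELAPSE_COL: "no"}
    for label_col, (names, coefs, intercept) in dict(spec.outcome_model).items():
        eta = np.full(len(meta), float(intercept))
        for name, beta in zip(names, coefs):
            z = markers[name].to_numpy()
            z = (z - np.nanmean(z)) / np.nanstd(z)
            eta += beta * np.nan_to_num(z)
        p = 1.0 / (1.0 + np.exp(-eta))
        draw = rng.random(len(meta)) < p
        meta[label_col] = np.where(draw, pos_value[label_col], neg_value[label_col])


def _draw_spectra(spec: CohortSpec, meta: pd.DataFrame, rng) -> BinnedMatrix:
    bins = make_bins(spec.scheme)
    centers = bin_centers(bins)
    base = template_profile(centers)
    folds = np.ones((len(meta), centers.size))
    for low, high, fold, label_col, cls in spec.effect_regions:
        lo, hi = min(low, high), max(low, high)
        hit = (np.minimum(bins[:, 1], hi) - np.maximum(bins[:, 0], lo)) > 1e-9
        in_class = meta[label_col].to_numpy() == cls
        folds[np.ix_(in_class, hit)] *= fold
    signal = base[None, :] * folds
    if spec.noise_model == "lognormal":
        # mean-one multiplicative log-normal noise with CV = bin_noise_cv
        sigma = np.sqrt(np.log1p(spec.bin_noise_cv**2))
        values = signal * np.exp(rng.normal(-sigma**2 / 2, sigma, size=signal.shape))
    elif spec.noise_model == "gaussian":
        values = signal + rng.normal(0.0, spec.bin_noise_cv * signal)
    else:
        raise ValueError(f"unknown noise_model {spec.noise_model!r}")
    return BinnedMatrix(
        values=values,
        bin_centers=centers,
        sample_ids=tuple(meta.index),
        normalized=False,
    )


def generate(spec: CohortSpec, seed: int = 0) -> SyntheticCohort:
    """Draw one cohort from the spec, fully reproducible under the seed."""
    rng = np.random.default_rng(seed)
    meta = _draw_labels(spec, rng)
    markers = _draw_markers(spec, meta, rng)
    if spec.outcome_model:
        _logistic_outcomes(spec, meta, markers, rng)
    matrix = _draw_spectra(spec, meta, rng)
    truth = {"seed": int(seed), "spec": spec.to_dict()}
    return SyntheticCohort(matrix=matrix, meta=meta, markers=markers, ground_truth=truth)


# ---------------------------------------------------------------------------
# Default cohort
# ---------------------------------------------------------------------------

#: ppm windows in which the estrogen-receptor contrast shifts intensity
#: (lipoprotein/cholesterol/creatinine-associated regions, ER+ higher).
ER_EFFECT_REGIONS = (
    (3.55, 3.57),
    (3.17, 3.19),
    (2.05, 2.23),
    (1.23, 1.37),
    (0.83, 0.91),
)

#: Default multiplicative fold applied to the ER+ arm in those windows.  With
#: bucket-noise CV 0.25 the per-bucket log effect is about one noise SD,
#: which spread over the ~27 affected buckets gives a clearly separable but
#: noisy multivariate contrast.
DEFAULT_ER_FOLD = 1.3
DEFAULT_BIN_NOISE_CV = 0.25


def default_markers() -> tuple[MarkerSpec, ...]:
    """Cytokine/metabolite panel with effect sizes in the published regime.

    Log-shifts are sized analytically from the normal-theory link between a
    standardized shift d and the rank statistics (AUROC = Phi(d/sqrt(2)),
    Cliff's delta = 2*AUROC - 1): valine d = 1.6 (delta ~ 0.75, higher in
    partial responders), TNF-alpha d = 1.5 (higher in complete responders),
    IL-2 d = 1.2 (delta ~ 0.6, lower in relapsers), IL-10 a small shift in
    the same direction.  TNF-alpha is unmeasured in 38% of the ER- arm.
    """
    return (
        MarkerSpec("valine", np.log(230.0), 0.40, effects=((RESPONSE_COL, "PR", 0.64),)),
        MarkerSpec("isoleucine", np.log(60.0), 0.40, effects=((RESPONSE_COL, "PR", 0.40),)),
        MarkerSpec("alanine", np.log(350.0), 0.35, effects=((RESPONSE_COL, "PR", 0.20),)),
        MarkerSpec("tyrosine", np.log(55.0), 0.35),
        MarkerSpec(
            "TNFa",
            np.log(8.0),
            0.50,
            effects=((RESPONSE_COL, "GR", 0.75),),
            missing=(("ER-", 0.38),),
        ),
        MarkerSpec("IL2", np.log(12.0), 0.50, effects=((RELAPSE_COL, "yes", -0.60),)),
        MarkerSpec("IL10", np.log(5.0), 0.50, effects=((RELAPSE_COL, "yes", -0.20),)),
        MarkerSpec("IL6", np.log(6.0), 0.50),
    )


def default_cohort_spec() -> CohortSpec:
    """The default study-like cohort: 21 ER- / 22 ER+ samples, ER fold
    changes in the five lipoprotein windows, the default marker panel, and
    deterministic response/relapse counts (13/8, 11/11; 3 and 8 relapsers).
    """
    return CohortSpec(
        effect_regions=tuple(
            (lo, hi, DEFAULT_ER_FOLD, ARM_COL, "ER+") for lo, hi in ER_EFFECT_REGIONS
        ),
        bin_noise_cv=DEFAULT_BIN_NOISE_CV,
        markers=default_markers(),
    )


def null_cohort_spec(n_per_arm: int = 21) -> CohortSpec:
    """A no-signal cohort: identical class parameters everywhere."""
    return CohortSpec(
        n_er_neg=n_per_arm,
        n_er_pos=n_per_arm,
        effect_regions=(),
        bin_noise_cv=DEFAULT_BIN_NOISE_CV,
        markers=tuple(
            MarkerSpec(m.name, m.log_mean, m.log_sd, effects=(), missing=m.missing)
            for m in default_markers()
        ),
        response_counts=(
            ("ER-", (n_per_arm // 2, n_per_arm - n_per_arm // 2)),
            ("ER+", (n_per_arm // 2, n_per_arm - n_per_arm // 2)),
        ),
        relapse_counts=(("ER-", n_per_arm // 3), ("ER+", n_per_arm // 3)),
    )


# ---------------------------------------------------------------------------
# Two-marker reference draw for fusion-weight recovery
# ---------------------------------------------------------------------------

def two_marker_cohort(
    w1_target: float = 0.784,
    total_d: float = 2.3,
    n_per_class: int = 100,
    seed: int = 0,
):
    """Two independent unit-variance Gaussian markers with a known optimal mix.

    The positive class is shifted by d_i = w_i * total_d on marker i; for
    independent equal-variance Gaussians the AUROC-optimal linear weights
    are proportional to the shifts, so the population optimum is exactly
    (w1_target, 1 - w1_target).  Returns (x1, x2, labels, optimal_weights).
    """
    if not 0 < w1_target < 1:
        raise ValueError("w1_target must be in (0, 1)")
    d1, d2 = w1_target * total_d, (1 - w1_target) * total_d
    rng = np.random.default_rng(seed)
    n = n_per_class
    labels = np.array(["neg"] * n + ["pos"] * n)
    x1 = np.concatenate([rng.normal(0, 1, n), rng.normal(d1, 1, n)])
    x2 = np.concatenate([rng.normal(0, 1, n), rng.normal(d2, 1, n)])
    return x1, x2, labels, (w1_target, 1 - w1_target)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write matrix.csv, meta.csv, cytokines.csv and truth.json to a directory."""
    from . import io as iom
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iom.write_binned_matrix(cohort.matrix, out / "matrix.csv")
    cohort.meta.to_csv(out / "meta.csv")
    cohort.markers.to_csv(out / "cytokines.csv")
    (out / "truth.json").write_text(json.dumps(cohort.ground_truth, indent=1))


def read_truth(path) -> dict:
    truth = json.loads(open(path).read())
    CohortSpec.from_dict(truth["spec"])  # validates the round-trip
    return truth
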
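"""Spectral bucketing of processed 1D plasma NMR spectra.

Input spectra are assumed already Fourier-transformed, phased,
baseline-corrected and chemical-shift calibrated.  This module turns them
into a samples x bins feature matrix: fixed-width bucketing over a ppm
range, removal of buckets overlapping solvent/additive regions (residual
water, dextrose, citrate), trapezoidal integration on the native ppm grid,
and total-integral normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

logger = logging.getLogger(__name__)

#: Overlap shorter than this (ppm) counts as boundary touching, not overlap.
_OVERLAP_TOL = 1e-9


@dataclass(frozen=True)
class Spectrum:
    """A processed 1D spectrum: chemical-shift axis (ppm) plus intensities.

    The ppm axis must be strictly monotone; descending axes (the common NMR
    display convention) are reversed on construction so that downstream code
    always sees an ascending axis.
    """

    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if ppm.ndim != 1 or inten.ndim != 1 or ppm.size != inten.size:
            raise ValueError("ppm and intensity must be 1-D and equal length")
        if ppm.size < 2:
            raise ValueError("spectrum needs at least two points")
        d = np.diff(ppm)
        if np.all(d < 0):  # descending axis -> store ascending
            ppm, inten = ppm[::-1], inten[::-1]
        elif not np.all(d > 0):
            raise ValueError("ppm axis must be strictly monotone")
        if not (np.isfinite(ppm).all() and np.isfinite(inten).all()):
            raise ValueError("spectrum contains non-finite values")
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", inten)


def _normalize_interval(a: float, b: float) -> tuple[float, float]:
    lo, hi = (a, b) if a <= b else (b, a)
    return float(lo), float(hi)


@dataclass(frozen=True)
class BinningScheme:
    """Fixed-width bucketing scheme with exclusion windows.

    Exclusion windows may be given in either ppm order (spectroscopists
    usually quote them high-to-low); they are normalized to (low, high).
    """

    range_low: float
    range_high: float
    bin_width: float
    exclusion_regions: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.range_low < self.range_high:
            raise ValueError("range_low must be below range_high")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        regions = tuple(_normalize_interval(*r) for r in self.exclusion_regions)
        clipped = tuple(
            (max(lo, self.range_low), min(hi, self.range_high)) for lo, hi in regions
        )
        object.__setattr__(self, "exclusion_regions", clipped)


#: Default plasma CPMG profile: 0.2-10.0 ppm in 0.02-ppm buckets, dropping the
#: residual-water window (4.39-6.00 ppm) and the dextrose/citrate windows.
PLASMA_CPMG_SCHEME = BinningScheme(
    range_low=0.20,
    range_high=10.00,
    bin_width=0.02,
    exclusion_regions=(
        (4.39, 6.00),
        (3.71, 3.91),
        (3.23, 3.55),
        (2.51, 2.69),
        (1.15, 1.19),
    ),
)

SCHEME_PROFILES = {"plasma_cpmg": PLASMA_CPMG_SCHEME}


def make_bins(scheme: BinningScheme) -> np.ndarray:
    """Tile [range_low, range_high) with half-open buckets of bin_width.

    Returns an (n, 2) array of (left, right) edges, left-closed/right-open,
    on the lattice range_low + i * bin_width.
    """
    span = scheme.range_high - scheme.range_low
    n = int(np.ceil(span / scheme.bin_width - _OVERLAP_TOL))
    edges = scheme.range_low + np.arange(n + 1) * scheme.bin_width
    return np.column_stack([edges[:-1], edges[1:]])


def apply_exclusions(
    bins: np.ndarray, exclusion_regions
) -> tuple[np.ndarray, np.ndarray]:
    """Drop every bucket that overlaps an exclusion window with positive measure.

    Boundary touching does not remove a bucket.  Returns (retained_bins,
    keep_mask) with input order preserved.
    """
    bins = np.asarray(bins, dtype=float)
    keep = np.ones(len(bins), dtype=bool)
    for region in exclusion_regions:
        lo, hi = _normalize_interval(*region)
        overlap = np.minimum(bins[:, 1], hi) - np.maximum(bins[:, 0], lo)
        keep &= overlap <= _OVERLAP_TOL
    return bins[keep], keep


def bin_centers(bins: np.ndarray) -> np.ndarray:
    bins = np.asarray(bins, dtype=float)
    return bins.mean(axis=1)


def integrate_bins(spectrum: Spectrum, bins: np.ndarray) -> np.ndarray:
    """Trapezoidal area of the spectrum over each bucket, on the native grid.

    The spectrum is treated as piecewise linear between its sampled points;
    bucket edges falling between grid points are handled by linear
    interpolation, so integration is exact for the piecewise-linear model and
    additive across adjacent buckets.
    """
    bins = np.asarray(bins, dtype=float)
    lo, hi = bins.min(), bins.max()
    if spectrum.ppm[0] > lo + _OVERLAP_TOL or spectrum.ppm[-1] < hi - _OVERLAP_TOL:
        raise ValueError(
            f"spectrum axis [{spectrum.ppm[0]:.3f}, {spectrum.ppm[-1]:.3f}] does not "
            f"cover the binning range [{lo:.3f}, {hi:.3f}]"
        )
    edges = np.unique(bins.ravel())
    grid = np.union1d(spectrum.ppm, edges)
    grid = grid[(grid >= spectrum.ppm[0]) & (grid <= spectrum.ppm[-1])]
    vals = np.interp(grid, spectrum.ppm, spectrum.intensity)
    cum = np.concatenate([[0.0], cumulative_trapezoid(vals, grid)])
    integral = lambda x: np.interp(x, grid, cum)  # noqa: E731
    areas = integral(bins[:, 1]) - integral(bins[:, 0])
    if (areas < -_OVERLAP_TOL).any():
        logger.warning(
            "%d bin area(s) are negative (baseline artifacts integrated as-is)",
            int((areas < -_OVERLAP_TOL).sum()),
        )
    return areas


@dataclass(frozen=True)
class BinnedMatrix:
    """Samples x spectral buckets, with bucket centers and normalization flag."""

    values: np.ndarray
    bin_centers: np.ndarray
    sample_ids: tuple[str, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        centers = np.asarray(self.bin_centers, dtype=float)
        ids = tuple(str(s) for s in self.sample_ids)
        if values.shape != (len(ids), centers.size):
            raise ValueError("values shape must be (n_samples, n_bins)")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "bin_centers", centers)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def bin_spectra(
    spectra: dict[str, Spectrum], scheme: BinningScheme = PLASMA_CPMG_SCHEME
) -> BinnedMatrix:
    """Bucket a set of spectra: make bins, drop exclusions, integrate each."""
    bins = make_bins(scheme)
    retained, _ = apply_exclusions(bins, scheme.exclusion_regions)
    rows = [integrate_bins(s, retained) for s in spectra.values()]
    return BinnedMatrix(
        values=np.vstack(rows),
        bin_centers=bin_centers(retained),
        sample_ids=tuple(spectra.keys()),
        normalized=False,
    )


def exclude_matrix_bins(
    matrix: BinnedMatrix, scheme: BinningScheme = PLASMA_CPMG_SCHEME
) -> BinnedMatrix:
    """Drop matrix columns whose bucket overlaps a scheme exclusion window.

    Bucket intervals are reconstructed from the stored centers and the
    scheme's width, so the same positive-measure overlap rule applies.
    Idempotent on an already-filtered matrix.
    """
    half = scheme.bin_width / 2
    bins = np.column_stack([matrix.bin_centers - half, matrix.bin_centers + half])
    _, keep = apply_exclusions(bins, scheme.exclusion_regions)
    if keep.all():
        return matrix
    return replace(
        matrix, values=matrix.values[:, keep], bin_centers=matrix.bin_centers[keep]
    )


def total_integral_normalize(matrix: BinnedMatrix) -> BinnedMatrix:
    """Divide each sample's bucket vector by its own sum (dilution correction).

    Idempotent up to floating point; raises if any row sums to <= 0.
    """
    sums = matrix.values.sum(axis=1)
    if (sums <= 0).any():
        bad = [matrix.sample_ids[i] for i in np.flatnonzero(sums <= 0)]
        raise ValueError(f"non-positive total integral for sample(s): {bad}")
    if (matrix.values < 0).any():
        warnings.warn("negative bin areas present before normalization")
    return replace(matrix, values=matrix.values / sums[:, None], normalized=True)
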
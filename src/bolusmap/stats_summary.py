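"""Histograms, distribution moments and chi-square histogram comparison.

Moments follow the population (divisor n) convention with Fisher-Pearson
skewness ``g1 = m3 / m2**1.5`` and non-excess kurtosis ``m4 / m2**2``
(a normal sample prints kurtosis near 3).  They are computed on the raw
per-voxel marker values, not on binned frequencies, so they are invariant
to the binning choice.

Two normalized histograms are compared with a symmetric frequency-based
chi-square, ``chi2 = sum (fa - fb)**2 / (fa + fb)`` over bins with any
mass, with ``df = (occupied bins) - 1`` and an upper-tail p-value.  A
goodness-of-fit variant (second histogram as the expected distribution) is
available via ``method="gof"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import MarkerMap

__all__ = [
    "MarkerHistogram",
    "HistogramMetrics",
    "HistogramComparison",
    "build_histogram",
    "histogram_metrics",
    "compare_histograms",
]


@dataclass
class MarkerHistogram:
    """Normalized frequency distribution of one marker."""

    bin_edges: np.ndarray
    frequencies: np.ndarray
    n_values: int
    kind: str

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.bin_edges.ndim != 1 or len(self.bin_edges) != len(self.frequencies) + 1:
            raise ValueError("need m+1 edges for m frequencies")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if (self.frequencies < 0).any():
            raise ValueError("frequencies must be nonnegative")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        if self.n_values < 1:
            raise ValueError("n_values must be >= 1")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "frequency": self.frequencies,
            }
        )


@dataclass
class HistogramMetrics:
    mean: float
    median: float
    skewness: float
    kurtosis: float


@dataclass
class HistogramComparison:
    chi2: float
    p_value: float
    df: int
    bins_compared: int


def build_histogram(
    marker: MarkerMap,
    bin_width: float | None = None,
    value_range: tuple[float, float] | None = None,
    n_bins: int = 20,
) -> MarkerHistogram:
    """Bin present marker values into a normalized frequency histogram.

    Defaults per kind: ``toa`` uses bins of width ``dt`` from 0 to the
    largest value; ``toa_norm``/``slope_norm`` use ``n_bins`` equal bins on
    [0, 1]; ``slope`` uses ``n_bins`` equal bins on [0, max].  Values equal
    to the top edge land in the last bin.
    """
    vals = marker.present_values
    if vals.size == 0:
        raise ValueError("empty marker map")
    if bin_width is not None and not bin_width > 0:
        raise ValueError("bin_width must be > 0")

    if value_range is not None:
        lo, hi = float(value_range[0]), float(value_range[1])
    elif marker.kind in ("toa_norm", "slope_norm"):
        lo, hi = 0.0, 1.0
    else:
        lo, hi = 0.0, float(vals.max())
    if marker.kind == "toa" and bin_width is None and value_range is None:
        bin_width = marker.dt

    if bin_width is not None:
        m = max(1, math.ceil((hi - lo) / bin_width - 1e-9))
        edges = lo + bin_width * np.arange(m + 1)
    else:
        if hi <= lo:
            hi = lo + 1.0  # degenerate all-equal values: one unit-wide bin
        edges = np.linspace(lo, hi, n_bins + 1)

    counts, _ = np.histogram(vals, bins=edges)
    return MarkerHistogram(
        bin_edges=edges,
        frequencies=counts / vals.size,
        n_values=int(vals.size),
        kind=marker.kind,
    )


def histogram_metrics(marker: MarkerMap) -> HistogramMetrics:
    """Mean, median, skewness and (non-excess) kurtosis of the raw values."""
    vals = marker.present_values
    if vals.size < 2:
        raise ValueError("need at least 2 present values")
    if np.ptp(vals) == 0:
        raise ValueError("zero variance: moments are undefined")
    return HistogramMetrics(
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        skewness=float(stats.skew(vals, bias=True)),
        kurtosis=float(stats.kurtosis(vals, fisher=False, bias=True)),
    )


def _rebin(edges: np.ndarray, freqs: np.ndarray, new_edges: np.ndarray) -> np.ndarray:
    """Redistribute bin mass onto a new edge grid proportional to overlap."""
    out = np.zeros(len(new_edges) - 1)
    for lo, hi, f in zip(edges[:-1], edges[1:], freqs):
        if f == 0:
            continue
        width = hi - lo
        for j in range(len(out)):
            ov = min(hi, new_edges[j + 1]) - max(lo, new_edges[j])
            if ov > 0:
                out[j] += f * ov / width
    return out


def compare_histograms(
    a: MarkerHistogram,
    b: MarkerHistogram,
    method: str = "symmetric",
    n_bins: int | None = None,
) -> HistogramComparison:
    """Chi-square comparison of two normalized marker histograms.

    Both histograms are first rebinned onto a common grid spanning the
    union of their ranges with ``n_bins`` bins (default: the larger of the
    two bin counts).  ``method="symmetric"`` uses
    ``sum (fa - fb)**2 / (fa + fb)`` over occupied bins;
    ``method="gof"`` treats ``b`` as the expected distribution
    (``sum (fa - fb)**2 / fb`` over bins where ``fb > 0``).
    """
    if a.kind != b.kind:
        raise ValueError(f"incompatible marker kinds: {a.kind} vs {b.kind}")
    if method not in ("symmetric", "gof"):
        raise ValueError("method must be 'symmetric' or 'gof'")
    m = n_bins or max(len(a.frequencies), len(b.frequencies))
    lo = min(a.bin_edges[0], b.bin_edges[0])
    hi = max(a.bin_edges[-1], b.bin_edges[-1])
    grid = np.linspace(lo, hi, m + 1)
    fa = _rebin(a.bin_edges, a.frequencies, grid)
    fb = _rebin(b.bin_edges, b.frequencies, grid)

    if method == "symmetric":
        occ = (fa + fb) > 0
        chi2 = float(np.sum((fa[occ] - fb[occ]) ** 2 / (fa[occ] + fb[occ])))
    else:
        occ = fb > 0
        if not occ.any():
            raise ValueError("expected histogram has zero support on the grid")
        chi2 = float(np.sum((fa[occ] - fb[occ]) ** 2 / fb[occ]))
    df = max(1, int(occ.sum()) - 1)
    p = float(stats.chi2.sf(chi2, df))
    return HistogramComparison(
        chi2=chi2, p_value=p, df=df, bins_compared=int(occ.sum())
    )
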
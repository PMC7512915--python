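"""Symbolization of continuous series.

Raw continuous measurements become categorical inputs in three steps:
an optional stationarity transform (percent change or first difference),
optional downsampling at the lag of the first minimum of the average
mutual information (AMI), and maximum-entropy partitioning — equal-frequency
quantization into a finite alphabet, which maximizes the empirical symbol
entropy among interval partitions of the same size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import CatfusionError, DegeneratePartitionError, ZeroEntropyError
from .series import CategoricalSeries

__all__ = [
    "PartitionScheme",
    "max_entropy_partition",
    "apply_partition",
    "ami_first_minimum",
    "downsample",
    "transform",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartitionScheme:
    """Interval partition of the real line into an alphabet.

    ``edges`` are the n_bins-1 interior cut points (strictly increasing);
    bins are right-closed and a value equal to an edge goes to the lower
    bin.
    """

    edges: tuple
    n_bins: int
    method: str = "equal-frequency"

    def __post_init__(self):
        edges = tuple(float(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        if len(edges) != self.n_bins - 1:
            raise CatfusionError("need n_bins - 1 interior edges")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise DegeneratePartitionError("edges must be strictly increasing")

    def codes(self, values):
        """Map values to 0-based bin codes (monotone in the values)."""
        return np.searchsorted(np.asarray(self.edges), np.asarray(values, dtype=float),
                               side="left").astype(np.int64)


def max_entropy_partition(values, n_bins, name="y"):
    """Equal-frequency (maximum-entropy) quantization into ``n_bins`` symbols.

    Interior edges sit at the empirical i/n_bins quantiles. Bin occupancies
    are as equal as the data allow (they differ only through ties and
    divisibility).

    Returns
    -------
    (CategoricalSeries, PartitionScheme)
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise CatfusionError("values must be a non-empty 1-d array")
    if n_bins < 2:
        raise CatfusionError("n_bins must be >= 2")
    if np.unique(values).size < n_bins:
        raise DegeneratePartitionError(
            f"need at least {n_bins} distinct values for {n_bins} bins"
        )
    qs = np.arange(1, n_bins) / n_bins
    edges = np.quantile(values, qs)
    if np.any(np.diff(edges) <= 0):
        raise DegeneratePartitionError(
            "ties collapse some quantile edges; reduce n_bins"
        )
    scheme = PartitionScheme(edges=tuple(edges), n_bins=n_bins)
    series = CategoricalSeries(scheme.codes(values), n_bins, name=name)
    return series, scheme


def apply_partition(values, scheme, name="y"):
    """Quantize new values with an existing partition."""
    return CategoricalSeries(scheme.codes(values), scheme.n_bins, name=name)


def _hist_mi(a, b, bins):
    """Histogram plug-in estimate of the mutual information I(a; b) in nats."""
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))


def ami_first_minimum(values, max_lag, n_hist_bins=None):
    """Lag at the first minimum of the average mutual information.

    I(lag) is the histogram MI between the series and its lag-shifted copy,
    for lag = 1..max_lag, with I(0) taken as the marginal entropy. Returns
    the smallest lag m with I(m) < I(m-1) and I(m) <= I(m+1); when no such
    interior minimum exists the argmin over the scanned range is returned
    with a logged warning. The histogram uses ceil(sqrt(n)) equal-width
    bins by default.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n <= max_lag + 1:
        raise CatfusionError("series too short for the requested max_lag")
    if np.all(values == values[0]):
        raise ZeroEntropyError("constant series has zero entropy")
    if n_hist_bins is None:
        n_hist_bins = int(np.ceil(np.sqrt(n)))

    counts, _ = np.histogram(values, bins=n_hist_bins)
    p = counts[counts > 0] / n
    I = np.empty(max_lag + 1)
    I[0] = float(-(p * np.log(p)).sum())  # marginal entropy
    for lag in range(1, max_lag + 1):
        I[lag] = _hist_mi(values[:-lag], values[lag:], n_hist_bins)
    for m in range(1, max_lag):
        if I[m] < I[m - 1] and I[m] <= I[m + 1]:
            return m
    best = int(np.argmin(I[1:])) + 1
    logger.warning(
        "no interior AMI minimum up to lag %d; returning argmin lag %d",
        max_lag, best,
    )
    return best


def downsample(values, step):
    """Keep every ``step``-th element, starting from the first."""
    if step < 1:
        raise CatfusionError("step must be >= 1")
    return np.asarray(values)[::step]


def transform(values, mode):
    """Stationarity transform; output is one element shorter.

    ``percent_change``: 100 * (v[t] - v[t-1]) / v[t-1]  (errors on zeros in
    the denominator); ``difference``: v[t] - v[t-1].
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise CatfusionError("need at least two values to transform")
    if mode == "difference":
        return np.diff(values)
    if mode == "percent_change":
        denom = values[:-1]
        if np.any(denom == 0):
            raise CatfusionError("percent_change undefined: zero value in the series")
        return 100.0 * np.diff(values) / denom
    raise CatfusionError(f"unknown transform mode {mode!r}")
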
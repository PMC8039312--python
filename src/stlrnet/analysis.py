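"""Weight-distribution analysis: histograms, mode detection, branch fractions,
weight/input similarity and output discrimination.

The scientific readout of a training run is the pooled synaptic-weight
histogram and its mode structure: Hebbian training of similar context
sequences yields two modes (enhanced vs. untouched weights), the
spatiotemporal rule yields a positive and a negative dominant mode for a
repeated frame and additional modes — one neighbourhood per distinct input
frame — for a different-context sequence.  Modality is made machine-checkable
by a fixed procedure: moving-average smoothing of the histogram counts
followed by peak detection with a relative prominence floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial.distance import squareform

from .patterns import PatternSet
from .plasticity import normalized_state

__all__ = [
    "WeightDistribution",
    "ModeReport",
    "SubsetFractions",
    "SimilarityReport",
    "weight_histogram",
    "count_modes",
    "subset_fractions",
    "hebbian_step_magnitude",
    "weight_input_similarity",
    "output_discrimination_matrix",
    "mean_offdiagonal",
]


@dataclass(frozen=True)
class WeightDistribution:
    """Pooled synaptic-weight histogram."""

    bin_edges: np.ndarray
    counts: np.ndarray
    source: Literal["raw", "normalized"] = "raw"

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        if len(edges) != len(counts) + 1:
            raise ValueError("bin_edges must have len(counts)+1 entries")
        if not (np.diff(edges) > 0).all():
            raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ModeReport:
    """Detected peak structure of a weight histogram."""

    n_modes: int
    mode_locations: np.ndarray  # bin centers, ascending
    prominences: np.ndarray  # aligned with mode_locations
    smooth_window: int
    min_prominence_frac: float

    def __post_init__(self):
        locs = np.asarray(self.mode_locations, dtype=float)
        proms = np.asarray(self.prominences, dtype=float)
        if self.n_modes != len(locs) or len(locs) != len(proms):
            raise ValueError("inconsistent mode report")
        object.__setattr__(self, "mode_locations", locs)
        object.__setattr__(self, "prominences", proms)

    def top_modes(self, k: int = 2) -> np.ndarray:
        """Locations of the ``k`` most prominent modes."""
        order = np.argsort(self.prominences)[::-1][:k]
        return self.mode_locations[order]


@dataclass(frozen=True)
class SubsetFractions:
    """Per-neuron fractions of active synapses in each plasticity branch.

    ``q`` (enhancement) + ``r`` (invariance) + ``p`` (attenuation) = 1
    exactly for every neuron with at least one active synapse; neurons
    without active synapses carry NaN.
    """

    q: np.ndarray
    r: np.ndarray
    p: np.ndarray


def weight_histogram(
    w,
    source: Literal["raw", "normalized"] = "raw",
    n_bins: int = 50,
    columns=None,
) -> WeightDistribution:
    """Histogram of pooled synaptic weights.

    Parameters
    ----------
    w : (n_out, n_in) array
        Weight matrix.
    source : {"raw", "normalized"}
        Pool raw weights or row-normalized weights ``w̃_ij = w_ij/|W_i|``.
    n_bins : int
        Number of equal-width bins over the pooled range.
    columns : bool mask or index array, optional
        Restrict pooling to these input columns (e.g. the synapses whose
        input was active at least once during training); default pools all.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.size == 0:
        raise ValueError("weight matrix must be 2-D and non-empty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if source == "normalized":
        norms = np.linalg.norm(w, axis=1, keepdims=True)
        if (norms == 0).any():
            raise ValueError("cannot normalize zero-norm weight rows")
        w = w / norms
    elif source != "raw":
        raise ValueError(f"source must be 'raw' or 'normalized', got {source!r}")
    pooled = w if columns is None else w[:, columns]
    if pooled.size == 0:
        raise ValueError("column selection left no weights to pool")
    counts, edges = np.histogram(pooled.ravel(), bins=n_bins)
    return WeightDistribution(edges, counts, source=source)


def count_modes(
    d: WeightDistribution,
    smooth_window: int = 5,
    min_prominence_frac: float = 0.10,
) -> ModeReport:
    """Count histogram modes: smooth, then find prominent local maxima.

    The counts are smoothed with a centered moving average of
    ``smooth_window`` bins (zero-padded, so peaks at the histogram edges are
    detectable), and local maxima with prominence at least
    ``min_prominence_frac`` of the maximum smoothed count are reported.
    Deterministic, and invariant to rescaling all counts by a constant.
    """
    if smooth_window < 1 or not 0 < min_prominence_frac < 1:
        raise ValueError("smooth_window must be >= 1 and min_prominence_frac in (0,1)")
    counts = d.counts.astype(float)
    if smooth_window > len(counts):
        raise ValueError(
            f"smooth_window ({smooth_window}) exceeds histogram length ({len(counts)})"
        )
    pad = smooth_window
    padded = np.concatenate([np.zeros(pad), counts, np.zeros(pad)])
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(padded, kernel, mode="same")
    if smoothed.max() <= 0:
        return ModeReport(0, np.empty(0), np.empty(0), smooth_window, min_prominence_frac)
    peaks, props = find_peaks(smoothed, prominence=min_prominence_frac * smoothed.max())
    # keep peaks that map into the real histogram (padding can hold no peak)
    keep = (peaks >= pad) & (peaks < pad + len(counts))
    peaks = peaks[keep] - pad
    proms = props["prominences"][keep]
    centers = d.centers[peaks]
    return ModeReport(len(peaks), centers, proms, smooth_window, min_prominence_frac)


def subset_fractions(coincidence, x, theta1: float, theta2: float) -> SubsetFractions:
    """Per-neuron enhancement/invariance/attenuation fractions.

    Classifies the coincidence coefficients of active synapses against the
    two thresholds and returns the per-neuron fractions ``q`` (>= theta1),
    ``r`` (between) and ``p`` (<= theta2); ``p`` is computed as ``1 - q - r``
    so the three sum to exactly 1.  Neurons with no active synapse get NaN.
    """
    if not theta1 > theta2:
        raise ValueError(f"theta1 ({theta1}) must be strictly greater than theta2 ({theta2})")
    coincidence = np.asarray(coincidence, dtype=float)
    x = np.asarray(x)
    active = x > 0
    n_active = int(active.sum())
    n_out = coincidence.shape[0]
    if n_active == 0:
        nan = np.full(n_out, np.nan)
        return SubsetFractions(nan.copy(), nan.copy(), nan.copy())
    sub = coincidence[:, active]
    q = (sub >= theta1).sum(axis=1) / n_active
    r = ((sub < theta1) & (sub > theta2)).sum(axis=1) / n_active
    p = 1.0 - (q + r)  # parenthesized so q + r + p == 1.0 holds exactly
    return SubsetFractions(q, r, p)


def hebbian_step_magnitude(x, y, dw: float) -> np.ndarray:
    """Per-neuron total Hebbian weight change, ``ΔŴ_i = y_i (Σ_j x_j) δw``.

    Equals the row-sum of the weight change of one Hebbian update exactly:
    a firing neuron potentiates one synapse per active input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return y * x.sum() * dw


@dataclass(frozen=True)
class SimilarityReport:
    """Cosine similarity of each weight row against each spatial pattern."""

    similarity: np.ndarray  # (n_out, k)
    best_pattern: np.ndarray  # (n_out,) argmax pattern index
    assignment_counts: np.ndarray  # (k,) neurons best-matching each pattern


def weight_input_similarity(w, ps: PatternSet | Sequence) -> SimilarityReport:
    """Cosine of every weight row against every pattern, with argmax assignment."""
    w = np.asarray(w, dtype=float)
    patterns = ps.matrix if isinstance(ps, PatternSet) else np.asarray(ps)
    patterns = patterns.astype(float)
    if w.shape[1] != patterns.shape[1]:
        raise ValueError("weight columns and pattern length differ")
    wn = np.linalg.norm(w, axis=1)
    pn = np.linalg.norm(patterns, axis=1)
    if (wn == 0).any() or (pn == 0).any():
        raise ValueError("zero-norm weight row or pattern")
    sims = (w / wn[:, None]) @ (patterns / pn[:, None]).T
    best = sims.argmax(axis=1)
    counts = np.bincount(best, minlength=patterns.shape[0])
    return SimilarityReport(sims, best, counts)


def output_discrimination_matrix(outputs) -> np.ndarray:
    """Pairwise Hamming distances between binary output vectors.

    Identical outputs across training conditions signal pattern completion
    (zero matrix); large off-diagonal distances signal discrimination.
    """
    arr = np.asarray(outputs)
    if arr.ndim != 2:
        raise ValueError("expected a (n_conditions, n_neurons) stack of outputs")
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("outputs must be binary")
    a = arr.astype(np.int64)
    m = len(a)
    dist = np.zeros((m, m), dtype=np.int64)
    for i in range(m):
        for j in range(i + 1, m):
            dist[i, j] = dist[j, i] = int(np.count_nonzero(a[i] != a[j]))
    return dist


def mean_offdiagonal(dist: np.ndarray) -> float:
    """Mean of the off-diagonal entries of a square distance matrix."""
    dist = np.asarray(dist, dtype=float)
    m = len(dist)
    if m < 2:
        return 0.0
    return float(squareform(dist, checks=False).mean())
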
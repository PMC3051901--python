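"""Hybridization and positional features for (segment, sample) pairs.

Three feature families describe how a segment hybridizes in one sample:

* ``f_abs`` — five local percentiles (P20, P40, P50, P60, P80) of the 3n
  pooled probe-by-replicate log2 intensities;
* ``f_rel`` — a 5-bin soft histogram of those intensities against five
  global percentiles, with linear interpolation between neighboring bins;
* ``f_pos`` — a 10-bin soft histogram of probe distances to the 3' end of
  the spliced transcript, one unit of weight per probe.

Percentiles use linear interpolation between closest order statistics
everywhere (numpy's default), stated once here and reused.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

__all__ = [
    "GlobalPercentiles",
    "SegmentFeatureVector",
    "ExpressionBinning",
    "PERCENTILE_LEVELS",
    "POSITION_LIMITS",
    "interp_histogram",
    "compute_global_percentiles",
    "compute_abs_features",
    "compute_rel_features",
    "compute_pos_features",
    "probe_distances_to_3prime",
    "fit_expression_binning",
]

PERCENTILE_LEVELS = (20.0, 40.0, 50.0, 60.0, 80.0)
POSITION_LIMITS = tuple(float(x) for x in range(100, 2000, 200))  # 100..1900
N_BINS_EXPRESSION = 10


@dataclass(frozen=True)
class GlobalPercentiles:
    """P20/P40/P50/P60/P80 of all genic probe intensities, all samples pooled."""

    values: np.ndarray  # shape (5,), non-decreasing

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (5,):
            raise ValueError(f"expected 5 percentiles, got shape {v.shape}")
        if np.any(np.diff(v) < 0):
            raise ValueError("percentiles must be non-decreasing")
        object.__setattr__(self, "values", v)


@dataclass
class SegmentFeatureVector:
    f_abs: np.ndarray  # (5,)
    f_rel: np.ndarray  # (5,)
    f_pos: np.ndarray  # (10,)

    def concat(self) -> np.ndarray:
        return np.concatenate([self.f_abs, self.f_rel, self.f_pos])


@dataclass(frozen=True)
class ExpressionBinning:
    """Ten expression strata delimited by the P10..P90 percentiles."""

    limits: np.ndarray  # shape (9,), non-decreasing

    def __post_init__(self) -> None:
        v = np.asarray(self.limits, dtype=float)
        if v.shape != (9,):
            raise ValueError(f"expected 9 limits, got shape {v.shape}")
        if np.any(np.diff(v) < 0):
            raise ValueError("limits must be non-decreasing")
        object.__setattr__(self, "limits", v)

    def bin_index(self, values: np.ndarray | float) -> np.ndarray:
        """1-based bin: 1 + number of limits strictly below the value."""
        v = np.asarray(values, dtype=float)
        return np.searchsorted(self.limits, v, side="left") + 1


def interp_histogram(values: np.ndarray, limits: np.ndarray) -> np.ndarray:
    """Soft histogram with linear interpolation between neighboring limits.

    Each value contributes total weight 1.  Values at or below the first
    limit load bin 1; values above the last limit load bin N; a value with
    L_k <= v < L_{k+1} splits weight alpha = (L_{k+1} - v)/(L_{k+1} - L_k)
    onto bin k and 1 - alpha onto bin k+1.  Cases are evaluated in that
    order, first match wins (so v == L_1 goes entirely to bin 1).
    """
    v = np.asarray(values, dtype=float).ravel()
    limits = np.asarray(limits, dtype=float)
    n_bins = len(limits)
    out = np.zeros(n_bins)
    if v.size == 0:
        return out
    low = v <= limits[0]
    high = v > limits[-1]
    mid = ~(low | high)
    out[0] += np.count_nonzero(low)
    out[-1] += np.count_nonzero(high)
    if np.any(mid):
        vm = v[mid]
        k = np.searchsorted(limits, vm, side="right") - 1
        k = np.clip(k, 0, n_bins - 2)
        width = limits[k + 1] - limits[k]
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(width > 0, (limits[k + 1] - vm) / width, 1.0)
        np.add.at(out, k, alpha)
        np.add.at(out, k + 1, 1.0 - alpha)
    return out


def compute_global_percentiles(values: np.ndarray) -> GlobalPercentiles:
    """Global L = (P20, P40, P50, P60, P80) of pooled genic intensities."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 5:
        raise ValueError("need at least 5 intensity values")
    return GlobalPercentiles(np.percentile(v, PERCENTILE_LEVELS))


def compute_abs_features(segment_values: np.ndarray) -> np.ndarray:
    """Five local percentiles of the segment's pooled 3n measurements."""
    v = np.asarray(segment_values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("segment has no measurements")
    return np.percentile(v, PERCENTILE_LEVELS)


def compute_rel_features(
    segment_values: np.ndarray, global_percentiles: GlobalPercentiles
) -> np.ndarray:
    """5-bin interpolated histogram against the global percentiles.

    Components sum to the number of measurements (n probes x 3 replicates).
    """
    v = np.asarray(segment_values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("segment has no measurements")
    return interp_histogram(v, global_percentiles.values)


def compute_pos_features(distances: np.ndarray) -> np.ndarray:
    """10-bin interpolated histogram of probe 3'-distances (one unit/probe)."""
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("segment has no probes")
    return interp_histogram(d, np.asarray(POSITION_LIMITS))


def probe_distances_to_3prime(
    probe_starts: np.ndarray,
    exons: list[tuple[int, int]],
    strand: str,
    probe_length: int = 25,
) -> np.ndarray:
    """Distance from each probe center to the transcript 3' end.

    Every probe is projected onto the spliced-transcript coordinate: exonic
    probes get their exact spliced distance, intronic probes collapse onto
    the spliced position of the intron boundary.  A single projection for
    both segment kinds keeps the positional features free of class
    information (a genomic-distance fallback for intronic probes would be
    systematically larger than neighboring exonic distances).
    """
    starts = np.asarray(probe_starts, dtype=int)
    centers = starts + probe_length // 2
    exons = sorted(exons)
    g3 = exons[-1][1] - 1 if strand == "+" else exons[0][0]

    def cumexon(x: int) -> int:
        # number of exonic bases at positions < x
        return sum(max(0, min(ee, x) - es) for es, ee in exons if es < x)

    out = np.empty(len(centers), dtype=float)
    for i, c in enumerate(centers):
        if strand == "+":
            spliced = cumexon(g3 + 1) - cumexon(c + 1)
        else:
            spliced = cumexon(c) - cumexon(g3)
        out[i] = float(max(spliced, 0))
    return out


def fit_expression_binning(values: np.ndarray) -> ExpressionBinning:
    """Limits = P10..P90 of pooled per-gene per-sample expression medians."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < N_BINS_EXPRESSION:
        raise ValueError(
            f"need at least {N_BINS_EXPRESSION} values, got {v.size}"
        )
    limits = np.percentile(v, np.arange(10, 100, 10))
    if len(np.unique(limits)) < len(limits):
        warnings.warn("degenerate expression bins (tied percentile limits)")
    return ExpressionBinning(limits)
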
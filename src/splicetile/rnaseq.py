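"""Coverage-based intron-retention calling and event-set overlap statistics.

Introns are called retained when all three coverage filters hold:

(a) median per-base read coverage in the intron strictly greater than 2;
(b) at least 75% of intronic positions covered by at least one read;
(c) mean intron coverage between 10% and 120% (inclusive) of the average
    flanking-exon coverage, with the two flanking exons within 4-fold of
    each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome import GenomicInterval, Segment

__all__ = [
    "IntronCoverage",
    "OverlapResult",
    "ir_filter",
    "call_ir_events",
    "overlap_stats",
    "read_bedgraph",
    "write_bedgraph",
    "write_bed6",
]

MEDIAN_MIN = 2.0
BREADTH_MIN = 0.75
MEAN_RATIO_LOW = 0.10
MEAN_RATIO_HIGH = 1.20
FLANK_FOLD_MAX = 4.0


@dataclass
class IntronCoverage:
    intron: Segment
    cov: np.ndarray  # per-base depth, length == intron length
    flank5_mean: float
    flank3_mean: float

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        if len(self.cov) != len(self.intron.interval):
            raise ValueError("coverage length != intron length")
        if np.any(self.cov < 0):
            raise ValueError("negative coverage")


@dataclass
class OverlapResult:
    n1: int
    n2: int
    overlap: int
    universe: int
    representation_factor: float
    p_value: float


def ir_filter(ic: IntronCoverage) -> bool:
    """Apply filters (a)-(c); returns True iff every clause holds."""
    if np.median(ic.cov) <= MEDIAN_MIN:  # (a) strict
        return False
    if np.mean(ic.cov >= 1) < BREADTH_MIN:  # (b) inclusive
        return False
    lo, hi = sorted((ic.flank5_mean, ic.flank3_mean))
    if lo <= 0:  # fold ratio undefined
        return False
    if hi / lo > FLANK_FOLD_MAX:  # (c) flank balance, inclusive
        return False
    flank_avg = (ic.flank5_mean + ic.flank3_mean) / 2.0
    mean_cov = float(np.mean(ic.cov))
    return (
        MEAN_RATIO_LOW * flank_avg <= mean_cov <= MEAN_RATIO_HIGH * flank_avg
    )


def call_ir_events(
    coverage: dict[str, np.ndarray],
    introns: list[Segment],
) -> list[Segment]:
    """All annotated introns passing the filter, deduplicated by interval.

    ``coverage`` maps chromosome to a per-base depth array of the merged
    libraries; introns whose flanking exons fall outside the track are
    treated as uncovered.
    """
    called: dict[tuple[str, int, int], Segment] = {}
    for intron in introns:
        iv = intron.interval
        track = coverage.get(iv.chrom)
        if track is None or iv.end > len(track):
            continue
        cov = track[iv.start : iv.end]
        flank5, flank3 = intron.flanking_exons
        f5 = track[flank5.start : flank5.end]
        f3 = track[flank3.start : flank3.end]
        if len(f5) == 0 or len(f3) == 0:
            continue
        ic = IntronCoverage(
            intron, cov, float(np.mean(f5)), float(np.mean(f3))
        )
        if ir_filter(ic):
            key = (iv.chrom, iv.start, iv.end)
            called.setdefault(key, intron)
    return [called[k] for k in sorted(called)]


def overlap_stats(
    set1: set, set2: set, universe_size: int
) -> OverlapResult:
    """Representation factor and hypergeometric upper-tail p of an overlap."""
    n1, n2 = len(set1), len(set2)
    o = len(set1 & set2)
    if n1 > universe_size or n2 > universe_size:
        raise ValueError("set larger than the universe")
    if n1 == 0 or n2 == 0:
        return OverlapResult(n1, n2, o, universe_size, float("nan"), 1.0)
    factor = o * universe_size / (n1 * n2)
    # P(X >= o) for X ~ Hypergeometric(N, n1, n2)
    p = float(stats.hypergeom.sf(o - 1, universe_size, n1, n2))
    return OverlapResult(n1, n2, o, universe_size, factor, p)


# ---------------------------------------------------------------------------
# I/O


def read_bedgraph(path: str, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Read a bedGraph file into per-base depth arrays (0-based half-open)."""
    tracks = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split()[:4]
            if chrom in tracks:
                tracks[chrom][int(start) : int(end)] = float(value)
    return tracks


def write_bedgraph(coverage: dict[str, np.ndarray], path: str) -> None:
    """Write per-base depth arrays as run-length-encoded bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(coverage):
            track = np.asarray(coverage[chrom])
            if len(track) == 0:
                continue
            change = np.nonzero(np.diff(track))[0]
            starts = np.r_[0, change + 1]
            ends = np.r_[change + 1, len(track)]
            for s, e in zip(starts, ends):
                v = track[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_bed6(segments: list[Segment], path: str) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            iv = seg.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{seg.id}\t0\t{iv.strand}\n"
            )
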
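"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own implementations: events are
found by all-pairs transcript comparison, auROC by O(n^2) pairwise
counting, the F statistic from its textbook formula, the hypergeometric
tail by explicit pmf summation, and the soft histogram by a scalar
case-by-case transcription of the piecewise definition.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --- splicing events by all-pairs transcript comparison --------------------


def brute_force_ir(transcripts) -> set[tuple[int, int]]:
    """Intron intervals retained by some other transcript's exon."""
    events = set()
    for t1, t2 in itertools.permutations(transcripts, 2):
        for a, b in zip(t1.exons, t1.exons[1:]):
            intron = (a.end, b.start)
            for e in t2.exons:
                if e.start <= intron[0] and e.end >= intron[1]:
                    events.add(intron)
    return events


def brute_force_es(transcripts) -> set[tuple[int, int]]:
    """Exon intervals skipped by some other transcript, with shared flanks."""
    events = set()
    for t1, t2 in itertools.permutations(transcripts, 2):
        common = {(e.start, e.end) for e in t1.exons} & {
            (e.start, e.end) for e in t2.exons
        }
        for e in t1.exons:
            for a, b in zip(t2.exons, t2.exons[1:]):
                if not (a.end <= e.start and e.end <= b.start):
                    continue
                left = any(ce <= e.start for _, ce in common)
                right = any(cs >= e.end for cs, _ in common)
                if left and right:
                    events.add((e.start, e.end))
    return events


# --- auROC by pairwise comparison ------------------------------------------


def pairwise_auroc(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels > labels.min()]
    neg = scores[labels <= labels.min()]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


# --- one-way ANOVA F from the textbook formula ------------------------------


def anova_f_and_p(groups) -> tuple[float, float]:
    from scipy.stats import f as f_dist

    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n - k
    f = (ss_between / df1) / (ss_within / df2)
    return f, float(f_dist.sf(f, df1, df2))


# --- hypergeometric upper tail by explicit summation ------------------------


def hypergeom_upper_tail(o: int, universe: int, n1: int, n2: int) -> float:
    def pmf(x: int) -> float:
        return (
            math.comb(n1, x)
            * math.comb(universe - n1, n2 - x)
            / math.comb(universe, n2)
        )

    lo = max(o, max(0, n1 + n2 - universe))
    hi = min(n1, n2)
    return float(sum(pmf(x) for x in range(lo, hi + 1)))


# --- scalar case-by-case soft histogram -------------------------------------


def soft_histogram_scalar(value: float, limits) -> np.ndarray:
    """Direct transcription of the piecewise interpolation, one value."""
    limits = list(limits)
    n = len(limits)
    out = np.zeros(n)
    if value <= limits[0]:
        out[0] = 1.0
        return out
    if value > limits[-1]:
        out[-1] = 1.0
        return out
    for k in range(n - 1):
        if limits[k] <= value < limits[k + 1]:
            alpha = (limits[k + 1] - value) / (limits[k + 1] - limits[k])
            out[k] = alpha
            out[k + 1] = 1.0 - alpha
            return out
    # value == some interior limit with zero-width interval fallthrough
    out[n - 1] = 1.0
    return out
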
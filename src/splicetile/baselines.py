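"""Unsupervised IR baselines: ANOVA splicing-index test, Ner-Gaon scoring.

The ANOVA baseline divides each sample's probe-by-replicate intensities by
the sample's gene-level median exonic intensity (the splicing index) and
tests the 24 sample groups with a one-way fixed-effects ANOVA.

The modified Ner-Gaon scorer classifies each intron by comparing its mean
signal to the other introns and the exons of the same gene at a grid of
significance levels, and reports N(s) = max_alpha c(s, alpha) + (1 - alpha).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SplicingIndexVectors",
    "NerGaonResult",
    "NERGAON_ALPHA_GRID",
    "splicing_index",
    "anova_ir_test",
    "nergaon_classify",
    "nergaon_score",
]

# 5 logarithmically spaced significance levels on [0.01, 0.5]
NERGAON_ALPHA_GRID = tuple(np.logspace(np.log10(0.01), np.log10(0.5), 5))


@dataclass
class SplicingIndexVectors:
    """Per sample, the segment's 3n intensities over the gene median."""

    groups: list[np.ndarray]  # one array of length 3n per sample


@dataclass
class NerGaonResult:
    classes: dict[float, int]  # alpha -> class
    score: float


def splicing_index(
    segment_values: np.ndarray, gene_medians: np.ndarray
) -> SplicingIndexVectors:
    """Normalize each sample's segment intensities by the gene median.

    ``segment_values`` has shape (n_probes, n_samples, 3) in linear units;
    ``gene_medians`` holds the per-sample median of the gene's constitutive
    exonic probe intensities (linear).
    """
    vals = np.asarray(segment_values, dtype=float)
    med = np.asarray(gene_medians, dtype=float)
    if vals.ndim != 3 or vals.shape[1] != med.shape[0]:
        raise ValueError("shape mismatch between values and gene medians")
    if np.any(med <= 0) or np.any(~np.isfinite(med)):
        raise ValueError("gene median must be positive in every sample")
    groups = [
        (vals[:, t, :] / med[t]).ravel() for t in range(vals.shape[1])
    ]
    return SplicingIndexVectors(groups)


def anova_ir_test(siv: SplicingIndexVectors) -> float:
    """One-way fixed-effects ANOVA p-value across the sample groups."""
    groups = [np.asarray(g, dtype=float) for g in siv.groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 observations each")
    grand = np.concatenate(groups)
    if np.ptp(grand) == 0:
        return 1.0
    within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    if within == 0:
        means = [g.mean() for g in groups]
        return 0.0 if np.ptp(means) > 0 else 1.0
    with np.errstate(invalid="ignore"):
        stat, p = stats.f_oneway(*groups)
    return float(p)


def _welch(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    """Welch two-sample t-test p-value, robust to tiny or constant groups."""
    if len(a) < 2 or len(b) < 2:
        return 1.0
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 1.0
        diff = a[0] - b[0]
        if alternative == "greater":
            return 0.0 if diff > 0 else 1.0
        if alternative == "less":
            return 0.0 if diff < 0 else 1.0
        return 0.0
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.pvalue)


def nergaon_classify(
    intron_values: np.ndarray,
    other_intron_values: np.ndarray | None,
    exon_values: np.ndarray,
    alpha: float,
) -> int:
    """Intron class 0-4 from two pairwise mean comparisons at level alpha.

    Comparisons are Welch tests on log2 intensities pooled over samples and
    replicates.  The class index increases with confidence of retention:

    * 4 — significantly above the other introns and similar to the exons
    * 3 — significantly above the other introns but below the exons
    * 2 — similar to both the other introns and the exons
    * 1 — similar to the other introns only
    * 0 — undifferentiated (no pattern matches, or no other introns)
    """
    iv = np.log2(np.asarray(intron_values, dtype=float).ravel())
    ev = np.log2(np.asarray(exon_values, dtype=float).ravel())
    if other_intron_values is None or len(other_intron_values) == 0:
        return 0
    ov = np.log2(np.asarray(other_intron_values, dtype=float).ravel())
    higher_than_introns = _welch(iv, ov, "greater") < alpha
    similar_to_introns = _welch(iv, ov, "two-sided") >= alpha
    similar_to_exons = _welch(iv, ev, "two-sided") >= alpha
    lower_than_exons = _welch(iv, ev, "less") < alpha
    if higher_than_introns and similar_to_exons:
        return 4
    if higher_than_introns and lower_than_exons:
        return 3
    if similar_to_introns and similar_to_exons:
        return 2
    if similar_to_introns:
        return 1
    return 0


def nergaon_score(
    intron_values: np.ndarray,
    other_intron_values: np.ndarray | None,
    exon_values: np.ndarray,
    alpha_grid: tuple[float, ...] = NERGAON_ALPHA_GRID,
) -> NerGaonResult:
    """N(s) = max over the alpha grid of c(s, alpha) + (1 - alpha)."""
    classes = {
        float(a): nergaon_classify(
            intron_values, other_intron_values, exon_values, a
        )
        for a in alpha_grid
    }
    score = max(c + (1.0 - a) for a, c in classes.items())
    return NerGaonResult(classes, float(score))
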
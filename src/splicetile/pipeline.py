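"""End-to-end orchestration: features, stage 1/2, baselines on a dataset.

These helpers operate on in-memory objects (gene models + ProbeMatrix) and
are shared by the CLI, the test suite, and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arraydata import (
    N_REPLICATES,
    GeneExpression,
    ProbeMatrix,
    _exonic_probe_index,
    assign_probes_to_segments,
    gene_expression,
)
from .baselines import anova_ir_test, nergaon_score, splicing_index
from .features import (
    ExpressionBinning,
    GlobalPercentiles,
    compute_global_percentiles,
    fit_expression_binning,
    interp_histogram,
    probe_distances_to_3prime,
    PERCENTILE_LEVELS,
    POSITION_LIMITS,
)
from .genome import Segment, Transcript, build_splicing_graph, enumerate_segments
from .stage1 import MetaClassifier, predict_inclusion, train_meta_classifier
from .stage2 import Stage2Model, assemble_stage2_features, train_stage2

__all__ = [
    "FeatureSet",
    "segment_universe",
    "compute_gene_expression_table",
    "compute_feature_set",
    "stage1_training_arrays",
    "run_stage1",
    "stage2_feature_matrix",
    "baseline_scores",
]


@dataclass
class FeatureSet:
    """Per-(segment, sample) features for every usable segment of a dataset."""

    segments: list[Segment]
    segment_ids: list[str]
    features: np.ndarray  # (n_segments, n_samples, 20)
    bins: np.ndarray  # (n_segments, n_samples) 1-based expression bins
    usable: np.ndarray  # (n_segments,) has >=1 assigned probe
    n_probes: np.ndarray  # (n_segments,)
    binning: ExpressionBinning
    global_percentiles: GlobalPercentiles
    gene_expr: dict[str, GeneExpression]


def segment_universe(
    genes: dict[str, list[Transcript]]
) -> list[Segment]:
    """All internal exons and introns across the gene set."""
    segments: list[Segment] = []
    for gid in sorted(genes):
        graph = build_splicing_graph(genes[gid])
        segments.extend(enumerate_segments(graph))
    return segments


def compute_gene_expression_table(
    matrix: ProbeMatrix, genes: dict[str, list[Transcript]]
) -> dict[str, GeneExpression]:
    exonic_idx, _ = _exonic_probe_index(matrix, genes)
    out: dict[str, GeneExpression] = {}
    for gid, idx in exonic_idx.items():
        if len(idx) == 0:
            continue
        out[gid] = gene_expression(matrix, gid, idx)
    return out


def compute_feature_set(
    matrix: ProbeMatrix,
    genes: dict[str, list[Transcript]],
    segments: list[Segment] | None = None,
) -> FeatureSet:
    """Compute the 20-dim feature vector for every (segment, sample) pair.

    Layout: f_abs (5) + f_rel (5) + f_pos (10).  Expression bins are fitted
    on the pooled per-gene per-sample medians and assigned per pair through
    the segment's gene.
    """
    if segments is None:
        segments = segment_universe(genes)
    assignment = assign_probes_to_segments(matrix, segments)
    gene_expr = compute_gene_expression_table(matrix, genes)
    log_values = matrix.log2()
    n_samples = matrix.n_samples

    # global percentiles over all unmasked genic probes, all samples pooled
    exonic_idx, genic_idx = _exonic_probe_index(matrix, genes)
    genic_probes = (
        np.unique(np.concatenate([v for v in genic_idx.values() if len(v)]))
        if genic_idx
        else np.arange(matrix.n_probes)
    )
    gp = compute_global_percentiles(log_values[genic_probes])

    pooled_expr = np.concatenate(
        [ge.per_sample for ge in gene_expr.values()]
    )
    binning = fit_expression_binning(pooled_expr)

    # longest isoform per gene for positional features
    longest: dict[str, Transcript] = {}
    for gid, tx in genes.items():
        longest[gid] = max(
            tx, key=lambda t: sum(len(e) for e in t.exons)
        )

    n_seg = len(segments)
    features = np.zeros((n_seg, n_samples, 20))
    bins = np.ones((n_seg, n_samples), dtype=int)
    usable = np.zeros(n_seg, dtype=bool)
    n_probes = np.zeros(n_seg, dtype=int)
    starts = matrix.probes["start"].to_numpy()
    pos_limits = np.asarray(POSITION_LIMITS)

    for i, seg in enumerate(segments):
        idx = assignment[seg.id]
        n_probes[i] = len(idx)
        ge = gene_expr.get(seg.gene_id)
        if len(idx) == 0 or ge is None:
            continue
        usable[i] = True
        vals = log_values[idx]  # (n, S, 3)
        pooled = vals.transpose(1, 0, 2).reshape(n_samples, -1)  # (S, 3n)
        features[i, :, 0:5] = np.percentile(
            pooled, PERCENTILE_LEVELS, axis=1
        ).T
        for t in range(n_samples):
            features[i, t, 5:10] = interp_histogram(pooled[t], gp.values)
        iso = longest[seg.gene_id]
        dists = probe_distances_to_3prime(
            starts[idx], [(e.start, e.end) for e in iso.exons], iso.strand
        )
        features[i, :, 10:20] = interp_histogram(dists, pos_limits)[None, :]
        bins[i] = binning.bin_index(ge.per_sample)

    return FeatureSet(
        segments=segments,
        segment_ids=[s.id for s in segments],
        features=features,
        bins=bins,
        usable=usable,
        n_probes=n_probes,
        binning=binning,
        global_percentiles=gp,
        gene_expr=gene_expr,
    )


def stage1_training_arrays(
    fs: FeatureSet,
    constitutive_ids: set[str],
    max_pairs_per_bin: int | None = None,
    seed: int = 17,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten (segment, sample) pairs of constitutive segments for training.

    Labels: +1 for exon pairs, -1 for intron pairs.
    """
    rows = []
    for i, seg in enumerate(fs.segments):
        if not fs.usable[i] or seg.id not in constitutive_ids:
            continue
        label = 1.0 if seg.kind == "exon" else -1.0
        for t in range(fs.features.shape[1]):
            rows.append((i, t, label))
    if not rows:
        raise ValueError("no constitutive training pairs")
    arr = np.array(rows)
    X = fs.features[arr[:, 0].astype(int), arr[:, 1].astype(int)]
    y = arr[:, 2]
    b = fs.bins[arr[:, 0].astype(int), arr[:, 1].astype(int)]
    if max_pairs_per_bin is not None:
        rng = np.random.default_rng(seed)
        keep = np.zeros(len(y), dtype=bool)
        for bb in np.unique(b):
            idx = np.nonzero(b == bb)[0]
            if len(idx) > max_pairs_per_bin:
                idx = rng.choice(idx, size=max_pairs_per_bin, replace=False)
            keep[idx] = True
        X, y, b = X[keep], y[keep], b[keep]
    return X, y, b


def run_stage1(
    fs: FeatureSet,
    constitutive_ids: set[str],
    seed: int = 17,
    max_pairs_per_bin: int | None = 4000,
) -> tuple[MetaClassifier, np.ndarray]:
    """Train the meta-classifier and predict inclusion for all usable pairs.

    Returns the classifier and the (n_segments, n_samples) inclusion
    probability matrix (NaN for unusable segments).
    """
    X, y, b = stage1_training_arrays(
        fs, constitutive_ids, max_pairs_per_bin, seed
    )
    meta = train_meta_classifier(X, y, b, fs.binning, seed=seed)
    n_seg, n_samples, _ = fs.features.shape
    p = np.full((n_seg, n_samples), np.nan)
    idx = np.nonzero(fs.usable)[0]
    flatX = fs.features[idx].reshape(len(idx) * n_samples, -1)
    flatb = fs.bins[idx].reshape(-1)
    p[idx] = predict_inclusion(meta, flatX, flatb).reshape(len(idx), n_samples)
    return meta, p


def stage2_feature_matrix(
    fs: FeatureSet,
    matrix: ProbeMatrix,
    inclusion: np.ndarray,
    kind: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Stage-2 feature rows for every usable segment of the given kind.

    Returns (row indices into fs.segments, feature matrix of width 2T).
    Flanking-exon expression is the per-sample median log2 intensity of the
    probes contained in the segment's flanking exons; segments whose flanks
    carry no probes fall back to the gene expression medians.
    """
    log_values = matrix.log2()
    n_samples = matrix.n_samples
    flank_segments = []
    flank_owner = []
    for i, seg in enumerate(fs.segments):
        if not fs.usable[i] or seg.kind != kind:
            continue
        for fe in seg.flanking_exons:
            flank_segments.append(
                Segment(seg.gene_id, "exon", fe, (), True)
            )
            flank_owner.append(i)
    assignment = assign_probes_to_segments(matrix, flank_segments)
    flank_probe_idx: dict[int, list[np.ndarray]] = {}
    for seg, owner in zip(flank_segments, flank_owner):
        flank_probe_idx.setdefault(owner, []).append(assignment[seg.id])

    rows = []
    feats = []
    for i, seg in enumerate(fs.segments):
        if not fs.usable[i] or seg.kind != kind:
            continue
        p_row = inclusion[i]
        if np.any(np.isnan(p_row)):
            continue
        idx_list = flank_probe_idx.get(i, [])
        idx = (
            np.concatenate(idx_list)
            if idx_list and sum(len(a) for a in idx_list)
            else np.empty(0, dtype=int)
        )
        if len(idx) > 0:
            fe = np.median(
                log_values[idx].transpose(1, 0, 2).reshape(n_samples, -1),
                axis=1,
            )
        else:
            ge = fs.gene_expr.get(seg.gene_id)
            if ge is None:
                continue
            fe = ge.per_sample
        rows.append(i)
        feats.append(assemble_stage2_features(p_row, fe))
    return np.array(rows, dtype=int), np.vstack(feats)


def baseline_scores(
    fs: FeatureSet,
    matrix: ProbeMatrix,
    genes: dict[str, list[Transcript]],
    kind: str = "intron",
    include_nergaon: bool = True,
    restrict_ids: set[str] | None = None,
) -> pd.DataFrame:
    """ANOVA and Ner-Gaon scores for every usable segment of the kind.

    Returns a table with segment_id, anova_p, anova_score (-log10 p) and
    nergaon_score columns; the two baselines share the segment universe
    with the supervised detector.
    """
    assignment = assign_probes_to_segments(matrix, fs.segments)
    exonic_idx, _ = _exonic_probe_index(matrix, genes)
    lin = matrix.values
    n_samples = matrix.n_samples

    # per-gene per-sample exonic medians (linear) for the splicing index
    gene_median_lin: dict[str, np.ndarray] = {}
    for gid, idx in exonic_idx.items():
        if len(idx):
            gene_median_lin[gid] = np.median(
                lin[idx].transpose(1, 0, 2).reshape(n_samples, -1), axis=1
            )

    # per-gene pooled intron/exon probe sets for Ner-Gaon
    introns_by_gene: dict[str, list[tuple[str, np.ndarray]]] = {}
    for i, seg in enumerate(fs.segments):
        if seg.kind == "intron" and fs.usable[i]:
            introns_by_gene.setdefault(seg.gene_id, []).append(
                (seg.id, assignment[seg.id])
            )

    rows = []
    for i, seg in enumerate(fs.segments):
        if not fs.usable[i] or seg.kind != kind:
            continue
        if restrict_ids is not None and seg.id not in restrict_ids:
            continue
        idx = assignment[seg.id]
        med = gene_median_lin.get(seg.gene_id)
        if med is None:
            continue
        vals = lin[idx]  # (n, S, 3)
        try:
            siv = splicing_index(vals, med)
            p = anova_ir_test(siv)
        except ValueError:
            p = np.nan
        anova_score = -np.log10(max(p, 1e-300)) if np.isfinite(p) else np.nan

        ng = np.nan
        if kind == "intron" and include_nergaon:
            others = [
                a
                for sid, a in introns_by_gene.get(seg.gene_id, [])
                if sid != seg.id and len(a)
            ]
            ex_idx = exonic_idx.get(seg.gene_id, np.empty(0, dtype=int))
            if others and len(ex_idx):
                other_vals = np.concatenate([lin[a].ravel() for a in others])
                ng = nergaon_score(
                    lin[idx].ravel(), other_vals, lin[ex_idx].ravel()
                ).score
        rows.append(
            dict(
                segment_id=seg.id,
                anova_p=p,
                anova_score=anova_score,
                nergaon_score=ng,
            )
        )
    return pd.DataFrame(rows)
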
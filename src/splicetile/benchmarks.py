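"""Self-contained benchmark runs on simulated data.

Shared by the acceptance tests and the acceptance report script: each
function generates its inputs with the simulator, runs the pipeline, and
measures recovery against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import auroc, partial_auroc
from .pipeline import (
    baseline_scores,
    compute_feature_set,
    run_stage1,
    stage1_training_arrays,
    stage2_feature_matrix,
)
from .scs import RatioParams, build_scs_from_table, compute_scs_composition
from .simulate import (
    SimulationConfig,
    default_config,
    easy_config,
    simulate_dataset,
)
from .stage1 import predict_inclusion, train_meta_classifier
from .stage2 import train_stage2

__all__ = [
    "IRBenchmarkResult",
    "run_ir_benchmark",
    "anova_null_pvalues",
    "noiseless_stage1_auroc",
    "noiseless_ir_filter_recovery",
]


@dataclass
class IRBenchmarkResult:
    stage1_auroc: float
    stage2_auroc: float
    stage2_partial_auroc: float  # normalized by the 0.3 FPR window
    anova_partial_auroc: float
    nergaon_partial_auroc: float
    permuted_stage2_auroc: float
    n_genes: int
    n_eval_introns: int
    n_eval_positives: int
    n_scs_positives: int


def run_ir_benchmark(
    n_genes: int = 1500,
    seed: int = 1,
    config: SimulationConfig | None = None,
    max_pairs_per_bin: int = 3000,
) -> IRBenchmarkResult:
    """Train on one half of the genes, measure recovery on the other half.

    Stage 1 is trained on (segment, sample) pairs of the training half,
    excluding sequence-confirmed AS events; its auROC is measured on truly
    constitutive pairs of the held-out half.  Stage 2 is trained on the SCS
    intron set of the training half and evaluated against planted truth on
    the held-out introns, alongside the two unsupervised baselines.
    """
    cfg = config or default_config(n_genes=n_genes, seed=seed)
    sim = simulate_dataset(cfg)
    fs = compute_feature_set(sim.matrix, sim.genes)
    labels = sim.truth.labels
    seg_row = {s: i for i, s in enumerate(fs.segment_ids)}

    gene_ids = sorted(sim.genes)
    train_genes = set(gene_ids[: len(gene_ids) // 2])
    eval_genes = set(gene_ids[len(gene_ids) // 2:])

    # SCS intron set from the training half's confirmation counts
    comp = compute_scs_composition(RatioParams())
    train_table = sim.confirmations[
        sim.confirmations.gene_id.isin(train_genes)
    ]
    scs = build_scs_from_table(
        fs.segments, train_table, "intron", comp.intron_ratio, seed=seed
    )
    scs_positive_ids = {s.id for s in scs.positives}

    # --- stage 1: train on the training half, without confirmed AS events
    train_ids = {
        s.id
        for s in fs.segments
        if s.gene_id in train_genes and s.id not in scs_positive_ids
    }
    X1, y1, b1 = stage1_training_arrays(
        fs, train_ids, max_pairs_per_bin=max_pairs_per_bin, seed=seed
    )
    meta = train_meta_classifier(X1, y1, b1, fs.binning, seed=seed)

    # held-out stage-1 accuracy on truly constitutive eval segments
    eval_const = labels[
        (~labels.is_as) & labels.gene_id.isin(eval_genes)
    ].segment_id
    rows = [seg_row[s] for s in eval_const if fs.usable[seg_row[s]]]
    Xe = fs.features[rows].reshape(len(rows) * fs.features.shape[1], -1)
    be = fs.bins[rows].reshape(-1)
    ye = np.repeat(
        [1.0 if fs.segments[r].kind == "exon" else -1.0 for r in rows],
        fs.features.shape[1],
    )
    pe = predict_inclusion(meta, Xe, be)
    stage1_auc = auroc(pe, ye)

    # inclusion probabilities for every usable segment
    n_seg, n_samples, _ = fs.features.shape
    inclusion = np.full((n_seg, n_samples), np.nan)
    usable_rows = np.nonzero(fs.usable)[0]
    flatX = fs.features[usable_rows].reshape(len(usable_rows) * n_samples, -1)
    flatb = fs.bins[usable_rows].reshape(-1)
    inclusion[usable_rows] = predict_inclusion(meta, flatX, flatb).reshape(
        len(usable_rows), n_samples
    )

    # --- stage 2 on the SCS intron set
    rows2, X2 = stage2_feature_matrix(fs, sim.matrix, inclusion, "intron")
    j_of_id = {fs.segment_ids[r]: j for j, r in enumerate(rows2)}
    train_j, y2 = [], []
    for s in scs.positives:
        if s.id in j_of_id:
            train_j.append(j_of_id[s.id])
            y2.append(1.0)
    for s in scs.negatives:
        if s.id in j_of_id:
            train_j.append(j_of_id[s.id])
            y2.append(-1.0)
    train_j = np.array(train_j)
    y2 = np.array(y2)
    model = train_stage2(X2[train_j], y2, seed=seed)

    # permuted-label null: retrain on shuffled labels, cross-validated auROC
    rng = np.random.default_rng(seed)
    permuted = train_stage2(X2[train_j], rng.permutation(y2), seed=seed)
    permuted_auc = float(np.mean(permuted.fold_aurocs))

    # --- evaluation against planted truth on the held-out half, restricted
    # to the top 50% expressed genes as in the genome-wide screen
    from .arraydata import select_top_expressed_genes

    top_genes = select_top_expressed_genes(list(fs.gene_expr.values()), 0.5)
    truth_ir = set(labels.loc[labels.event_type == "IR", "segment_id"])
    eval_j = [
        j
        for j, r in enumerate(rows2)
        if fs.segments[r].gene_id in eval_genes
        and fs.segments[r].gene_id in top_genes
    ]
    eval_ids = [fs.segment_ids[rows2[j]] for j in eval_j]
    y_eval = np.array([1.0 if s in truth_ir else 0.0 for s in eval_ids])
    scores = model.score(X2[eval_j])

    bl = baseline_scores(
        fs, sim.matrix, sim.genes, kind="intron", restrict_ids=set(eval_ids)
    ).set_index("segment_id")
    anova = bl.loc[eval_ids, "anova_score"].to_numpy()
    nerg = bl.loc[eval_ids, "nergaon_score"].to_numpy()
    ok_a = np.isfinite(anova)
    ok_n = np.isfinite(nerg)

    return IRBenchmarkResult(
        stage1_auroc=float(stage1_auc),
        stage2_auroc=float(auroc(scores, y_eval)),
        stage2_partial_auroc=float(
            partial_auroc(scores, y_eval, normalized=True)
        ),
        anova_partial_auroc=float(
            partial_auroc(anova[ok_a], y_eval[ok_a], normalized=True)
        ),
        nergaon_partial_auroc=float(
            partial_auroc(nerg[ok_n], y_eval[ok_n], normalized=True)
        ),
        permuted_stage2_auroc=permuted_auc,
        n_genes=cfg.n_genes,
        n_eval_introns=len(eval_j),
        n_eval_positives=int(y_eval.sum()),
        n_scs_positives=len(scs.positives),
    )


def anova_null_pvalues(n_genes: int = 420, seed: int = 3) -> np.ndarray:
    """ANOVA p-values for purely constitutive introns under a clean null.

    The null design keeps the ANOVA model's assumptions exactly: no
    per-sample expression shifts, no probe affinity offsets, no positional
    decay; single-probe introns and seven long exons so the gene-median
    denominator is nearly noise-free.
    """
    cfg = default_config(
        n_genes=n_genes,
        r_as=0.0,
        expr_sample_sd=0.0,
        decay_per_kb=0.0,
        affinity_sd=0.0,
        exons_per_gene=7,
        exon_len_range=(450, 530),
        intron_len_range=(60, 68),
        seed=seed,
    )
    sim = simulate_dataset(cfg)
    fs = compute_feature_set(sim.matrix, sim.genes)
    bl = baseline_scores(
        fs, sim.matrix, sim.genes, kind="intron", include_nergaon=False
    )
    return bl["anova_p"].dropna().to_numpy()


def _noiseless_run(n_genes: int, seed: int):
    cfg = easy_config(n_genes=n_genes, seed=seed)
    sim = simulate_dataset(cfg)
    fs = compute_feature_set(sim.matrix, sim.genes)
    return cfg, sim, fs


def noiseless_stage1_auroc(n_genes: int = 120, seed: int = 5) -> float:
    """Held-out stage-1 auROC in the zero-noise, disjoint-signal limit."""
    cfg, sim, fs = _noiseless_run(n_genes, seed)
    labels = sim.truth.labels
    const = set(labels.loc[~labels.is_as, "segment_id"])
    _, inclusion = run_stage1(fs, const, seed=seed, max_pairs_per_bin=1000)
    seg_row = {s: i for i, s in enumerate(fs.segment_ids)}
    rows = [seg_row[s] for s in const if fs.usable[seg_row[s]]]
    p = inclusion[rows].ravel()
    y = np.repeat(
        [1.0 if fs.segments[r].kind == "exon" else -1.0 for r in rows],
        inclusion.shape[1],
    )
    ok = np.isfinite(p)
    return float(auroc(p[ok], y[ok]))


def noiseless_ir_filter_recovery(n_genes: int = 120, seed: int = 5):
    """Fraction of planted fully retained introns passing the RNA-seq filter.

    Returns (n_passing, n_planted).  In the easy preset every planted IR
    intron is fully retained at noise-free coverage, so all must pass.
    """
    from .rnaseq import call_ir_events

    cfg, sim, fs = _noiseless_run(n_genes, seed)
    labels = sim.truth.labels
    # basal fully retained introns (inclusion 1.0 in every sample)
    inc = sim.truth.inclusion
    seg_idx = sim.truth.segment_index
    planted = [
        s
        for s in labels.loc[labels.event_type == "IR", "segment_id"]
        if np.all(inc[seg_idx[s]] == 1.0)
    ]
    introns = [s for s in fs.segments if s.kind == "intron"]
    called = {
        (s.interval.chrom, s.interval.start, s.interval.end)
        for s in call_ir_events(sim.coverage, introns)
    }
    by_id = {s.id: s for s in introns}
    n_pass = sum(
        (
            by_id[s].interval.chrom,
            by_id[s].interval.start,
            by_id[s].interval.end,
        )
        in called
        for s in planted
    )
    return n_pass, len(planted)
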
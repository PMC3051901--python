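"""Synthetic tiling-array datasets with planted IR/ES events.

Generates a toy genome of multi-exon genes, an Affymetrix-like 25-mer probe
layout (~35 bp center-to-center), a 24-sample x 3-replicate hybridization
design (11 tissues plus stress treatment/control pairs), EST/cDNA-style
confirmation counts, and merged per-base coverage tracks — all with ground
truth, so the full pipeline is testable without external data.

Signal model (log2 scale): exonic probes follow gene expression minus a 3'
positional decay; intronic probes follow a background with a configurable
expression-dependent component; a partially included segment mixes the two
linearly in intensity space at its inclusion level.  Per-probe affinity
offsets and Gaussian noise are added on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arraydata import ProbeMatrix, SampleInfo
from .features import probe_distances_to_3prime
from .genome import (
    GenomicInterval,
    Segment,
    Transcript,
    build_splicing_graph,
    enumerate_segments,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedDataset",
    "easy_config",
    "default_config",
    "simulate_dataset",
    "simulate_confirmations",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 200
    exons_per_gene: int = 5
    exon_len_range: tuple[int, int] = (100, 260)
    intron_len_range: tuple[int, int] = (80, 200)
    intergenic_gap: int = 200
    probe_length: int = 25
    probe_spacing: int = 35
    n_tissues: int = 11
    n_stress_pairs: int = 10
    n_controls: int = 3
    replicates: int = 3
    expr_mean: float = 8.0
    expr_sd: float = 1.5
    expr_sample_sd: float = 0.3
    intron_base: float = 4.0  # b0: intron background at zero expression
    intron_slope: float = 0.2  # gamma: expression leakage into introns
    noise_sd_exon: float = 0.5
    noise_sd_intron: float = 0.5
    affinity_sd: float = 0.3
    decay_per_kb: float = 0.3  # 3' positional decay of exonic signal
    r_as: float = 0.30
    ir_fraction: float = 0.75  # AS genes carrying IR (rest carry ES)
    differential_fraction: float = 0.5
    ir_inclusion: float = 0.9
    es_inclusion: float = 0.1
    confirmation_depth: float = 12.0
    confirmation_rate: float = 0.6  # P(a sequence confirms a given segment)
    cdna_fraction: float = 0.2
    coverage_depth: float = 30.0
    coverage_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intron_slope >= 1:
            raise ValueError("intron_slope must be < 1")
        if self.exons_per_gene < 3:
            raise ValueError("need at least 3 exons per gene")
        if self.exon_len_range[0] < self.probe_length:
            raise ValueError("exons must be at least one probe long")

    @property
    def n_samples(self) -> int:
        return self.n_tissues + self.n_stress_pairs + self.n_controls


def easy_config(**overrides) -> SimulationConfig:
    """Noiseless, fully separable preset for exactness tests."""
    base = dict(
        noise_sd_exon=0.0,
        noise_sd_intron=0.0,
        affinity_sd=0.0,
        expr_sample_sd=0.0,
        intron_slope=0.0,
        decay_per_kb=0.0,
        ir_inclusion=1.0,
        es_inclusion=0.0,
        coverage_noise=False,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def default_config(**overrides) -> SimulationConfig:
    """Moderate-noise preset for statistical acceptance checks."""
    return SimulationConfig(**overrides)


@dataclass
class SyntheticTruth:
    """Ground truth for every enumerated segment and gene."""

    segments: list[Segment]
    labels: pd.DataFrame  # segment_id, gene_id, kind, is_as, event_type, regulation
    inclusion: np.ndarray  # (n_segments, n_samples) true inclusion levels
    gene_expr_log2: pd.DataFrame  # genes x samples
    segment_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.segment_index:
            self.segment_index = {
                seg.id: i for i, seg in enumerate(self.segments)
            }


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: dict[str, list[Transcript]]
    matrix: ProbeMatrix
    truth: SyntheticTruth
    confirmations: pd.DataFrame
    coverage: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]


def _make_samples(cfg: SimulationConfig) -> list[SampleInfo]:
    samples = [
        SampleInfo(f"T{i + 1:02d}", "tissue") for i in range(cfg.n_tissues)
    ]
    controls = [f"C{i + 1:02d}" for i in range(cfg.n_controls)]
    samples += [SampleInfo(c, "stress_control") for c in controls]
    samples += [
        SampleInfo(
            f"S{i + 1:02d}",
            "stress_treatment",
            controls[i % cfg.n_controls],
        )
        for i in range(cfg.n_stress_pairs)
    ]
    return samples


def _plant_inclusion(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    samples: list[SampleInfo],
    kind: str,
) -> tuple[np.ndarray, str]:
    """True inclusion level per sample for one planted event."""
    n = len(samples)
    tissue_idx = [
        i for i, s in enumerate(samples) if s.condition_class == "tissue"
    ]
    treat_idx = [
        i
        for i, s in enumerate(samples)
        if s.condition_class == "stress_treatment"
    ]
    on = cfg.ir_inclusion if kind == "IR" else 1.0 - cfg.es_inclusion
    base = 1.0 if kind == "ES" else 0.0  # constitutive inclusion level
    event = 1.0 - on if kind == "ES" else on  # event-state inclusion
    if rng.random() >= cfg.differential_fraction:
        return np.full(n, event), "basal"
    if rng.random() < 0.5:
        # tissue-specific: event state in 2 .. ~half of the tissues
        k = int(rng.integers(2, max(3, len(tissue_idx) // 2 + 2)))
        chosen = rng.choice(tissue_idx, size=k, replace=False)
        inc = np.full(n, base)
        inc[chosen] = event
        return inc, "tissue"
    k = int(rng.integers(2, max(3, len(treat_idx) // 2 + 1)))
    chosen = rng.choice(treat_idx, size=k, replace=False)
    inc = np.full(n, base)
    inc[chosen] = event
    return inc, "stress"


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = _make_samples(cfg)
    n_samples = len(samples)
    chrom = "chr1"

    # --- gene structures -------------------------------------------------
    genes: dict[str, list[Transcript]] = {}
    cursor = cfg.intergenic_gap
    gene_ids: list[str] = []
    for g in range(cfg.n_genes):
        gid = f"G{g + 1:05d}"
        gene_ids.append(gid)
        strand = "+" if rng.random() < 0.5 else "-"
        exon_lens = rng.integers(
            cfg.exon_len_range[0], cfg.exon_len_range[1] + 1, cfg.exons_per_gene
        )
        intron_lens = rng.integers(
            cfg.intron_len_range[0],
            cfg.intron_len_range[1] + 1,
            cfg.exons_per_gene - 1,
        )
        exons = []
        pos = cursor
        for i in range(cfg.exons_per_gene):
            exons.append(
                GenomicInterval(chrom, pos, pos + int(exon_lens[i]), strand)
            )
            pos += int(exon_lens[i])
            if i < cfg.exons_per_gene - 1:
                pos += int(intron_lens[i])
        genes[gid] = [Transcript(f"{gid}.1", gid, exons, "annotation")]
        cursor = pos + cfg.intergenic_gap
    chrom_sizes = {chrom: cursor + cfg.intergenic_gap}

    # --- per-sample gene expression --------------------------------------
    base_expr = rng.normal(cfg.expr_mean, cfg.expr_sd, cfg.n_genes)
    expr = np.empty((cfg.n_genes, n_samples))
    control_col = {s.sample_id: i for i, s in enumerate(samples)}
    for j, s in enumerate(samples):
        if s.condition_class == "stress_treatment":
            continue
        expr[:, j] = base_expr + rng.normal(
            0.0, cfg.expr_sample_sd, cfg.n_genes
        )
    for j, s in enumerate(samples):
        if s.condition_class == "stress_treatment":
            # treatments share their control's expression exactly, so the
            # stress score is isolated from expression confounding
            expr[:, j] = expr[:, control_col[s.control_id]]

    # --- segments and planted events -------------------------------------
    segments: list[Segment] = []
    segments_by_gene: dict[str, list[Segment]] = {}
    label_rows: list[dict] = []
    inclusion_rows: list[np.ndarray] = []
    event_segment_of_gene: dict[str, tuple[str, str, float]] = {}
    for g, gid in enumerate(gene_ids):
        graph = build_splicing_graph(genes[gid])
        gene_segments = enumerate_segments(graph)
        introns = [s for s in gene_segments if s.kind == "intron"]
        internal_exons = [s for s in gene_segments if s.kind == "exon"]
        is_as_gene = rng.random() < cfg.r_as
        event_seg_id = None
        event_type = None
        regulation = None
        event_inc = None
        if is_as_gene:
            if rng.random() < cfg.ir_fraction:
                event_type = "IR"
                target = introns[int(rng.integers(0, len(introns)))]
            else:
                event_type = "ES"
                target = internal_exons[
                    int(rng.integers(0, len(internal_exons)))
                ]
            event_seg_id = target.id
            event_inc, regulation = _plant_inclusion(
                cfg, rng, samples, event_type
            )
            event_segment_of_gene[gid] = (
                event_seg_id,
                event_type,
                float(np.mean(event_inc)),
            )
        for seg in gene_segments:
            constitutive = 1.0 if seg.kind == "exon" else 0.0
            if seg.id == event_seg_id:
                inc = event_inc
                row = dict(
                    segment_id=seg.id,
                    gene_id=gid,
                    kind=seg.kind,
                    is_as=True,
                    event_type=event_type,
                    regulation=regulation,
                )
            else:
                inc = np.full(n_samples, constitutive)
                row = dict(
                    segment_id=seg.id,
                    gene_id=gid,
                    kind=seg.kind,
                    is_as=False,
                    event_type=None,
                    regulation=None,
                )
            segments.append(seg)
            segments_by_gene.setdefault(gid, []).append(seg)
            label_rows.append(row)
            inclusion_rows.append(inc)

    inclusion = np.vstack(inclusion_rows)
    labels = pd.DataFrame(label_rows)
    truth = SyntheticTruth(
        segments=segments,
        labels=labels,
        inclusion=inclusion,
        gene_expr_log2=pd.DataFrame(
            expr, index=gene_ids, columns=[s.sample_id for s in samples]
        ),
    )

    # --- probes and intensities ------------------------------------------
    seg_index = truth.segment_index
    probe_rows: list[tuple[str, str, int, str]] = []
    values_blocks: list[np.ndarray] = []
    probe_counter = 0
    for g, gid in enumerate(gene_ids):
        t = genes[gid][0]
        span = t.span
        starts = np.arange(
            span.start, span.end - cfg.probe_length + 1, cfg.probe_spacing
        )
        if len(starts) == 0:
            continue
        exon_bounds = [(e.start, e.end) for e in t.exons]
        dists = probe_distances_to_3prime(
            starts, exon_bounds, t.strand, cfg.probe_length
        )
        # map each probe to its segment (or terminal exon / none)
        centers = starts + cfg.probe_length // 2
        seg_of_probe = np.full(len(starts), -1, dtype=int)  # truth row or -1
        is_exonic = np.zeros(len(starts), dtype=bool)
        fully_contained = np.zeros(len(starts), dtype=bool)
        for i, s0 in enumerate(starts):
            e0 = s0 + cfg.probe_length
            for es, ee in exon_bounds:
                if es <= centers[i] < ee:
                    is_exonic[i] = True
                    fully_contained[i] = s0 >= es and e0 <= ee
                    break
        graph_segments = segments_by_gene.get(gid, [])
        for i, s0 in enumerate(starts):
            e0 = s0 + cfg.probe_length
            for seg in graph_segments:
                iv = seg.interval
                if s0 >= iv.start and e0 <= iv.end:
                    seg_of_probe[i] = seg_index[seg.id]
                    break
        # signal construction
        e_gt = expr[g]  # (S,)
        exon_sig = e_gt[None, :] - cfg.decay_per_kb * dists[:, None] / 1000.0
        intron_sig = cfg.intron_base + cfg.intron_slope * e_gt[None, :]
        pi = np.empty((len(starts), n_samples))
        for i in range(len(starts)):
            row = seg_of_probe[i]
            if row >= 0:
                pi[i] = inclusion[row]
            else:
                # terminal exons and boundary probes: constitutive behavior
                pi[i] = 1.0 if is_exonic[i] else 0.0
        mix = pi * np.exp2(exon_sig) + (1.0 - pi) * np.exp2(intron_sig)
        log_mean = np.log2(mix)
        affinity = rng.normal(0.0, cfg.affinity_sd, len(starts))
        sd = np.where(is_exonic, cfg.noise_sd_exon, cfg.noise_sd_intron)
        noise = rng.normal(
            0.0, 1.0, (len(starts), n_samples, cfg.replicates)
        ) * sd[:, None, None]
        block = np.exp2(log_mean[:, :, None] + affinity[:, None, None] + noise)
        values_blocks.append(block)
        for s0 in starts:
            probe_counter += 1
            probe_rows.append((f"P{probe_counter:07d}", chrom, int(s0), "+"))

    probes = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "start", "strand"]
    )
    matrix = ProbeMatrix(
        probes=probes,
        values=np.concatenate(values_blocks, axis=0),
        samples=samples,
    )

    # --- confirmation counts ----------------------------------------------
    confirmations = simulate_confirmations(
        cfg, truth, base_expr, event_segment_of_gene, rng
    )

    # --- merged coverage track --------------------------------------------
    coverage = _simulate_coverage(cfg, genes, truth, base_expr, rng, chrom_sizes)

    return SimulatedDataset(
        config=cfg,
        genes=genes,
        matrix=matrix,
        truth=truth,
        confirmations=confirmations,
        coverage=coverage,
        chrom_sizes=chrom_sizes,
    )


def simulate_confirmations(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    base_expr: np.ndarray,
    events: dict[str, tuple[str, str, float]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """EST/cDNA-style confirmation counts per segment.

    Per gene, a Poisson number of sequenced transcripts with rate
    proportional to linear expression; each sequence confirms a given
    segment with probability ``confirmation_rate`` and is a cDNA with
    probability ``cdna_fraction``.  For AS genes the sequences split
    between the two isoforms at the event's mean inclusion level.
    """
    gene_ids = list(truth.gene_expr_log2.index)
    lam = cfg.confirmation_depth * np.exp2(
        np.clip(base_expr - cfg.expr_mean, -3, 3)
    )
    n_seqs = rng.poisson(lam)
    rows = []
    by_gene: dict[str, list[int]] = {}
    for i, seg in enumerate(truth.segments):
        by_gene.setdefault(seg.gene_id, []).append(i)
    for g, gid in enumerate(gene_ids):
        total = int(n_seqs[g])
        event = events.get(gid)
        if event is not None:
            seg_id, ev_type, mean_inc = event
            frac_alt = mean_inc if ev_type == "IR" else 1.0 - mean_inc
            frac_alt = float(np.clip(frac_alt, 0.15, 0.85))
            n_alt_iso = int(rng.binomial(total, frac_alt))
        else:
            seg_id, n_alt_iso = None, 0
        n_ref_iso = total - n_alt_iso
        for i in by_gene.get(gid, []):
            seg = truth.segments[i]
            if seg.id == seg_id:
                # reference-isoform sequences confirm the splice junctions;
                # alternative-isoform sequences load n_alt
                n_conf = int(rng.binomial(n_ref_iso, cfg.confirmation_rate))
                n_alt = n_alt_iso
                if seg.kind == "intron":  # IR: inclusion = retained isoform
                    n_incl, n_excl = n_alt_iso, n_conf
                else:  # ES: inclusion = exon-carrying isoform
                    n_incl, n_excl = n_conf, n_alt_iso
            else:
                n_conf = int(rng.binomial(total, cfg.confirmation_rate))
                n_alt = 0
                n_incl = n_conf if seg.kind == "exon" else 0
                n_excl = n_conf if seg.kind == "intron" else 0
            n_cdna = int(rng.binomial(n_conf, cfg.cdna_fraction))
            rows.append(
                dict(
                    segment_id=seg.id,
                    gene_id=gid,
                    kind=seg.kind,
                    n_est=n_conf - n_cdna,
                    n_cdna=n_cdna,
                    n_alt=n_alt,
                    n_inclusion_support=n_incl,
                    n_exclusion_support=n_excl,
                )
            )
    return pd.DataFrame(rows)


def _simulate_coverage(
    cfg: SimulationConfig,
    genes: dict[str, list[Transcript]],
    truth: SyntheticTruth,
    base_expr: np.ndarray,
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
) -> dict[str, np.ndarray]:
    coverage = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    gene_ids = list(truth.gene_expr_log2.index)
    depth = cfg.coverage_depth * np.exp2(
        np.clip(base_expr - cfg.expr_mean, -3, 3)
    )
    mean_inc = truth.inclusion.mean(axis=1)
    seg_index = truth.segment_index
    for g, gid in enumerate(gene_ids):
        t = genes[gid][0]
        track = coverage[t.chrom]
        c_g = float(depth[g])
        for e in t.exons:
            track[e.start : e.end] = c_g
        for iv in t.introns():
            seg_id = (
                f"{gid}:intron:{iv.chrom}:{iv.start}-{iv.end}"
            )
            pi = mean_inc[seg_index[seg_id]] if seg_id in seg_index else 0.0
            track[iv.start : iv.end] = pi * c_g
    if cfg.coverage_noise:
        for c, track in coverage.items():
            coverage[c] = rng.poisson(track).astype(float)
    return coverage


# ---------------------------------------------------------------------------
# file emission (closes the loop with the ingest side)


def write_dataset(sim: SimulatedDataset, outdir: str) -> dict[str, str]:
    """Write GFF3, probe matrix, sample sheet, confirmations, coverage, truth."""
    import os

    from .arraydata import write_probe_matrix, write_sample_sheet
    from .genome import write_gff3
    from .rnaseq import write_bedgraph

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "gff3": os.path.join(outdir, "genes.gff3"),
        "probes": os.path.join(outdir, "probes.tsv"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "confirmations": os.path.join(outdir, "confirmations.tsv"),
        "coverage": os.path.join(outdir, "coverage.bedgraph"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_gff3(sim.genes, paths["gff3"])
    write_probe_matrix(sim.matrix, paths["probes"])
    write_sample_sheet(sim.matrix.samples, paths["samples"])
    sim.confirmations.to_csv(paths["confirmations"], sep="\t", index=False)
    write_bedgraph(sim.coverage, paths["coverage"])
    truth_table = sim.truth.labels.copy()
    inc = sim.truth.inclusion
    for j, s in enumerate(sim.matrix.samples):
        truth_table[f"inclusion.{s.sample_id}"] = inc[:, j]
    truth_table.to_csv(paths["truth"], sep="\t", index=False)
    return paths
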
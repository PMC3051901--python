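"""Probe-level tiling-array data: loading, masking, normalization, summaries.

Intensities are stored linear; every statistic downstream of normalization
operates on log2 values.  The tensor layout is (probe, sample, replicate)
with exactly three replicates per sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import Segment, Transcript

__all__ = [
    "SampleInfo",
    "ProbeMatrix",
    "GeneExpression",
    "quantile_normalize",
    "build_kmer_index",
    "mask_repetitive_probes",
    "transcript_normalize",
    "assign_probes_to_segments",
    "gene_expression",
    "select_top_expressed_genes",
    "read_probe_matrix",
    "write_probe_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
]

PROBE_LENGTH = 25
N_REPLICATES = 3


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    condition_class: str  # {tissue, stress_treatment, stress_control}
    control_id: str | None = None

    def __post_init__(self) -> None:
        if self.condition_class not in (
            "tissue",
            "stress_treatment",
            "stress_control",
        ):
            raise ValueError(f"bad condition class: {self.condition_class!r}")
        if self.condition_class == "stress_treatment" and not self.control_id:
            raise ValueError(
                f"stress treatment {self.sample_id} lacks a control"
            )


@dataclass
class ProbeMatrix:
    """Probe coordinates plus an intensity tensor (probe, sample, replicate)."""

    probes: pd.DataFrame  # columns: probe_id, chrom, start, strand
    values: np.ndarray  # linear fluorescence, shape (n_probes, n_samples, 3)
    samples: list[SampleInfo]
    repetitive_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[2] != N_REPLICATES:
            raise ValueError(
                f"expected (probe, sample, {N_REPLICATES}) tensor, "
                f"got {self.values.shape}"
            )
        if self.values.shape[0] != len(self.probes):
            raise ValueError("probe table and tensor length differ")
        if self.values.shape[1] != len(self.samples):
            raise ValueError("sample sheet and tensor width differ")
        if np.any(self.values <= 0):
            raise ValueError("intensities must be strictly positive")
        if self.repetitive_mask is None:
            self.repetitive_mask = np.zeros(len(self.probes), dtype=bool)
        sample_ids = {s.sample_id for s in self.samples}
        for s in self.samples:
            if s.condition_class == "stress_treatment":
                if s.control_id not in sample_ids:
                    raise ValueError(
                        f"control {s.control_id!r} of {s.sample_id} not found"
                    )

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return i
        raise KeyError(sample_id)

    def log2(self) -> np.ndarray:
        return np.log2(self.values)


@dataclass
class GeneExpression:
    """Per-sample and pooled median exonic log2 intensity of one gene."""

    gene_id: str
    per_sample: np.ndarray  # shape (n_samples,)
    pooled: float


def quantile_normalize_columns(arr: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of a (probe, array) matrix.

    Each column's distribution is mapped to the across-column mean of the
    sorted values.  Tied values within a column receive the mean of the
    corresponding reference values (via average ranks), so identical inputs
    map to identical outputs and the map is idempotent.
    """
    from scipy.stats import rankdata

    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-d matrix with at least two arrays")
    n = arr.shape[0]
    reference = np.mean(np.sort(arr, axis=0), axis=1)
    ranks = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks[:, j] = rankdata(arr[:, j], method="average")
    # interpolate average ranks onto the reference order statistics
    return np.interp(ranks, np.arange(1, n + 1), reference)


def quantile_normalize(matrix: ProbeMatrix) -> ProbeMatrix:
    """Map each array's distribution to the across-array mean.

    Arrays are the (sample, replicate) columns of the tensor.
    """
    n = matrix.n_probes
    out = quantile_normalize_columns(matrix.values.reshape(n, -1))
    return replace(matrix, values=out.reshape(matrix.values.shape))


def build_kmer_index(
    sequences: dict[str, str], k: int = PROBE_LENGTH
) -> dict[str, int]:
    """Count genome-wide occurrences of every k-mer (both strands)."""
    complement = str.maketrans("ACGTacgt", "TGCAtgca")
    counts: dict[str, int] = {}
    for seq in sequences.values():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] = counts.get(seq[i : i + k], 0) + 1
        rc = seq.translate(complement)[::-1]
        for i in range(len(rc) - k + 1):
            counts[rc[i : i + k]] = counts.get(rc[i : i + k], 0) + 1
    return counts


def mask_repetitive_probes(
    matrix: ProbeMatrix,
    kmer_index: dict[str, int] | None = None,
    sequences: dict[str, str] | None = None,
) -> ProbeMatrix:
    """Flag probes whose 25-mer occurs more than once genome-wide.

    Either a precomputed multiplicity index or the genome sequences must be
    supplied.  A k-mer and its reverse complement count as one sequence, so
    a unique genomic 25-mer has multiplicity 2 in the two-strand index.
    """
    if kmer_index is None:
        if sequences is None:
            raise ValueError("need a k-mer index or genome sequences")
        kmer_index = build_kmer_index(sequences)
    if sequences is None:
        raise ValueError("probe sequences require the genome sequences")
    mask = matrix.repetitive_mask.copy()
    for i, row in enumerate(matrix.probes.itertuples(index=False)):
        seq = sequences[row.chrom][row.start : row.start + PROBE_LENGTH]
        seq = seq.upper()
        # odd k: a k-mer is never its own reverse complement, so the probe's
        # own site contributes exactly 1 to the two-strand count
        if kmer_index.get(seq, 0) > 1:
            mask[i] = True
    return replace(matrix, repetitive_mask=mask)


def assign_probes_to_segments(
    matrix: ProbeMatrix, segments: list[Segment]
) -> dict[str, np.ndarray]:
    """Map each segment to the ordered indices of its fully contained probes.

    A probe belongs to a segment iff its complete 25-mer lies within the
    segment interval and the probe is not masked.  Probes are ordered in
    transcription direction.
    """
    order = np.argsort(matrix.probes["start"].to_numpy(), kind="stable")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chroms = matrix.probes["chrom"].to_numpy()
    starts = matrix.probes["start"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = order[chroms[order] == chrom]
        by_chrom[chrom] = (starts[sel], sel)
    unmasked = ~matrix.repetitive_mask
    assignment: dict[str, np.ndarray] = {}
    for seg in segments:
        iv = seg.interval
        if iv.chrom not in by_chrom:
            assignment[seg.id] = np.empty(0, dtype=int)
            continue
        seg_starts, seg_idx = by_chrom[iv.chrom]
        lo = np.searchsorted(seg_starts, iv.start, side="left")
        hi = np.searchsorted(seg_starts, iv.end - PROBE_LENGTH, side="right")
        idx = seg_idx[lo:hi]
        idx = idx[unmasked[idx]]
        if iv.strand == "-":
            idx = idx[::-1]
        assignment[seg.id] = idx
    return assignment


def transcript_normalize(
    matrix: ProbeMatrix,
    genes: dict[str, list[Transcript]],
    enabled: bool = True,
) -> ProbeMatrix:
    """Remove per-probe affinity offsets relative to the gene's exonic median.

    The probe effect is the median, over samples, of the probe's log2
    intensity minus the gene's median exonic log2 intensity in the same
    sample; it is subtracted from the probe's log2 intensities.  A
    simplified, toggleable probe-effect correction.
    """
    if not enabled:
        return matrix
    log_values = matrix.log2()
    exonic_idx, gene_of_probe = _exonic_probe_index(matrix, genes)
    out = log_values.copy()
    for gid, probe_idx in gene_of_probe.items():
        ex_idx = exonic_idx.get(gid)
        if ex_idx is None or len(ex_idx) == 0:
            continue
        # per-sample gene medians over exonic probes x replicates
        med = np.median(
            log_values[ex_idx].transpose(1, 0, 2).reshape(matrix.n_samples, -1),
            axis=1,
        )
        probe_med = np.median(log_values[probe_idx], axis=2)  # (n_p, S)
        effect = np.median(probe_med - med[None, :], axis=1)  # (n_p,)
        out[probe_idx] -= effect[:, None, None]
    return replace(matrix, values=np.exp2(out))


def _exonic_probe_index(
    matrix: ProbeMatrix, genes: dict[str, list[Transcript]]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Unmasked probe indices per gene: (exonic-only, all within gene span)."""
    starts = matrix.probes["start"].to_numpy()
    chroms = matrix.probes["chrom"].to_numpy()
    order = np.argsort(starts, kind="stable")
    unmasked = ~matrix.repetitive_mask
    exonic: dict[str, np.ndarray] = {}
    genic: dict[str, np.ndarray] = {}
    for gid, tx in genes.items():
        chrom = tx[0].chrom
        sel = order[chroms[order] == chrom]
        s = starts[sel]
        span_start = min(t.span.start for t in tx)
        span_end = max(t.span.end for t in tx)
        lo = np.searchsorted(s, span_start, side="left")
        hi = np.searchsorted(s, span_end - PROBE_LENGTH, side="right")
        idx = sel[lo:hi]
        idx = idx[unmasked[idx]]
        genic[gid] = idx
        exon_ivs = sorted(
            {(e.start, e.end) for t in tx for e in t.exons}
        )
        keep = np.zeros(len(idx), dtype=bool)
        p = starts[idx]
        for es, ee in exon_ivs:
            keep |= (p >= es) & (p + PROBE_LENGTH <= ee)
        exonic[gid] = idx[keep]
    return exonic, genic


def gene_expression(
    matrix: ProbeMatrix,
    gene_id: str,
    exonic_probe_idx: np.ndarray,
) -> GeneExpression:
    """Median exonic log2 intensity per sample, plus the pooled median."""
    if len(exonic_probe_idx) == 0:
        raise ValueError(f"gene {gene_id} has no usable exonic probes")
    vals = matrix.log2()[exonic_probe_idx]  # (n_p, S, 3)
    per_sample = np.median(
        vals.transpose(1, 0, 2).reshape(matrix.n_samples, -1), axis=1
    )
    pooled = float(np.median(vals))
    return GeneExpression(gene_id, per_sample, pooled)


def select_top_expressed_genes(
    expressions: list[GeneExpression], fraction: float
) -> set[str]:
    """Top ceil(fraction * n) genes by pooled median; ties break by gene id."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not expressions:
        return set()
    ranked = sorted(expressions, key=lambda e: (-e.pooled, e.gene_id))
    k = math.ceil(fraction * len(ranked))
    return {e.gene_id for e in ranked[:k]}


# ---------------------------------------------------------------------------
# I/O


def write_probe_matrix(matrix: ProbeMatrix, path: str) -> None:
    cols = {
        "probe_id": matrix.probes["probe_id"],
        "chrom": matrix.probes["chrom"],
        "start": matrix.probes["start"],
        "strand": matrix.probes["strand"],
    }
    df = pd.DataFrame(cols)
    for j, s in enumerate(matrix.samples):
        for r in range(N_REPLICATES):
            df[f"{s.sample_id}.{r + 1}"] = matrix.values[:, j, r]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_probe_matrix(path: str, samples: list[SampleInfo]) -> ProbeMatrix:
    df = pd.read_csv(path, sep="\t")
    probes = df[["probe_id", "chrom", "start", "strand"]].copy()
    n = len(df)
    values = np.empty((n, len(samples), N_REPLICATES))
    for j, s in enumerate(samples):
        for r in range(N_REPLICATES):
            col = f"{s.sample_id}.{r + 1}"
            if col not in df.columns:
                raise ValueError(f"missing intensity column {col!r}")
            values[:, j, r] = df[col].to_numpy(float)
    return ProbeMatrix(probes=probes, values=values, samples=samples)


def write_sample_sheet(samples: list[SampleInfo], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tclass\tcontrol_id\n")
        for s in samples:
            fh.write(
                f"{s.sample_id}\t{s.condition_class}\t{s.control_id or '.'}\n"
            )


def read_sample_sheet(path: str) -> list[SampleInfo]:
    samples = []
    df = pd.read_csv(path, sep="\t", dtype=str)
    for _, row in df.iterrows():
        control = row["control_id"]
        if control in (".", "", None) or pd.isna(control):
            control = None
        samples.append(SampleInfo(row["sample_id"], row["class"], control))
    return samples
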
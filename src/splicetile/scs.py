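"""Sequence-confirmed splicing (SCS) benchmark construction.

Positive examples are IR/ES events whose two isoforms are each confirmed by
at least two sequenced transcripts; negative examples are constitutive
segments with at least 5-fold weighted confirmation (cDNAs counted twice)
and no alternative evidence.  Negatives are resampled with replacement to
the class ratio implied by genome-level AS prevalence estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import ASEvent, Segment, SplicingGraph, Transcript

__all__ = [
    "ConfirmationCount",
    "RatioParams",
    "SCSComposition",
    "SCSDataset",
    "count_confirmations",
    "select_scs_examples",
    "compute_scs_composition",
    "sample_to_ratio",
    "build_scs_from_table",
]

CDNA_WEIGHT = 2
MIN_ISOFORM_SUPPORT = 2
MIN_CONSTITUTIVE_CONFIRMATION = 5


@dataclass
class ConfirmationCount:
    segment: Segment
    n_est: int = 0
    n_cdna: int = 0
    n_alt: int = 0  # sequences supporting an alternative isoform

    @property
    def effective(self) -> int:
        """EST count plus doubly weighted cDNA count."""
        return self.n_est + CDNA_WEIGHT * self.n_cdna

    @property
    def n_sequences(self) -> int:
        return self.n_est + self.n_cdna


@dataclass(frozen=True)
class RatioParams:
    """Published prevalence estimates driving the SCS class composition."""

    r_as: float = 0.30  # fraction of genes undergoing AS
    r_ie: float = 0.709  # fraction of AS genes with an IR or ES event
    g_a: int = 964  # alternatively spliced genes with IR/ES
    i_a: int = 996  # IR events in those genes
    e_a: int = 259  # ES events in those genes
    exons_per_gene: int = 5
    introns_per_gene: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.r_as < 1 and 0 < self.r_ie < 1):
            raise ValueError("fractions must be in (0, 1)")
        if min(self.g_a, self.i_a, self.e_a) <= 0:
            raise ValueError("counts must be positive")


@dataclass
class SCSComposition:
    r: float  # combined prevalence r_IE * r_AS (carried unrounded)
    g_c: int  # single-isoform genes
    e_c: int  # constitutive exons
    i_c: int  # constitutive introns
    intron_ratio: int  # i_a : i_c displayed as 1 : intron_ratio
    exon_ratio: int  # e_a : e_c displayed as 1 : exon_ratio


@dataclass
class SCSDataset:
    kind: str  # {intron, exon}
    positives: list[Segment]
    negatives: list[Segment]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("intron", "exon"):
            raise ValueError(f"bad SCS kind: {self.kind!r}")


def _transcript_introns(t: Transcript) -> list[tuple[int, int]]:
    return [(iv.start, iv.end) for iv in t.introns()]


def count_confirmations(
    segments: list[Segment],
    evidence: list[Transcript],
    graph: SplicingGraph | None = None,
) -> list[ConfirmationCount]:
    """Count sequenced transcripts confirming both splice sites per segment.

    A transcript confirms an intron when it splices exactly that intron;
    it confirms an exon when the exon appears internally with both
    boundaries matched.  Alternative-isoform support (an exon spanning the
    intron, or an intron covering the exon with shared flanks) is tallied
    into ``n_alt``.
    """
    counts = [ConfirmationCount(seg) for seg in segments]
    for t in evidence:
        if t.source not in ("est", "cdna"):
            continue
        introns = set(_transcript_introns(t))
        internal_exons = {
            (e.start, e.end) for e in t.exons[1:-1]
        }
        exon_spans = [(e.start, e.end) for e in t.exons]
        for cc in counts:
            seg = cc.segment
            key = (seg.interval.start, seg.interval.end)
            if seg.interval.chrom != t.chrom or seg.interval.strand != t.strand:
                continue
            confirmed = (
                key in introns if seg.kind == "intron" else key in internal_exons
            )
            if confirmed:
                if t.source == "cdna":
                    cc.n_cdna += 1
                else:
                    cc.n_est += 1
                continue
            if seg.kind == "intron":
                # exon spanning the intron: IR-supporting isoform
                if any(s <= key[0] and e >= key[1] for s, e in exon_spans):
                    cc.n_alt += 1
            else:
                # intron covering the exon: ES-supporting isoform
                if any(s <= key[0] and e >= key[1] for s, e in introns):
                    cc.n_alt += 1
    return counts


def select_scs_examples(
    counts: list[ConfirmationCount],
    events: list[ASEvent],
    kind: str,
    event_support: dict[str, tuple[int, int]] | None = None,
) -> SCSDataset:
    """Build the unsampled positive and negative pools for one segment kind.

    Positives: events of the matching kind whose two isoforms each have at
    least two supporting sequences (from the event's transcript lists, or
    from ``event_support`` mapping segment id -> (n_inclusion, n_exclusion)).
    Negatives: segments with weighted confirmation >= 5 and no alternative
    evidence.
    """
    if kind not in ("intron", "exon"):
        raise ValueError(f"bad kind: {kind!r}")
    event_kind = "IR" if kind == "intron" else "ES"
    positives = []
    for ev in events:
        if ev.kind != event_kind:
            continue
        if event_support is not None:
            n_in, n_ex = event_support.get(ev.segment.id, (0, 0))
        else:
            n_in = len(ev.inclusion_transcripts)
            n_ex = len(ev.exclusion_transcripts)
        if n_in >= MIN_ISOFORM_SUPPORT and n_ex >= MIN_ISOFORM_SUPPORT:
            positives.append(ev.segment)
    positive_ids = {seg.id for seg in positives}
    negatives = [
        cc.segment
        for cc in counts
        if cc.segment.kind == kind
        and cc.segment.id not in positive_ids
        and cc.effective >= MIN_CONSTITUTIVE_CONFIRMATION
        and cc.n_alt == 0
    ]
    if not positives or not negatives:
        raise ValueError(
            f"empty {kind} SCS pool: {len(positives)} positives, "
            f"{len(negatives)} negatives"
        )
    return SCSDataset(kind=kind, positives=positives, negatives=negatives)


def compute_scs_composition(params: RatioParams) -> SCSComposition:
    """Class-ratio arithmetic from prevalence estimates.

    r is carried unrounded; g_c is rounded to the nearest integer; the
    segment-level counts follow the average gene shape (5 exons, 4 introns,
    one AS event per AS gene); ratio denominators are rounded quotients.
    """
    r = params.r_ie * params.r_as
    if r <= 0:
        raise ValueError("combined AS prevalence must be positive")
    g_c = round(params.g_a * (1.0 - r) / r)
    e_c = params.exons_per_gene * g_c + (params.exons_per_gene - 1) * params.g_a
    i_c = params.introns_per_gene * g_c + (params.introns_per_gene - 1) * params.g_a
    return SCSComposition(
        r=r,
        g_c=g_c,
        e_c=e_c,
        i_c=i_c,
        intron_ratio=round(i_c / params.i_a),
        exon_ratio=round(e_c / params.e_a),
    )


def build_scs_from_table(
    segments: list[Segment],
    table,
    kind: str,
    ratio_denominator: int,
    seed: int,
) -> SCSDataset:
    """Build a sampled SCS set from a tabular confirmation file.

    The table needs columns segment_id, n_est, n_cdna, n_alt and the
    per-isoform support columns n_inclusion_support / n_exclusion_support
    (as emitted by the simulator or an external junction counter).
    """
    by_id = {seg.id: seg for seg in segments}
    positives: list[Segment] = []
    negatives: list[Segment] = []
    for row in table.itertuples(index=False):
        seg = by_id.get(row.segment_id)
        if seg is None or seg.kind != kind:
            continue
        n_in = int(getattr(row, "n_inclusion_support", 0))
        n_ex = int(getattr(row, "n_exclusion_support", 0))
        effective = int(row.n_est) + CDNA_WEIGHT * int(row.n_cdna)
        if n_in >= MIN_ISOFORM_SUPPORT and n_ex >= MIN_ISOFORM_SUPPORT:
            positives.append(seg)
        elif (
            effective >= MIN_CONSTITUTIVE_CONFIRMATION
            and int(row.n_alt) == 0
        ):
            negatives.append(seg)
    if not positives or not negatives:
        raise ValueError(
            f"empty {kind} SCS pool from table: {len(positives)} positives, "
            f"{len(negatives)} negatives"
        )
    pools = SCSDataset(kind=kind, positives=positives, negatives=negatives)
    return sample_to_ratio(pools, ratio_denominator, seed)


def sample_to_ratio(
    pools: SCSDataset,
    ratio_denominator: int,
    seed: int,
) -> SCSDataset:
    """Resample negatives with replacement to the target 1:k class ratio."""
    rng = np.random.default_rng(seed)
    n_neg = ratio_denominator * len(pools.positives)
    idx = rng.integers(0, len(pools.negatives), size=n_neg)
    negatives = [pools.negatives[i] for i in idx]
    return SCSDataset(
        kind=pools.kind,
        positives=list(pools.positives),
        negatives=negatives,
        seed=seed,
    )
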
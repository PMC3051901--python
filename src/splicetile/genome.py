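"""Gene structures, splicing graphs, and IR/ES event detection.

Coordinates are 0-based half-open internally; GFF3 readers/writers perform
the 1-based inclusive shift and are the only place that shift happens.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "Transcript",
    "SplicingGraph",
    "Segment",
    "ASEvent",
    "build_splicing_graph",
    "merge_gene_structures",
    "detect_ir_events",
    "detect_es_events",
    "enumerate_segments",
    "read_gff3",
    "write_gff3",
    "read_exon_table",
    "write_events",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative coordinate: {self}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and self.end >= other.end
        )


@dataclass
class Transcript:
    """An exon chain on one strand; `source` tags the evidence type."""

    id: str
    gene_id: str
    exons: list[GenomicInterval]
    source: str = "annotation"  # {annotation, est, cdna}

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"transcript {self.id} mixes chromosomes/strands")
        for a, b in itertools.pairwise(exons):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.id}: exons overlap or touch ({a}, {b})"
                )
        self.exons = exons

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in itertools.pairwise(self.exons)
        ]


@dataclass
class SplicingGraph:
    """Per-gene DAG: exon intervals as nodes, introns as edges between them."""

    gene_id: str
    chrom: str
    strand: str
    exon_nodes: dict[GenomicInterval, list[str]] = field(default_factory=dict)
    # edge key: (left exon, right exon) in genome order
    intron_edges: dict[
        tuple[GenomicInterval, GenomicInterval], list[str]
    ] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def intron_interval(
        self, edge: tuple[GenomicInterval, GenomicInterval]
    ) -> GenomicInterval:
        left, right = edge
        return GenomicInterval(self.chrom, left.end, right.start, self.strand)


@dataclass
class Segment:
    """One exon or intron of a gene — the unit inclusion is scored on."""

    gene_id: str
    kind: str  # {exon, intron}
    interval: GenomicInterval
    flanking_exons: tuple[GenomicInterval, ...] = ()
    is_internal: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "intron"):
            raise ValueError(f"bad segment kind: {self.kind!r}")
        if self.kind == "intron" and len(self.flanking_exons) != 2:
            raise ValueError("intron segments need two flanking exons")

    @property
    def id(self) -> str:
        iv = self.interval
        return f"{self.gene_id}:{self.kind}:{iv.chrom}:{iv.start}-{iv.end}"


@dataclass
class ASEvent:
    kind: str  # {IR, ES}
    segment: Segment
    inclusion_transcripts: list[str]
    exclusion_transcripts: list[str]

    def __post_init__(self) -> None:
        if self.kind not in ("IR", "ES"):
            raise ValueError(f"bad event kind: {self.kind!r}")
        if not self.inclusion_transcripts or not self.exclusion_transcripts:
            raise ValueError("both transcript lists must be non-empty")


def build_splicing_graph(transcripts: Sequence[Transcript]) -> SplicingGraph:
    """Union the exon chains of one gene into a splicing graph.

    Identical exon intervals merge into one node; identical introns into one
    edge; supporting transcript ids are recorded per node and edge.
    """
    if not transcripts:
        raise ValueError("no transcripts")
    gene_ids = {t.gene_id for t in transcripts}
    strands = {t.strand for t in transcripts}
    chroms = {t.chrom for t in transcripts}
    if len(gene_ids) > 1:
        raise ValueError(f"mixed gene ids: {sorted(gene_ids)}")
    if len(strands) > 1 or len(chroms) > 1:
        raise ValueError("transcripts mix strands or chromosomes")
    graph = SplicingGraph(
        gene_id=gene_ids.pop(), chrom=chroms.pop(), strand=strands.pop()
    )
    for t in sorted(transcripts, key=lambda t: t.id):
        if t.id in graph.transcripts:
            # identical id: idempotent merge, list support once
            continue
        graph.transcripts[t.id] = t
        for exon in t.exons:
            graph.exon_nodes.setdefault(exon, []).append(t.id)
        for left, right in itertools.pairwise(t.exons):
            graph.intron_edges.setdefault((left, right), []).append(t.id)
    return graph


def merge_gene_structures(
    annotation: Iterable[Transcript], evidence: Iterable[Transcript]
) -> dict[str, list[Transcript]]:
    """Group transcripts into genes by span overlap on the same strand.

    Overlap is transitively closed (single-linkage).  The merged gene id is
    the lexicographically smallest gene id among members; transcripts keep
    their exon structures but are re-labeled with the shared gene id.
    """
    transcripts = list(annotation) + list(evidence)
    by_key: dict[tuple[str, str], list[Transcript]] = {}
    for t in transcripts:
        by_key.setdefault((t.chrom, t.strand), []).append(t)

    genes: dict[str, list[Transcript]] = {}
    for group in by_key.values():
        group.sort(key=lambda t: (t.span.start, t.span.end, t.id))
        # sweep: transcripts chain into one cluster while spans overlap
        cluster: list[Transcript] = []
        cluster_end = -1
        for t in group + [None]:  # type: ignore[list-item]
            if t is not None and (not cluster or t.span.start < cluster_end):
                cluster.append(t)
                cluster_end = max(cluster_end, t.span.end)
                continue
            if cluster:
                gid = min(c.gene_id for c in cluster)
                genes[gid] = [
                    Transcript(c.id, gid, list(c.exons), c.source)
                    for c in cluster
                ]
            if t is not None:
                cluster = [t]
                cluster_end = t.span.end
    return genes


def detect_ir_events(graph: SplicingGraph) -> list[ASEvent]:
    """Introns spliced out in one isoform and spanned by an exon in another."""
    events: list[ASEvent] = []
    for edge, exclusion in sorted(graph.intron_edges.items()):
        intron = graph.intron_interval(edge)
        inclusion = sorted(
            {
                tid
                for exon, tids in graph.exon_nodes.items()
                if exon.contains(intron)
                for tid in tids
            }
        )
        if inclusion:
            seg = Segment(
                gene_id=graph.gene_id,
                kind="intron",
                interval=intron,
                flanking_exons=edge,
            )
            events.append(ASEvent("IR", seg, inclusion, sorted(exclusion)))
    return events


def _shared_flanks(
    t_in: Transcript, t_ex: Transcript, exon: GenomicInterval
) -> bool:
    """Do the two transcripts share an exon on each side of `exon`?

    Upstream/downstream follow transcription direction, but requiring one
    shared exon on *each* side makes the test symmetric in genome order.
    """
    common = set(t_in.exons) & set(t_ex.exons)
    left = any(e.end <= exon.start for e in common)
    right = any(e.start >= exon.end for e in common)
    return left and right


def detect_es_events(graph: SplicingGraph) -> list[ASEvent]:
    """Exons of one isoform entirely inside an intron of another isoform.

    The two isoforms must share at least one exon on each side of the
    skipped exon.
    """
    events: list[ASEvent] = []
    for exon, exon_tids in sorted(graph.exon_nodes.items()):
        inclusion: set[str] = set()
        exclusion: set[str] = set()
        for edge, edge_tids in graph.intron_edges.items():
            intron = graph.intron_interval(edge)
            if not intron.contains(exon):
                continue
            for tid_in in exon_tids:
                for tid_ex in edge_tids:
                    if _shared_flanks(
                        graph.transcripts[tid_in],
                        graph.transcripts[tid_ex],
                        exon,
                    ):
                        inclusion.add(tid_in)
                        exclusion.add(tid_ex)
        if inclusion and exclusion:
            flanks = _internal_flanks(graph, exon)
            seg = Segment(
                gene_id=graph.gene_id,
                kind="exon",
                interval=exon,
                flanking_exons=flanks,
                is_internal=True,
            )
            events.append(ASEvent("ES", seg, sorted(inclusion), sorted(exclusion)))
    return events


def _internal_flanks(
    graph: SplicingGraph, exon: GenomicInterval
) -> tuple[GenomicInterval, ...]:
    """Neighbors of `exon` in the first supporting transcript where it is internal."""
    for tid in sorted(graph.exon_nodes.get(exon, [])):
        exons = graph.transcripts[tid].exons
        i = exons.index(exon)
        if 0 < i < len(exons) - 1:
            return (exons[i - 1], exons[i + 1])
    return ()


def enumerate_segments(graph: SplicingGraph) -> list[Segment]:
    """All introns plus all internal exons of a gene, deduplicated.

    Terminal-only exons are excluded: AS testing is restricted to internal
    exons and introns.
    """
    segments: dict[tuple[str, GenomicInterval], Segment] = {}
    for edge in graph.intron_edges:
        intron = graph.intron_interval(edge)
        key = ("intron", intron)
        if key not in segments:
            segments[key] = Segment(
                gene_id=graph.gene_id,
                kind="intron",
                interval=intron,
                flanking_exons=edge,
            )
    for exon in graph.exon_nodes:
        flanks = _internal_flanks(graph, exon)
        if len(flanks) == 2:
            key = ("exon", exon)
            if key not in segments:
                segments[key] = Segment(
                    gene_id=graph.gene_id,
                    kind="exon",
                    interval=exon,
                    flanking_exons=flanks,
                    is_internal=True,
                )
    return sorted(segments.values(), key=lambda s: (s.interval, s.kind))


# ---------------------------------------------------------------------------
# I/O


def read_gff3(path: str) -> dict[str, list[Transcript]]:
    """Read gene/mRNA/exon features from a GFF3 file.

    Returns a mapping gene_id -> transcripts.  Exon coordinates are shifted
    to the internal 0-based half-open convention here and nowhere else.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: dict[str, list[Transcript]] = {}
    for mrna in db.features_of_type("mRNA"):
        tid = mrna.id
        parents = [p.id for p in db.parents(mrna, featuretype="gene")]
        gid = parents[0] if parents else tid
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
            for e in db.children(mrna, featuretype="exon")
        ]
        if not exons:
            continue
        src = mrna.source if mrna.source in ("est", "cdna") else "annotation"
        genes.setdefault(gid, []).append(Transcript(tid, gid, exons, src))
    for tx in genes.values():
        tx.sort(key=lambda t: t.id)
    return genes


def write_gff3(genes: dict[str, list[Transcript]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(genes):
            tx = genes[gid]
            chrom = tx[0].chrom
            strand = tx[0].strand
            gstart = min(t.span.start for t in tx)
            gend = max(t.span.end for t in tx)
            fh.write(
                f"{chrom}\tsplicetile\tgene\t{gstart + 1}\t{gend}\t.\t"
                f"{strand}\t.\tID={gid}\n"
            )
            for t in sorted(tx, key=lambda t: t.id):
                src = t.source if t.source in ("est", "cdna") else "splicetile"
                fh.write(
                    f"{chrom}\t{src}\tmRNA\t{t.span.start + 1}\t{t.span.end}"
                    f"\t.\t{strand}\t.\tID={t.id};Parent={gid}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{chrom}\t{src}\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{strand}\t.\tParent={t.id}\n"
                    )


def read_exon_table(path: str) -> dict[str, list[Transcript]]:
    """Read transcript evidence as a 6-column tab file.

    Columns: transcript_id, gene_id, chrom, start, end, strand — one row per
    exon, coordinates 1-based inclusive like GFF3.  An optional 7th column
    carries the evidence source (est/cdna).
    """
    rows: dict[str, tuple[str, str, list[GenomicInterval]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            tid, gid, chrom, start, end, strand = parts[:6]
            if tid == "transcript_id":
                continue
            source = parts[6] if len(parts) > 6 else "est"
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            if tid not in rows:
                rows[tid] = (gid, source, [])
            rows[tid][2].append(iv)
    genes: dict[str, list[Transcript]] = {}
    for tid, (gid, source, exons) in rows.items():
        genes.setdefault(gid, []).append(Transcript(tid, gid, exons, source))
    for tx in genes.values():
        tx.sort(key=lambda t: t.id)
    return genes


def write_events(events: Iterable[ASEvent], path: str) -> None:
    """Tab-delimited event table (1-based inclusive coordinates on disk)."""
    with open(path, "w") as fh:
        fh.write(
            "event_kind\tgene_id\tchrom\tstart\tend\tstrand\t"
            "n_inclusion\tn_exclusion\n"
        )
        for ev in events:
            iv = ev.segment.interval
            fh.write(
                f"{ev.kind}\t{ev.segment.gene_id}\t{iv.chrom}\t{iv.start + 1}"
                f"\t{iv.end}\t{iv.strand}\t{len(ev.inclusion_transcripts)}"
                f"\t{len(ev.exclusion_transcripts)}\n"
            )
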
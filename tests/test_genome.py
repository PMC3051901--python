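from __future__ import annotations

import itertools

import numpy as np
import pytest

from splicetile.genome import (
    GenomicInterval,
    Transcript,
    build_splicing_graph,
    detect_es_events,
    detect_ir_events,
    enumerate_segments,
    merge_gene_structures,
    read_gff3,
    write_gff3,
)

from .conftest import iv, tx
from .oracles import brute_force_es, brute_force_ir


class TestGenomicInterval:
    def test_rejects_inverted(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10, "+")

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10, "+")

    def test_containment(self):
        assert iv(0, 100).contains(iv(10, 90))
        assert not iv(0, 100).contains(iv(10, 110))


class TestTranscript:
    def test_sorts_exons(self):
        t = tx("t", [(200, 300), (0, 100)])
        assert [e.start for e in t.exons] == [0, 200]

    def test_rejects_overlapping_exons(self):
        with pytest.raises(ValueError):
            tx("t", [(0, 100), (50, 150)])

    def test_rejects_touching_exons(self):
        with pytest.raises(ValueError):
            tx("t", [(0, 100), (100, 200)])

    def test_introns(self):
        t = tx("t", [(0, 100), (200, 300), (400, 500)])
        assert [(i.start, i.end) for i in t.introns()] == [(100, 200), (300, 400)]


class TestBuildSplicingGraph:
    def test_single_isoform_three_exons(self, three_exon_transcript):
        g = build_splicing_graph([three_exon_transcript])
        assert len(g.exon_nodes) == 3
        assert len(g.intron_edges) == 2

    def test_identical_transcripts_merge(self, three_exon_transcript):
        other = tx("t2", [(0, 100), (200, 300), (400, 500)])
        g = build_splicing_graph([three_exon_transcript, other])
        assert len(g.exon_nodes) == 3
        assert len(g.intron_edges) == 2
        for tids in g.exon_nodes.values():
            assert tids == ["t1", "t2"]

    def test_skip_variant_adds_edge(self):
        # {E1-E2-E3, E1-E3}: 3 nodes, 3 distinct intron edges (hand count)
        t1 = tx("t1", [(0, 100), (200, 300), (400, 500)])
        t2 = tx("t2", [(0, 100), (400, 500)])
        g = build_splicing_graph([t1, t2])
        assert len(g.exon_nodes) == 3
        assert len(g.intron_edges) == 3

    def test_rejects_mixed_strand(self):
        t1 = tx("t1", [(0, 100)])
        t2 = Transcript("t2", "G1", [iv(0, 100, strand="-")])
        with pytest.raises(ValueError):
            build_splicing_graph([t1, t2])


class TestMergeGeneStructures:
    def test_overlap_same_strand(self):
        a = tx("a", [(0, 100), (200, 300)], gene_id="GA")
        b = tx("b", [(250, 400)], gene_id="GB", source="cdna")
        genes = merge_gene_structures([a], [b])
        assert len(genes) == 1
        (members,) = genes.values()
        assert {t.id for t in members} == {"a", "b"}

    def test_opposite_strands_stay_separate(self):
        a = tx("a", [(0, 300)], gene_id="GA")
        b = Transcript("b", "GB", [iv(0, 300, strand="-")], "est")
        genes = merge_gene_structures([a], [b])
        assert len(genes) == 2

    def test_transitive_chain(self):
        # A overlaps B, B overlaps C, A disjoint from C -> one gene
        a = tx("a", [(0, 100)], gene_id="GA")
        b = tx("b", [(50, 250)], gene_id="GB")
        c = tx("c", [(200, 400)], gene_id="GC")
        genes = merge_gene_structures([a, b, c], [])
        assert len(genes) == 1
        (members,) = genes.values()
        assert {t.id for t in members} == {"a", "b", "c"}

    def test_disjoint_transcripts_form_singletons(self):
        a = tx("a", [(0, 100)], gene_id="GA")
        b = tx("b", [(500, 600)], gene_id="GB")
        assert len(merge_gene_structures([a, b], [])) == 2


class TestDetectIR:
    def test_single_isoform_no_events(self, three_exon_transcript):
        g = build_splicing_graph([three_exon_transcript])
        assert detect_ir_events(g) == []

    def test_retained_intron_detected(self):
        spliced = tx("t1", [(0, 100), (200, 300)])
        retained = tx("t2", [(0, 300)])
        g = build_splicing_graph([spliced, retained])
        events = detect_ir_events(g)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "IR"
        assert (ev.segment.interval.start, ev.segment.interval.end) == (100, 200)
        assert ev.inclusion_transcripts == ["t2"]
        assert ev.exclusion_transcripts == ["t1"]

    def test_partial_span_is_not_retention(self):
        spliced = tx("t1", [(0, 100), (200, 300)])
        half = tx("t2", [(0, 150)])  # covers only half the intron
        g = build_splicing_graph([spliced, half])
        assert detect_ir_events(g) == []


class TestDetectES:
    def test_cassette_exon(self):
        t1 = tx("t1", [(0, 100), (200, 300), (400, 500)])
        t2 = tx("t2", [(0, 100), (400, 500)])
        g = build_splicing_graph([t1, t2])
        events = detect_es_events(g)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "ES"
        assert (ev.segment.interval.start, ev.segment.interval.end) == (200, 300)

    def test_no_shared_downstream_exon(self):
        t1 = tx("t1", [(0, 100), (200, 300)])
        t2 = tx("t2", [(0, 100), (400, 500)])
        g = build_splicing_graph([t1, t2])
        assert detect_es_events(g) == []

    def test_terminal_exon_not_skipped(self):
        # the candidate exon is terminal in t1: no shared upstream exon
        t1 = tx("t1", [(200, 300), (400, 500)])
        t2 = tx("t2", [(0, 100), (400, 500)])
        g = build_splicing_graph([t1, t2])
        assert detect_es_events(g) == []


class TestEnumerateSegments:
    def test_three_exon_gene(self, three_exon_transcript):
        segs = enumerate_segments(build_splicing_graph([three_exon_transcript]))
        kinds = sorted(s.kind for s in segs)
        assert kinds == ["exon", "intron", "intron"]

    def test_two_exon_gene(self):
        segs = enumerate_segments(
            build_splicing_graph([tx("t", [(0, 100), (200, 300)])])
        )
        assert [s.kind for s in segs] == ["intron"]

    def test_skipped_exon_deduplicated(self):
        t1 = tx("t1", [(0, 100), (200, 300), (400, 500)])
        t2 = tx("t2", [(0, 100), (400, 500)])
        segs = enumerate_segments(build_splicing_graph([t1, t2]))
        exon_ivs = [
            (s.interval.start, s.interval.end) for s in segs if s.kind == "exon"
        ]
        assert exon_ivs.count((200, 300)) == 1

    def test_event_segments_are_enumerated(self):
        t1 = tx("t1", [(0, 100), (200, 300), (400, 500)])
        t2 = tx("t2", [(0, 100), (400, 500)])
        t3 = tx("t3", [(0, 300), (400, 500)])
        g = build_splicing_graph([t1, t2, t3])
        seg_keys = {(s.kind, s.interval.start, s.interval.end)
                    for s in enumerate_segments(g)}
        for ev in detect_ir_events(g) + detect_es_events(g):
            s = ev.segment
            assert (s.kind, s.interval.start, s.interval.end) in seg_keys


def _random_gene(rng: np.random.Generator):
    """Random gene: up to 5 transcripts over a shared exon scaffold."""
    n_slots = int(rng.integers(3, 7))
    bounds = np.sort(rng.choice(np.arange(1, 60), size=2 * n_slots, replace=False))
    slots = [(int(bounds[2 * i]) * 10, int(bounds[2 * i + 1]) * 10)
             for i in range(n_slots)]
    transcripts = []
    for k in range(int(rng.integers(1, 6))):
        keep = rng.random(n_slots) < 0.7
        if keep.sum() < 2:
            keep[:2] = True
        exons = [s for s, used in zip(slots, keep) if used]
        # occasionally fuse two neighboring slots into one exon (an IR form)
        if len(exons) >= 2 and rng.random() < 0.4:
            j = int(rng.integers(0, len(exons) - 1))
            exons = (
                exons[:j] + [(exons[j][0], exons[j + 1][1])] + exons[j + 2:]
            )
        transcripts.append(tx(f"t{k}", exons))
    return transcripts


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(40))
    def test_events_match_all_pairs_comparison(self, seed):
        rng = np.random.default_rng(seed)
        transcripts = _random_gene(rng)
        g = build_splicing_graph(transcripts)
        got_ir = {
            (e.segment.interval.start, e.segment.interval.end)
            for e in detect_ir_events(g)
        }
        got_es = {
            (e.segment.interval.start, e.segment.interval.end)
            for e in detect_es_events(g)
        }
        assert got_ir == brute_force_ir(transcripts)
        assert got_es == brute_force_es(transcripts)

    def test_invariant_under_order_and_duplication(self):
        rng = np.random.default_rng(123)
        transcripts = _random_gene(rng)
        g1 = build_splicing_graph(transcripts)
        shuffled = list(reversed(transcripts)) + [transcripts[0]]
        g2 = build_splicing_graph(shuffled)

        def key(events):
            return {(e.kind, e.segment.interval.start, e.segment.interval.end)
                    for e in events}

        assert key(detect_ir_events(g1)) == key(detect_ir_events(g2))
        assert key(detect_es_events(g1)) == key(detect_es_events(g2))


class TestGff3Roundtrip:
    def test_roundtrip(self, tmp_path):
        genes = {
            "G1": [
                tx("G1.1", [(0, 100), (200, 300), (400, 500)], gene_id="G1"),
                tx("G1.2", [(0, 100), (400, 500)], gene_id="G1"),
            ],
            "G2": [
                Transcript(
                    "G2.1", "G2", [iv(1000, 1100, strand="-"),
                                   iv(1200, 1400, strand="-")], "cdna"
                )
            ],
        }
        path = tmp_path / "genes.gff3"
        write_gff3(genes, str(path))
        back = read_gff3(str(path))
        assert set(back) == {"G1", "G2"}
        assert len(back["G1"]) == 2
        orig = {(e.start, e.end) for t in genes["G1"] for e in t.exons}
        got = {(e.start, e.end) for t in back["G1"] for e in t.exons}
        assert got == orig
        assert back["G2"][0].source == "cdna"
        assert back["G2"][0].strand == "-"
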
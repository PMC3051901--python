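from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicetile.arraydata import (
    GeneExpression,
    SampleInfo,
    assign_probes_to_segments,
    build_kmer_index,
    gene_expression,
    mask_repetitive_probes,
    quantile_normalize,
    quantile_normalize_columns,
    read_probe_matrix,
    read_sample_sheet,
    select_top_expressed_genes,
    transcript_normalize,
    write_probe_matrix,
    write_sample_sheet,
)
from splicetile.genome import Segment

from .conftest import iv, make_matrix, tx


def _tensor(columns: list[list[float]]) -> np.ndarray:
    """Stack per-array columns into a (probe, sample=1-col-per-3, 3) tensor."""
    arr = np.array(columns, dtype=float).T  # (probes, arrays)
    n, m = arr.shape
    assert m % 3 == 0
    return arr.reshape(n, m // 3, 3)


class TestQuantileNormalize:
    def test_identical_arrays_are_fixed_point(self):
        col = [3.0, 1.0, 2.0]
        m = make_matrix(_tensor([col] * 3))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_two_array_hand_computation(self):
        # arrays (1,2,3) and (10,20,30) -> both (5.5, 11, 16.5)
        arr = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        out = quantile_normalize_columns(arr)
        np.testing.assert_allclose(out[:, 0], [5.5, 11.0, 16.5])
        np.testing.assert_allclose(out[:, 1], [5.5, 11.0, 16.5])

    def test_distributions_identical_after(self):
        rng = np.random.default_rng(0)
        m = make_matrix(np.exp2(rng.normal(8, 1, (50, 2, 3))))
        out = quantile_normalize(m)
        flat = out.values.reshape(50, -1)
        ref = np.sort(flat[:, 0])
        for j in range(1, flat.shape[1]):
            np.testing.assert_allclose(np.sort(flat[:, j]), ref)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = make_matrix(np.exp2(rng.normal(8, 1, (30, 2, 3))))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)

    def test_ties_get_mean_of_reference(self):
        m = make_matrix(_tensor([[1, 1, 3], [10, 20, 30], [1, 2, 3]]))
        out = quantile_normalize(m)
        # tied ranks 1.5 -> mean of reference order stats 1 and 2
        ref = np.mean(
            [np.sort(c) for c in ([1, 1, 3], [10, 20, 30], [1, 2, 3])], axis=0
        )
        expected_tie = (ref[0] + ref[1]) / 2
        np.testing.assert_allclose(out.values[:, 0, 0][:2], expected_tie)


class TestMaskRepetitiveProbes:
    def _matrix_for(self, genome: str, starts):
        vals = np.full((len(starts), 1, 3), 100.0)
        return make_matrix(vals, starts=starts), {"chr1": genome}

    def test_unique_genome_unmasked(self):
        rng = np.random.default_rng(0)
        genome = "".join(rng.choice(list("ACGT"), 300))
        m, seqs = self._matrix_for(genome, [0, 35, 70])
        out = mask_repetitive_probes(m, sequences=seqs)
        assert not out.repetitive_mask.any()

    def test_duplicated_block_masks_contained_probes(self):
        rng = np.random.default_rng(1)
        block = "".join(rng.choice(list("ACGT"), 100))
        pad = "".join(rng.choice(list("ACGT"), 50))
        genome = block + pad + block
        # probe fully inside the first copy of the block
        m, seqs = self._matrix_for(genome, [10])
        out = mask_repetitive_probes(m, sequences=seqs)
        assert out.repetitive_mask[0]

    def test_boundary_probe_unmasked(self):
        rng = np.random.default_rng(2)
        block = "".join(rng.choice(list("ACGT"), 100))
        pad = "".join(rng.choice(list("ACGT"), 50))
        genome = block + pad + block
        # probe overlapping the block boundary by 1 bp is unique
        m, seqs = self._matrix_for(genome, [76])
        out = mask_repetitive_probes(m, sequences=seqs)
        assert not out.repetitive_mask[0]

    def test_missing_inputs_rejected(self):
        m, _ = self._matrix_for("A" * 100, [0])
        with pytest.raises(ValueError):
            mask_repetitive_probes(m)

    def test_reverse_complement_duplication_masked(self):
        rng = np.random.default_rng(3)
        block = "".join(rng.choice(list("ACGT"), 60))
        comp = str.maketrans("ACGT", "TGCA")
        genome = block + "".join(rng.choice(list("ACGT"), 40)) + block.translate(comp)[::-1]
        m, seqs = self._matrix_for(genome, [5])
        out = mask_repetitive_probes(m, sequences=seqs)
        assert out.repetitive_mask[0]


class TestAssignProbes:
    def _segments(self):
        return [
            Segment("G1", "exon", iv(0, 105), (), True),
            Segment("G1", "intron", iv(105, 128), (iv(0, 105), iv(128, 300)), True),
        ]

    def test_probe_spacing_geometry(self):
        # 105 bp exon tiled at 35 bp spacing holds >= 2 full probes
        m = make_matrix(np.full((4, 1, 3), 10.0), starts=[0, 35, 70, 105])
        exon = self._segments()[0]
        assignment = assign_probes_to_segments(m, [exon])
        assert len(assignment[exon.id]) >= 2

    def test_short_segment_gets_no_probes(self):
        m = make_matrix(np.full((4, 1, 3), 10.0), starts=[0, 35, 70, 105])
        intron = self._segments()[1]  # 23 bp < probe length
        assignment = assign_probes_to_segments(m, [intron])
        assert len(assignment[intron.id]) == 0

    def test_straddling_probe_assigned_to_neither(self):
        m = make_matrix(np.full((1, 1, 3), 10.0), starts=[90])  # spans 90-115
        segs = self._segments()
        assignment = assign_probes_to_segments(m, segs)
        assert all(len(v) == 0 for v in assignment.values())

    def test_masked_probes_excluded(self):
        m = make_matrix(np.full((2, 1, 3), 10.0), starts=[0, 35])
        m.repetitive_mask[0] = True
        exon = self._segments()[0]
        assignment = assign_probes_to_segments(m, [exon])
        assert list(assignment[exon.id]) == [1]

    def test_minus_strand_ordering(self):
        m = make_matrix(np.full((3, 1, 3), 10.0), starts=[0, 35, 70])
        seg = Segment("G1", "exon", iv(0, 105, strand="-"), (), True)
        assignment = assign_probes_to_segments(m, [seg])
        starts = m.probes["start"].to_numpy()[assignment[seg.id]]
        assert list(starts) == [70, 35, 0]


class TestGeneExpression:
    def test_constant(self):
        m = make_matrix(np.full((4, 2, 3), 2.0**7))
        ge = gene_expression(m, "G1", np.arange(4))
        np.testing.assert_allclose(ge.per_sample, 7.0)
        assert ge.pooled == 7.0

    def test_replicate_median(self):
        vals = np.array([[[2.0, 4.0, 8.0]]])  # log2 -> 1, 2, 3
        m = make_matrix(vals)
        ge = gene_expression(m, "G1", np.array([0]))
        assert ge.per_sample[0] == 2.0

    def test_two_probe_median(self):
        # log2 values 1..6 over 2 probes x 3 replicates -> median 3.5
        vals = np.exp2(np.array([[[1.0, 2, 3]], [[4.0, 5, 6]]]))
        m = make_matrix(vals)
        ge = gene_expression(m, "G1", np.arange(2))
        assert ge.per_sample[0] == 3.5

    def test_zero_probe_gene_rejected(self):
        m = make_matrix(np.full((1, 1, 3), 10.0))
        with pytest.raises(ValueError):
            gene_expression(m, "G1", np.empty(0, dtype=int))

    def test_invariant_under_probe_and_replicate_permutation(self):
        rng = np.random.default_rng(5)
        vals = np.exp2(rng.normal(8, 1, (6, 2, 3)))
        m1 = make_matrix(vals)
        perm = rng.permutation(6)
        m2 = make_matrix(vals[perm][:, :, [2, 0, 1]])
        g1 = gene_expression(m1, "G", np.arange(6))
        g2 = gene_expression(m2, "G", np.arange(6))
        np.testing.assert_allclose(g1.per_sample, g2.per_sample)


class TestSelectTopExpressed:
    def _expr(self, pooled):
        return [
            GeneExpression(f"G{i}", np.array([p]), p)
            for i, p in enumerate(pooled)
        ]

    def test_half(self):
        top = select_top_expressed_genes(self._expr([1, 4, 2, 3]), 0.5)
        assert top == {"G1", "G3"}

    def test_all(self):
        top = select_top_expressed_genes(self._expr([1, 2]), 1.0)
        assert len(top) == 2

    def test_tie_break_lexicographic(self):
        expr = [
            GeneExpression("Gb", np.array([2.0]), 2.0),
            GeneExpression("Ga", np.array([2.0]), 2.0),
            GeneExpression("Gc", np.array([5.0]), 5.0),
        ]
        assert select_top_expressed_genes(expr, 0.5) == {"Gc", "Ga"}

    def test_empty(self):
        assert select_top_expressed_genes([], 0.5) == set()


class TestTranscriptNormalize:
    def test_constant_offset_removed(self):
        genes = {"G1": [tx("t1", [(0, 130)], gene_id="G1")]}
        rng = np.random.default_rng(0)
        base = np.exp2(rng.normal(8, 0.5, (1, 4, 1)) * np.ones((1, 4, 3)))
        vals = np.vstack([base, base * 2.0])  # probe 2 offset +1 in log2
        m = make_matrix(vals, starts=[0, 35])
        out = transcript_normalize(m, genes)
        # probe offsets relative to the gene median must vanish
        logs = np.log2(out.values)
        med = np.median(logs.transpose(1, 0, 2).reshape(4, -1), axis=1)
        p_eff = np.median(np.median(logs, axis=2) - med[None, :], axis=1)
        np.testing.assert_allclose(p_eff, 0.0, atol=1e-9)

    def test_identity_when_probes_match_median(self):
        genes = {"G1": [tx("t1", [(0, 130)], gene_id="G1")]}
        vals = np.full((2, 2, 3), 2.0**8)
        m = make_matrix(vals, starts=[0, 35])
        out = transcript_normalize(m, genes)
        np.testing.assert_allclose(out.values, vals)

    def test_disabled_is_identity(self):
        genes = {"G1": [tx("t1", [(0, 130)], gene_id="G1")]}
        vals = np.full((2, 2, 3), 5.0)
        m = make_matrix(vals, starts=[0, 35])
        out = transcript_normalize(m, genes, enabled=False)
        assert out is m

    def test_symmetric_offsets_cancel(self):
        genes = {"G1": [tx("t1", [(0, 130)], gene_id="G1")]}
        base = np.full((1, 2, 3), 8.0)
        vals = np.exp2(np.vstack([base + 1.0, base - 1.0]))
        m = make_matrix(vals, starts=[0, 35])
        out = transcript_normalize(m, genes)
        logs = np.log2(out.values)
        np.testing.assert_allclose(logs[0], logs[1], atol=1e-9)


class TestIO:
    def test_probe_matrix_roundtrip(self, tmp_path, simple_samples):
        rng = np.random.default_rng(0)
        vals = np.exp2(rng.normal(8, 1, (5, 3, 3)))
        m = make_matrix(vals, samples=simple_samples)
        path = tmp_path / "probes.tsv"
        write_probe_matrix(m, str(path))
        back = read_probe_matrix(str(path), simple_samples)
        np.testing.assert_allclose(back.values, m.values, rtol=1e-5)
        assert list(back.probes["start"]) == list(m.probes["start"])

    def test_sample_sheet_roundtrip(self, tmp_path, simple_samples):
        path = tmp_path / "samples.tsv"
        write_sample_sheet(simple_samples, str(path))
        back = read_sample_sheet(str(path))
        assert back == simple_samples

    def test_stress_without_control_rejected(self):
        with pytest.raises(ValueError):
            SampleInfo("S01", "stress_treatment")


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_quantile_normalization_preserves_rank_order(seed):
    rng = np.random.default_rng(seed)
    vals = np.exp2(rng.normal(8, 1, (20, 2, 3)))
    m = make_matrix(vals)
    out = quantile_normalize(m)
    flat_in = vals.reshape(20, -1)
    flat_out = out.values.reshape(20, -1)
    for j in range(flat_in.shape[1]):
        order_in = np.argsort(flat_in[:, j], kind="stable")
        assert np.all(np.diff(flat_out[order_in, j]) >= 0)
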
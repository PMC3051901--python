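from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicetile.features import (
    POSITION_LIMITS,
    ExpressionBinning,
    GlobalPercentiles,
    compute_abs_features,
    compute_global_percentiles,
    compute_pos_features,
    compute_rel_features,
    fit_expression_binning,
    interp_histogram,
    probe_distances_to_3prime,
)

from .oracles import soft_histogram_scalar


class TestGlobalPercentiles:
    def test_one_to_hundred(self):
        # order-statistic interpolation oracle: P_q = 1 + (q/100) * 99
        gp = compute_global_percentiles(np.arange(1, 101))
        np.testing.assert_allclose(
            gp.values, [20.8, 40.6, 50.5, 60.4, 80.2]
        )

    def test_constant_input(self):
        gp = compute_global_percentiles(np.full(10, 7.0))
        np.testing.assert_allclose(gp.values, 7.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=100)
        gp1 = compute_global_percentiles(v)
        gp2 = compute_global_percentiles(rng.permutation(v))
        np.testing.assert_allclose(gp1.values, gp2.values)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            compute_global_percentiles(np.array([1.0, 2.0]))

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            GlobalPercentiles(np.array([5.0, 4.0, 3.0, 2.0, 1.0]))


class TestAbsFeatures:
    def test_single_probe_constant_replicates(self):
        np.testing.assert_allclose(
            compute_abs_features(np.array([5.0, 5.0, 5.0])), 5.0
        )

    def test_one_to_ten(self):
        f = compute_abs_features(np.arange(1, 11))
        expected = np.percentile(np.arange(1, 11), [20, 40, 50, 60, 80])
        np.testing.assert_allclose(f, expected)

    def test_replicate_permutation_invariant(self):
        v = np.array([1.0, 9.0, 4.0, 2.0, 8.0, 3.0])
        np.testing.assert_allclose(
            compute_abs_features(v), compute_abs_features(v[::-1])
        )


class TestRelFeatures:
    L = GlobalPercentiles(np.array([2.0, 4.0, 5.0, 6.0, 8.0]))

    def test_interior_interpolation(self):
        # I=4.5 between L2=4 and L3=5: alpha=(5-4.5)/(5-4)=0.5
        f = compute_rel_features(np.array([4.5]), self.L)
        np.testing.assert_allclose(f, [0, 0.5, 0.5, 0, 0])

    def test_boundary_branches(self):
        np.testing.assert_allclose(
            compute_rel_features(np.array([1.0]), self.L), [1, 0, 0, 0, 0]
        )
        np.testing.assert_allclose(
            compute_rel_features(np.array([9.0]), self.L), [0, 0, 0, 0, 1]
        )

    def test_value_at_first_limit_goes_to_first_bin(self):
        f = compute_rel_features(np.array([2.0]), self.L)
        np.testing.assert_allclose(f, [1, 0, 0, 0, 0])

    def test_conservation(self):
        rng = np.random.default_rng(1)
        v = rng.normal(5, 2, size=27)  # 9 probes x 3 replicates
        f = compute_rel_features(v, self.L)
        assert abs(f.sum() - 27) < 1e-9
        assert np.all(f >= 0)

    def test_additivity(self):
        rng = np.random.default_rng(2)
        v = rng.normal(5, 2, size=12)
        whole = compute_rel_features(v, self.L)
        parts = sum(compute_rel_features(np.array([x]), self.L) for x in v)
        np.testing.assert_allclose(whole, parts, atol=1e-12)


class TestBruteForceHistogramOracle:
    def test_1000_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            limits = np.sort(rng.normal(0, 3, size=rng.integers(2, 8)))
            value = rng.normal(0, 4)
            got = interp_histogram(np.array([value]), limits)
            want = soft_histogram_scalar(value, limits)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_draws_hitting_limits_exactly(self):
        rng = np.random.default_rng(43)
        for _ in range(200):
            limits = np.sort(
                rng.choice(np.arange(-5, 6), size=5, replace=False)
            ).astype(float)
            value = float(rng.integers(-6, 7))
            got = interp_histogram(np.array([value]), limits)
            want = soft_histogram_scalar(value, limits)
            np.testing.assert_allclose(got, want, atol=1e-12)
            assert abs(got.sum() - 1.0) < 1e-12


class TestPosFeatures:
    def test_distance_at_first_limit(self):
        f = compute_pos_features(np.array([100.0]))
        np.testing.assert_allclose(f, np.eye(10)[0])

    def test_distance_200_splits(self):
        # alpha = (300-200)/(300-100) = 0.5
        f = compute_pos_features(np.array([200.0]))
        expected = np.zeros(10)
        expected[0] = expected[1] = 0.5
        np.testing.assert_allclose(f, expected)

    def test_far_distance_last_bin(self):
        f = compute_pos_features(np.array([5000.0]))
        np.testing.assert_allclose(f, np.eye(10)[9])

    def test_one_unit_per_probe(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 3000, size=17)
        assert abs(compute_pos_features(d).sum() - 17) < 1e-9


class TestProbeDistances:
    # transcript: exons (0,100) and (200, 300); probe length 25
    EXONS = [(0, 100), (200, 300)]

    def test_plus_strand_exonic_spliced(self):
        # probe start 283 -> center 295; 3' end 299; spliced distance 4
        d = probe_distances_to_3prime(np.array([283]), self.EXONS, "+")
        assert d[0] == 4

    def test_plus_strand_upstream_exon_skips_intron(self):
        # center 62; exonic bases in (62, 299]: 37 in exon1 + 100 in exon2
        d = probe_distances_to_3prime(np.array([50]), self.EXONS, "+")
        assert d[0] == 137

    def test_plus_strand_intronic_collapses_to_boundary(self):
        # center 162 inside the intron projects onto the spliced coordinate
        # of the intron boundary: exonic bases in (162, 299] = 100
        d = probe_distances_to_3prime(np.array([150]), self.EXONS, "+")
        assert d[0] == 100

    def test_minus_strand(self):
        # 3' end at position 0; probe center 212: exonic bases in (0..211]
        d = probe_distances_to_3prime(np.array([200]), self.EXONS, "-")
        assert d[0] == 100 + 12

    def test_minus_strand_intronic(self):
        # exonic bases between the 3' end (position 0) and center 162: 100
        d = probe_distances_to_3prime(np.array([150]), self.EXONS, "-")
        assert d[0] == 100


class TestExpressionBinning:
    def test_one_to_hundred_bins(self):
        b = fit_expression_binning(np.arange(1, 101))
        assert b.bin_index(5) == 1
        assert b.bin_index(95) == 10

    def test_extremes(self):
        b = fit_expression_binning(np.arange(1, 101))
        assert b.bin_index(-100) == 1
        assert b.bin_index(1e9) == 10

    def test_partition(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=500)
        b = fit_expression_binning(v)
        bins = b.bin_index(v)
        assert bins.min() >= 1 and bins.max() <= 10
        # every value maps to exactly one bin by construction; roughly equal
        counts = np.bincount(bins, minlength=11)[1:]
        assert counts.sum() == 500

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            fit_expression_binning(np.arange(5))

    def test_degenerate_warns(self):
        with pytest.warns(UserWarning):
            fit_expression_binning(np.ones(50))


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.floats(min_value=-100, max_value=100, allow_nan=False),
        min_size=1,
        max_size=30,
    ),
    st.integers(min_value=0, max_value=2**31 - 1),
)
def test_histogram_conservation_property(values, seed):
    rng = np.random.default_rng(seed)
    limits = np.sort(rng.normal(0, 10, size=5))
    f = interp_histogram(np.array(values), limits)
    assert abs(f.sum() - len(values)) < 1e-9
    assert np.all(f >= -1e-12)
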
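"""Ground-truth sample processing: base, normalization, rectifier, trimming."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eodchirp as ec
from eodchirp.gt_processing import (
    ChirpAnnotation,
    GTSample,
    SampleError,
    center_index,
    cutoff,
    estimate_base,
    normalize_sample,
    rectified_cdf,
    rectify,
    trim_sample,
    trim_width,
    _group_for_count,
)
from eodchirp.signal_extraction import OscillationSeries


def flat_series(n, f=700.0, a=1.0, dt=1 / 700.0):
    T = np.arange(n) * dt
    return OscillationSeries(T, np.full(n, f), np.full(n, a))


def bump_sample(n=101, f_base=700.0, rise=100.0, a_base=1.0, drop=0.08,
                width=10.0):
    """A synthetic chirp-like sample: sech-ish bump in the middle."""
    j = np.arange(n) - n // 2
    shape = 1.0 / np.cosh(j / width)
    T = np.arange(n) / 750.0
    f = f_base + rise * shape
    A = a_base * (1 - drop * shape)
    return GTSample("rec", 0, T, f, A)


class TestBuildSample:
    def test_points_inside_annotation(self):
        series = flat_series(400)
        ann = ChirpAnnotation("rec", 0.1, 0.4)
        sample = ec.build_gt_sample(series, ann)
        inside = (series.T >= 0.1) & (series.T <= 0.4)
        assert len(sample) == inside.sum()
        assert sample.source_offset == int(np.flatnonzero(inside)[0])

    def test_too_few_points_is_an_error(self):
        series = flat_series(400)
        ann = ChirpAnnotation("rec", 0.1, 0.105)  # ~4 points
        with pytest.raises(SampleError, match="rec"):
            ec.build_gt_sample(series, ann)


class TestBaseEstimates:
    def test_balanced_edges_median(self):
        f = np.concatenate([np.full(10, 700.0), np.full(30, 900.0), np.full(10, 702.0)])
        A = np.ones(50)
        f_base, _ = estimate_base(f, A)
        assert f_base == 701.0

    def test_constant_sample(self):
        f = np.full(50, 700.0)
        f_base, A_base = estimate_base(f, np.ones(50))
        assert f_base == 700.0 and A_base == 1.0

    def test_outlier_in_tail_absorbed_by_median(self):
        A = np.concatenate([np.full(10, 1.0), np.ones(30),
                            np.full(9, 0.8), [5.0]])
        pooled = np.sort(np.concatenate([A[:10], A[-10:]]))
        expected = 0.5 * (pooled[9] + pooled[10])
        _, A_base = estimate_base(np.linspace(700, 800, 50), A)
        assert A_base == expected


class TestNormalization:
    def test_simple_values(self):
        f = np.array([700.0, 750.0, 800.0])
        A = np.array([1.0, 0.5, 1.0])
        phi, a = normalize_sample(f, A, f_base=700.0, A_base=1.0)
        assert phi[1] == pytest.approx(0.5)
        assert a[1] == pytest.approx(-0.5)

    def test_peak_is_exactly_one(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            f = 700 + rng.normal(0, 1, 101)
            f[50] += rng.uniform(50, 400)
            f_base, _ = estimate_base(f, np.ones(101))
            phi, _ = normalize_sample(f, np.ones(101), f_base, 1.0)
            assert phi.max() == 1.0

    def test_flat_sample_has_no_rise(self):
        f = np.full(101, 700.0)
        with pytest.raises(SampleError, match="rise"):
            normalize_sample(f, np.ones(101), 700.0, 1.0)

    def test_zero_base_amplitude_rejected(self):
        f = np.full(101, 700.0)
        f[50] = 800.0
        with pytest.raises(SampleError, match="amplitude"):
            normalize_sample(f, np.zeros(101), 700.0, 0.0)


class TestRectifier:
    def test_value_at_cutoff(self):
        # exponent vanishes at |phi| = cutoff: ln(2) / (delta - delta*cutoff)
        assert rectify(0.2, 0.2, 50.0) == pytest.approx(math.log(2) / 40.0)

    def test_asymptote_at_full_rise(self):
        assert rectify(1.0, 0.2, 50.0) == pytest.approx(1.0, abs=1e-6)

    def test_small_argument_series_expansion(self):
        # ln(1 + e^-10)/40 ~ e^-10/40
        assert rectify(0.0, 0.2, 50.0) == pytest.approx(math.exp(-10) / 40.0,
                                                        rel=1e-4)

    def test_no_overflow_for_extreme_arguments(self):
        out = rectify(np.array([50.0, -50.0]), 0.2, 50.0)
        assert np.all(np.isfinite(out))
        # linear asymptote: delta*(|phi| - cutoff) / (delta - delta*cutoff)
        assert out[0] == pytest.approx(50 * (50 - 0.2) / 40.0, rel=1e-6)

    def test_cutoff_at_or_above_one_rejected(self):
        with pytest.raises(ValueError):
            rectify(0.5, 1.0, 50.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        phi=st.floats(-2, 2, allow_nan=False),
        phi2=st.floats(-2, 2, allow_nan=False),
        phi_bar=st.floats(0, 0.9),
    )
    def test_even_and_monotone_in_magnitude(self, phi, phi2, phi_bar):
        h = rectify(phi, phi_bar)
        assert h == rectify(-phi, phi_bar)
        if abs(phi2) >= abs(phi):
            assert rectify(phi2, phi_bar) >= h


class TestCutoff:
    def test_zero_spread_edges(self):
        phi = np.concatenate([np.zeros(10), np.ones(30), np.full(10, 0.1)])
        assert cutoff(phi) == 0.0

    def test_alternating_head(self):
        head = np.tile([0.0, 0.1], 5)
        phi = np.concatenate([head, np.ones(20), np.zeros(10)])
        expected = 4.0 * np.std(head, ddof=1)
        assert cutoff(phi) == pytest.approx(expected)
        assert expected == pytest.approx(0.2108, abs=2e-4)

    def test_symmetric_in_head_and_tail(self):
        rng = np.random.default_rng(0)
        head, tail = rng.normal(0, 0.05, 10), rng.normal(0, 0.02, 10)
        a = np.concatenate([head, np.ones(30), tail])
        b = np.concatenate([tail, np.ones(30), head])
        assert cutoff(a) == cutoff(b)


class TestCentering:
    def test_point_mass_staircase(self):
        # nearly-point-mass rectified values {~0, ~0, 1, ~0, ~0}: H jumps
        # from ~0 to ~1 at the third point, which becomes the center
        h = np.array([0.01, 0.01, 1.0, 0.02, 0.02])
        H = np.cumsum(h) / h.sum()
        np.testing.assert_allclose(H[2:], 1.0, atol=0.04)
        assert center_index(H) == 2

    def test_tie_breaks_to_smallest_index(self):
        H = np.array([0.5, 0.5, 1.0])
        assert center_index(H) == 0

    def test_symmetric_bump_centers_in_middle(self):
        sample = bump_sample(101)
        _, j_cen = trim_sample(sample)
        assert abs(j_cen - 50) <= 1

    def test_cdf_is_monotone_and_ends_at_one(self):
        sample = bump_sample(101)
        f_base, A_base = estimate_base(sample.f, sample.A)
        phi, _ = normalize_sample(sample.f, sample.A, f_base, A_base)
        H = rectified_cdf(phi, cutoff(phi))
        assert np.all(np.diff(H) >= 0)
        assert H[-1] == pytest.approx(1.0, abs=1e-15)


class TestTrimming:
    def test_hand_built_staircase_width(self):
        # H crosses 0.1 at index 40 and 0.9 at index 60; times are 2 ms apart
        n = 101
        H = np.clip((np.arange(n) - 37.5) / 25.0, 0.0, 1.0)
        assert H[40] == 0.1 and H[60] == 0.9
        T_cen = (np.arange(n) - 50) * 0.002
        width = trim_width(H, T_cen)
        assert width == pytest.approx(0.04)
        keep = (T_cen >= -3 * width) & (T_cen <= 3 * width)
        assert T_cen[keep].min() >= -0.12 and T_cen[keep].max() <= 0.12

    def test_center_always_retained(self):
        sample = bump_sample(101)
        keep, j_cen = trim_sample(sample)
        assert keep[j_cen]

    def test_retrim_of_trimmed_sample_is_stable(self):
        sample = bump_sample(201, width=8.0)
        keep, _ = trim_sample(sample)
        trimmed = GTSample("rec", int(np.flatnonzero(keep)[0]),
                           sample.T[keep], sample.f[keep], sample.A[keep])
        keep2, _ = trim_sample(trimmed)
        # negligible rectified mass outside the first trim -> no further loss
        assert keep2.sum() >= keep.sum() - 2


class TestGrouping:
    def test_count_routes_to_expected_group(self):
        assert _group_for_count(5) == 1
        assert _group_for_count(50) == 2
        assert _group_for_count(500) == 3

    def test_group_boundaries_are_half_open(self):
        assert _group_for_count(11) == 1
        assert _group_for_count(12) == 2
        assert _group_for_count(101) == 2
        assert _group_for_count(102) == 3

    def test_oversized_count_clamped_to_largest_group(self):
        assert _group_for_count(1500) == 3

    def test_resampled_group2_member_has_101_points(self, g2_group):
        for s in g2_group.samples:
            assert len(s.T) == 101
            assert s.phi.max() == 1.0

    def test_every_surviving_sample_in_exactly_one_group(self, synth_study):
        _, anns, series = synth_study
        groups = ec.prepare_gt_groups(series, anns)
        total = sum(len(g) for g in groups.values())
        assert total <= len(anns)
        assert len(groups[2]) == total  # 20 ms type-2 chirps are all mid-scale

    def test_edge_overrunning_sample_dropped(self):
        # chirp too close to the recording start: its group-2 resampling
        # window (101 points around the center) would run off the edge
        n = 200
        series = flat_series(n)
        j = np.arange(n)
        f = 700.0 + 100.0 / np.cosh((j - 25) / 4.0)
        series = OscillationSeries(series.T, f, series.A)
        ann = ChirpAnnotation("rec", 0.0, n / 700.0)
        sample = ec.build_gt_sample(series, ann)
        groups = ec.group_and_resample([sample], {"rec": series})
        assert all(len(g) == 0 for g in groups.values())
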
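"""Alignment, rater fusion, smoothing, trimming and descriptives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_rating_table
from urgetide.data import SubjectBundle, UrgeTrace
from urgetide.preprocess import (
    align_urge,
    build_subject_series,
    combine_modalities,
    fuse_raters,
    instantaneous_intensity,
    subject_summary,
    trim_and_standardize,
)


class TestAlignUrge:
    def test_constant_trace_gives_constant_intervals(self):
        trace = UrgeTrace("s", 10.0, np.full(300, 40.0))
        assert np.allclose(align_urge(trace), 40.0)

    def test_standard_session_yields_300_intervals(self):
        trace = UrgeTrace("s", 10.0, np.linspace(0, 100, 3000))
        assert align_urge(trace).size == 300

    def test_interval_mean_of_arithmetic_sequence(self):
        values = np.concatenate([np.arange(0, 100, 10), np.full(10, 7.0)])
        trace = UrgeTrace("s", 10.0, values.astype(float))
        out = align_urge(trace)
        assert out[0] == pytest.approx(45.0)
        assert out[1] == pytest.approx(7.0)

    def test_last_sample_alignment_option(self):
        trace = UrgeTrace("s", 10.0, np.arange(20, dtype=float))
        assert np.array_equal(align_urge(trace, method="last"), [9.0, 19.0])

    def test_trace_shorter_than_interval_rejected(self):
        trace = UrgeTrace("s", 10.0, np.arange(5, dtype=float))
        with pytest.raises(ValueError, match="shorter"):
            align_urge(trace)


class TestFusion:
    def test_single_rater_tic_keeps_its_intensity(self):
        a = make_rating_table(motor_intensity=[2.0])
        b = make_rating_table(motor_intensity=[np.nan])
        mp, mi, _, _ = fuse_raters(a, b)
        assert mp[0] and mi[0] == 2.0

    def test_both_raters_average_intensity(self):
        a = make_rating_table(motor_intensity=[2.0])
        b = make_rating_table(motor_intensity=[4.0])
        _, mi, _, _ = fuse_raters(a, b)
        assert mi[0] == 3.0

    def test_no_rater_no_tic(self):
        a = make_rating_table(n=1)
        b = make_rating_table(n=1)
        mp, mi, _, _ = fuse_raters(a, b)
        assert not mp[0] and np.isnan(mi[0])

    def test_mismatched_grids_rejected(self):
        a = make_rating_table(n=3)
        b = make_rating_table(n=4)
        with pytest.raises(ValueError, match="grid"):
            fuse_raters(a, b)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_fusion_commutative_and_dominates_single_rater(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        mk = lambda: np.where(rng.random(n) < 0.4,
                              np.round(rng.uniform(1, 8, n)), np.nan)
        a = make_rating_table(motor_intensity=mk())
        b = make_rating_table(motor_intensity=mk(), rater_id="R2")
        pa_ab, ia_ab, _, _ = fuse_raters(a, b)
        pa_ba, ia_ba, _, _ = fuse_raters(b, a)
        assert np.array_equal(pa_ab, pa_ba)
        assert np.allclose(ia_ab, ia_ba, equal_nan=True)
        # disjunction never reports fewer tic intervals than either rater
        for t in (a, b):
            assert pa_ab.sum() >= t.table["motor_present"].sum()


class TestCombineModalities:
    @pytest.mark.parametrize(
        "motor, vocal, expected",
        [(3.0, 5.0, 5.0), (3.0, np.nan, 3.0), (np.nan, np.nan, np.nan)],
    )
    def test_max_combination_rules(self, motor, vocal, expected):
        out = combine_modalities(np.array([motor]), np.array([vocal]))
        if np.isnan(expected):
            assert np.isnan(out[0])
        else:
            assert out[0] == expected

    def test_combined_at_least_each_present_input(self):
        rng = np.random.default_rng(0)
        m = np.where(rng.random(50) < 0.5, rng.uniform(1, 8, 50), np.nan)
        v = np.where(rng.random(50) < 0.5, rng.uniform(1, 7, 50), np.nan)
        out = combine_modalities(m, v)
        ok = np.isfinite(m)
        assert np.all(out[ok] >= m[ok])
        ok = np.isfinite(v)
        assert np.all(out[ok] >= v[ok])

    def test_out_of_scale_intensity_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            combine_modalities(np.array([9.0]), np.array([np.nan]))


class TestInstantaneousIntensity:
    def test_constant_series_is_fixed_point(self):
        x = np.full(40, 2.5)
        assert np.allclose(instantaneous_intensity(x), 2.5)

    def test_single_event_spreads_over_window(self):
        x = np.zeros(50)
        x[25] = 11.0
        out = instantaneous_intensity(x, window_s=11)
        covered = slice(20, 31)
        assert np.allclose(out[covered], 1.0)
        mask = np.ones(50, dtype=bool)
        mask[covered] = False
        assert np.allclose(out[mask], 0.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_explicit_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 60)
        x = np.where(rng.random(n) < 0.5, rng.uniform(1, 8, n), np.nan)
        out = instantaneous_intensity(x, window_s=11)
        filled = np.nan_to_num(x)
        for t in range(n):
            lo, hi = max(0, t - 5), min(n - 1, t + 5)
            assert out[t] == pytest.approx(filled[lo : hi + 1].mean())

    def test_bounded_by_input_range(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 8, 100)
        out = instantaneous_intensity(x)
        assert out.min() >= x.min() - 1e-12 and out.max() <= x.max() + 1e-12


def _session_series(n=300, seed=0):
    rng = np.random.default_rng(seed)
    motor = np.where(rng.random(n) < 0.5, np.round(rng.uniform(1, 8, n)), np.nan)
    bundle = SubjectBundle(
        subject_id="S1",
        urge=UrgeTrace("S1", 10.0, np.clip(rng.normal(30, 10, n * 10), 0, 100)),
        rater_a=make_rating_table(motor_intensity=motor),
        rater_b=make_rating_table(motor_intensity=motor, rater_id="R2"),
    )
    return build_subject_series(bundle)


class TestTrimAndStandardize:
    def test_standard_session_keeps_280_intervals(self):
        out = trim_and_standardize(_session_series(), trim_s=10)
        assert out.n_intervals == 280
        assert out.times[0] == 10.0 and out.times[-1] == 289.0

    def test_zscores_have_mean_zero_unit_variance(self):
        out = trim_and_standardize(_session_series(seed=3))
        for z in (out.urge_z, out.inst_intensity_z):
            assert abs(z.mean()) < 1e-10
            assert abs(np.var(z, ddof=1) - 1.0) < 1e-10

    def test_constant_urge_flagged_degenerate_not_divided(self):
        s = _session_series()
        s.urge = np.full(s.n_intervals, 40.0)
        out = trim_and_standardize(s)
        assert out.degenerate_urge and out.urge_z is None
        assert np.allclose(out.urge, 40.0)

    def test_over_trimming_rejected(self):
        with pytest.raises(ValueError, match="trim"):
            trim_and_standardize(_session_series(n=19), trim_s=10)

    def test_restandardization_is_idempotent(self):
        out = trim_and_standardize(_session_series(seed=5))
        again = trim_and_standardize(
            _replace_raw_with_z(out), trim_s=0, standardize=True
        )
        assert np.allclose(again.urge_z, out.urge_z, atol=1e-10)


def _replace_raw_with_z(series):
    from dataclasses import replace

    return replace(
        series,
        urge=series.urge_z.copy(),
        inst_intensity=series.inst_intensity_z.copy(),
        urge_z=None,
        inst_intensity_z=None,
        standardized=False,
    )


class TestSubjectSummary:
    def test_all_tic_constant_intensity(self):
        s = _session_series()
        out = trim_and_standardize(s, standardize=False)
        out.tic = np.ones(out.n_intervals, dtype=bool)
        out.tic_intensity = np.full(out.n_intervals, 2.0)
        summ = subject_summary(out)
        assert summ.tic_freq_pct == 100.0
        assert summ.mean_tic_intensity == 2.0

    def test_partial_tic_fraction(self):
        out = trim_and_standardize(_session_series(), standardize=False)
        out.tic = np.zeros(280, dtype=bool)
        out.tic[:28] = True
        out.tic_intensity = np.where(out.tic, 3.0, np.nan)
        assert subject_summary(out).tic_freq_pct == pytest.approx(10.0)

    def test_matches_hand_computed_fixture(self):
        # 10-interval toy: urge 10..100, tics at intervals 1, 4, 8 with
        # intensities 2, 5, 3  ->  spreadsheet arithmetic
        out = trim_and_standardize(_session_series(), standardize=False)
        out.times = np.arange(10.0)
        out.urge = np.arange(10.0, 101.0, 10.0)
        out.tic = np.zeros(10, dtype=bool)
        out.tic[[1, 4, 8]] = True
        out.tic_intensity = np.full(10, np.nan)
        out.tic_intensity[[1, 4, 8]] = [2.0, 5.0, 3.0]
        summ = subject_summary(out)
        assert summ.mean_urge == pytest.approx(55.0)
        assert summ.sd_urge == pytest.approx(np.std(out.urge, ddof=1))
        assert summ.tic_freq_pct == pytest.approx(30.0)
        assert summ.mean_tic_intensity == pytest.approx(10.0 / 3.0)

    def test_no_tics_gives_nan_intensity(self):
        out = trim_and_standardize(_session_series(), standardize=False)
        out.tic = np.zeros(out.n_intervals, dtype=bool)
        out.tic_intensity = np.full(out.n_intervals, np.nan)
        assert np.isnan(subject_summary(out).mean_tic_intensity)
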
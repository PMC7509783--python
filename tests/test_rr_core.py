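import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvsym.rr_core import (
    AnalysisWindow,
    BeatSeries,
    EmptySeriesError,
    ValidationError,
    beats_to_rr,
    diff,
    extract_window,
    replace_ectopic,
)


def beats(times, labels=None):
    times = np.asarray(times, dtype=float)
    if labels is None:
        labels = ["N"] * times.size
    return BeatSeries(times, np.asarray(labels))


class TestBeatsToRR:
    def test_direct_differencing(self):
        rr = beats_to_rr(beats([0, 800, 1600, 2410]))
        np.testing.assert_allclose(rr.rr, [800, 800, 810])
        np.testing.assert_allclose(rr.start_times, [0, 800, 1600])

    def test_minimal_input(self):
        np.testing.assert_allclose(beats_to_rr(beats([0, 1000])).rr, [1000])

    def test_single_beat_rejected(self):
        with pytest.raises(EmptySeriesError):
            beats_to_rr(beats([0]))

    def test_non_increasing_times_rejected_naming_index(self):
        with pytest.raises(ValidationError, match="index 2"):
            beats([0, 800, 750])

    @given(
        st.lists(st.floats(200, 2000), min_size=2, max_size=50),
        st.floats(0, 1e6),
    )
    @settings(deadline=None, derandomize=True)
    def test_cumsum_round_trip(self, intervals, t0):
        """Differencing then cumulative summation recovers the beat times."""
        times = t0 + np.concatenate(([0.0], np.cumsum(intervals)))
        rr = beats_to_rr(beats(times))
        recovered = np.concatenate(([times[0]], times[0] + np.cumsum(rr.rr)))
        np.testing.assert_allclose(recovered, times, rtol=1e-12)


class TestReplaceEctopic:
    def test_single_ventricular_interpolated_to_midpoint(self):
        fixed, report = replace_ectopic(
            beats([0, 800, 1200, 2400], ["N", "N", "V", "N"])
        )
        np.testing.assert_allclose(fixed.beat_times, [0, 800, 1600, 2400])
        assert report.n_replaced == 1
        assert (fixed.beat_labels == "N").all()

    def test_all_normal_unchanged(self):
        src = beats([0, 810, 1590, 2400])
        fixed, report = replace_ectopic(src)
        np.testing.assert_array_equal(fixed.beat_times, src.beat_times)
        assert report.n_replaced == 0

    def test_run_of_two_equally_spaced(self):
        fixed, report = replace_ectopic(
            beats([0, 700, 1500, 2400], ["N", "V", "V", "N"])
        )
        np.testing.assert_allclose(fixed.beat_times, [0, 800, 1600, 2400])
        assert report.n_replaced == 2

    def test_preserves_endpoints_and_count(self):
        src = beats([0, 500, 1200, 2000, 3100], ["N", "S", "N", "A", "N"])
        fixed, _ = replace_ectopic(src)
        assert len(fixed) == len(src)
        assert fixed.beat_times[0] == src.beat_times[0]
        assert fixed.beat_times[-1] == src.beat_times[-1]

    def test_edge_ectopic_trimmed_with_warning(self):
        with pytest.warns(UserWarning, match="trimmed"):
            fixed, report = replace_ectopic(
                beats([0, 700, 1500, 2400], ["V", "N", "N", "N"])
            )
        assert report.n_trimmed == 1
        assert len(fixed) == 3

    def test_high_ectopic_fraction_warns(self):
        with pytest.warns(UserWarning, match="non-normal"):
            replace_ectopic(
                beats([0, 700, 1500, 2400, 3000], ["N", "V", "V", "V", "N"])
            )


class TestExtractWindow:
    def test_constant_1000ms_gives_300_intervals(self, metronome_beats):
        rr = beats_to_rr(metronome_beats)
        out = extract_window(rr, AnalysisWindow(300_000, "T1"))
        assert len(out) == 300
        assert out.window_label == "T1"

    def test_constant_750ms_gives_400_intervals(self):
        times = np.arange(0, 300_001, 750.0)
        rr = beats_to_rr(beats(times))
        out = extract_window(rr, AnalysisWindow(300_000, "T2"))
        assert len(out) == 400

    def test_window_before_recording_rejected(self, metronome_beats):
        rr = beats_to_rr(metronome_beats)
        with pytest.raises(ValidationError, match="before the recording"):
            extract_window(rr, AnalysisWindow(100_000, "T1"))

    def test_durations_sum_at_most_window_length(self, metronome_beats):
        rr = beats_to_rr(metronome_beats)
        out = extract_window(rr, AnalysisWindow(300_000, "T3"))
        assert out.rr.sum() <= 300_000

    def test_adjacent_windows_partition_intervals(self):
        times = np.arange(0, 601_000, 1000.0)
        rr = beats_to_rr(beats(times))
        w1 = extract_window(rr, AnalysisWindow(300_000, "T1"))
        w2 = extract_window(rr, AnalysisWindow(600_000, "T2"))
        shared = set(w1.start_times) & set(w2.start_times)
        assert not shared
        assert len(w1) + len(w2) == len(rr)


class TestDiff:
    def test_direct_rule(self, make_rr_series):
        d = diff(make_rr_series([800, 810, 805]))
        np.testing.assert_allclose(d.drr, [10, -5])

    def test_constant_series_all_zero(self, make_rr_series):
        assert not diff(make_rr_series([700.0] * 5)).drr.any()

    def test_single_difference(self, make_rr_series):
        np.testing.assert_allclose(diff(make_rr_series([616, 672])).drr, [56])

    def test_too_short_rejected(self, make_rr_series):
        with pytest.raises(EmptySeriesError):
            diff(make_rr_series([800]))

    def test_reconstruction_exact(self, make_rr_series, rng):
        rr = make_rr_series(rng.uniform(600, 1000, 200))
        np.testing.assert_allclose(diff(rr).reconstruct(), rr.rr, rtol=1e-12)
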
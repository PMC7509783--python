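import numpy as np
import pytest

from hrvsym.rr_core import beats_to_rr, diff
from hrvsym.symbolic import encode_sign, encode_threshold, pattern_distribution
from hrvsym.synthetic import (
    DEFAULT_PERIODS,
    CohortSpec,
    PeriodSpec,
    generate_cohort,
    generate_window,
)
from hrvsym.time_domain import time_domain


def period(label="T1", **kw):
    base = next(p for p in DEFAULT_PERIODS if p.label == label)
    from dataclasses import replace

    return replace(base, **kw)


class TestGenerateWindow:
    def test_metronome_produces_exact_beats(self):
        spec = PeriodSpec("T1", base_rr=1000, drift=0, a_lf=0, a_hf=0,
                          noise_sd=0)
        beats = generate_window(spec, seed=0)
        assert len(beats) == 300
        np.testing.assert_allclose(np.diff(beats.beat_times), 1000.0)

    def test_window_spans_five_minutes(self):
        beats = generate_window(period("T1"), seed=1)
        assert beats.beat_times[-1] < 300_000
        assert beats.beat_times[-1] > 295_000

    def test_seed_reproducibility(self):
        a = generate_window(period("T4"), seed=7)
        b = generate_window(period("T4"), seed=7)
        np.testing.assert_array_equal(a.beat_times, b.beat_times)

    def test_pure_hf_window_concentrates_power_in_hf(self):
        from hrvsym.frequency_domain import spectral_analysis

        spec = PeriodSpec("T1", base_rr=800, drift=0, a_lf=0, a_hf=20,
                          noise_sd=0)
        res = spectral_analysis(beats_to_rr(generate_window(spec, seed=3)))
        assert res.hf_pct >= 90

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PeriodSpec("T1", base_rr=-5)
        with pytest.raises(ValueError):
            PeriodSpec("T1", base_rr=800, f_lf=0.2)
        with pytest.raises(ValueError):
            generate_window(PeriodSpec("T1", base_rr=100, a_lf=60, a_hf=50))

    def test_strong_drift_triggers_segmentation(self, rng):
        from hrvsym.stationarity import segment

        spec = PeriodSpec("T4", base_rr=800, drift=-150, a_lf=0, a_hf=0,
                          noise_sd=5)
        hits = 0
        for _ in range(20):
            rr = beats_to_rr(generate_window(spec, seed=rng))
            hits += segment(rr.rr).n_segments >= 2
        assert hits >= 18


class TestGenerateCohort:
    @pytest.fixture(scope="class")
    def cohort(self):
        return generate_cohort(CohortSpec(n_subjects=6, seed=11))

    def test_shapes_and_markers(self, cohort):
        assert len(cohort.beats) == 6
        for sid, markers in cohort.markers.items():
            assert list(markers) == [f"T{i}" for i in range(1, 10)]
            assert markers["T9"] == pytest.approx(9 * 300_000)

    def test_seed_contract_identical_rerun(self, cohort):
        again = generate_cohort(CohortSpec(n_subjects=6, seed=11))
        for sid in cohort.beats:
            np.testing.assert_array_equal(
                cohort.beats[sid].beat_times, again.beats[sid].beat_times
            )
        assert cohort.vas.equals(again.vas)

    def test_different_seed_differs(self, cohort):
        other = generate_cohort(CohortSpec(n_subjects=6, seed=12))
        sid = next(iter(cohort.beats))
        assert not np.array_equal(
            cohort.beats[sid].beat_times, other.beats[sid].beat_times
        )

    def test_vas_missingness_present(self):
        c = generate_cohort(CohortSpec(n_subjects=24, seed=3,
                                       vas_missing_prob=0.15))
        assert c.vas.isna().any().any()
        assert c.vas.notna().sum().sum() > 0.6 * c.vas.size

    def test_gender_split(self, cohort):
        values = list(cohort.gender.values())
        assert values.count("f") == 3 and values.count("m") == 3

    def test_stress_ordering_recovered_by_pipeline(self, cohort):
        """T4 windows: shorter RR, lower RMSSD, more 0V patterns than T1."""
        from hrvsym.rr_core import AnalysisWindow, extract_window

        stats = {"T1": [], "T4": []}
        for sid, beats in cohort.beats.items():
            rr = beats_to_rr(beats)
            for label in ("T1", "T4"):
                w = extract_window(
                    rr, AnalysisWindow(cohort.markers[sid][label], label)
                )
                td = time_domain(w)
                p0v = pattern_distribution(encode_sign(diff(w))).p0v_pct
                p0vt = pattern_distribution(
                    encode_threshold(diff(w), 35.0)
                ).p0v_pct
                stats[label].append((td.mean_rr, td.rmssd, p0v, p0vt))
        t1 = np.median(stats["T1"], axis=0)
        t4 = np.median(stats["T4"], axis=0)
        assert t4[0] < t1[0]  # mean RR drops under stress
        assert t4[1] < t1[1]  # RMSSD drops
        assert t4[2] > t1[2]  # P0V% rises
        assert t4[3] > t1[3]  # P0V_tau% rises
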
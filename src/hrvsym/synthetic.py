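"""Synthetic TSST-like cohort generator.

Emulates the recording conditions of a stress-test session: nine 5-minute
analysis periods (T1-T2 waiting, T3-T5 stress test: speech preparation,
speech delivery, mental arithmetic, T6-T9 recovery), each with its own RR
baseline, linear within-window drift (the nonstationarity the diagnostics
should flag), band-limited LF (~0.10 Hz) and HF (~0.25 Hz) modulation,
per-beat noise, and per-period VAS stress scores with occasional missingness.

Per-window beat times are generated by stepping the instantaneous tachogram

    r(t) = base_rr + drift(t) + a_lf sin(2 pi f_lf t + phi1)
                               + a_hf sin(2 pi f_hf t + phi2) + eps

with t_{n+1} = t_n + r(t_n)/1000 s — a deliberately simple beat-emission
model that is adequate for exercising the analysis chain (an
integral-pulse-frequency-modulation model would be the physiological
refinement).

Default period parameters are frozen in :data:`DEFAULT_PERIODS`; they were
chosen once to mimic a strong acute-stress response (rest RR around 855 ms
dropping to about 616 ms under peak stress, depressed beat-to-beat
variability during stress, VAS peaking at the arithmetic task) and tests
assert orderings and directions on them, never exact real-cohort medians.

All randomness flows from one master seed through named per-subject,
per-period substreams, so any window can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .rr_core import PERIOD_LABELS, BeatSeries, WINDOW_MS


@dataclass(frozen=True)
class PeriodSpec:
    """Generation parameters for one 5-minute analysis period."""

    label: str
    base_rr: float  # ms
    drift: float = 0.0  # total linear baseline change over the window, ms
    # (applied centered: the baseline runs from base_rr - drift/2 to
    # base_rr + drift/2, so base_rr stays the window's mean level)
    a_lf: float = 25.0  # LF modulation amplitude, ms
    a_hf: float = 30.0  # HF modulation amplitude, ms
    f_lf: float = 0.10  # Hz
    f_hf: float = 0.25  # Hz
    noise_sd: float = 7.0  # per-beat white noise, ms
    vas_mu: float = 10.0  # mean perceived-stress score (0-100)
    vas_sd: float = 12.0
    vas_missing_prob: float = 0.0
    ectopic_prob: float = 0.0  # per-beat chance of a ventricular label

    def __post_init__(self) -> None:
        if self.base_rr <= 0:
            raise ValueError("base_rr must be positive")
        if not (0.04 <= self.f_lf < 0.15):
            raise ValueError("f_lf must lie in the LF band [0.04, 0.15)")
        if not (0.15 <= self.f_hf < 0.40):
            raise ValueError("f_hf must lie in the HF band [0.15, 0.4)")
        if min(self.a_lf, self.a_hf, self.noise_sd) < 0:
            raise ValueError("amplitudes and noise_sd must be >= 0")


#: Frozen per-period defaults emulating a pronounced TSST response:
#: waiting (T1-T2), stress test (T3 preparation, T4 speech, T5 arithmetic),
#: recovery (T6-T9).  Stress shortens the baseline RR, damps HF modulation
#: and per-beat noise (vagal withdrawal), and raises the VAS level.
DEFAULT_PERIODS: tuple[PeriodSpec, ...] = (
    PeriodSpec("T1", base_rr=855, drift=-40, a_lf=25, a_hf=28, noise_sd=7,
               vas_mu=8),
    PeriodSpec("T2", base_rr=813, drift=-40, a_lf=25, a_hf=27, noise_sd=7,
               vas_mu=9),
    PeriodSpec("T3", base_rr=750, drift=-60, a_lf=28, a_hf=22, noise_sd=6,
               vas_mu=38),
    PeriodSpec("T4", base_rr=616, drift=-40, a_lf=18, a_hf=8, noise_sd=3,
               vas_mu=40),
    PeriodSpec("T5", base_rr=672, drift=50, a_lf=18, a_hf=10, noise_sd=3.5,
               vas_mu=57),
    PeriodSpec("T6", base_rr=839, drift=80, a_lf=28, a_hf=33, noise_sd=8,
               vas_mu=18),
    PeriodSpec("T7", base_rr=882, drift=40, a_lf=26, a_hf=32, noise_sd=7,
               vas_mu=11),
    PeriodSpec("T8", base_rr=853, drift=-40, a_lf=27, a_hf=33, noise_sd=7,
               vas_mu=7),
    PeriodSpec("T9", base_rr=885, drift=40, a_lf=25, a_hf=30, noise_sd=7,
               vas_mu=5),
)


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic cohort: n subjects, gender split, nine period specs."""

    n_subjects: int = 24
    n_female: int | None = None  # default: half the cohort
    periods: tuple[PeriodSpec, ...] = DEFAULT_PERIODS
    between_subject_sd: float = 60.0  # subject-level RR baseline offset, ms
    period_jitter_sd: float = 20.0  # subject x period baseline jitter, ms
    vas_missing_prob: float = 0.08
    ectopic_prob: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.n_female is None:
            object.__setattr__(self, "n_female", self.n_subjects // 2)
        if not 0 <= self.n_female <= self.n_subjects:
            raise ValueError("n_female must lie in [0, n_subjects]")
        if tuple(p.label for p in self.periods) != PERIOD_LABELS:
            raise ValueError("periods must be exactly T1..T9 in order")


@dataclass
class SyntheticCohort:
    """Generated cohort: beat series, markers, VAS table, gender labels."""

    beats: dict[str, BeatSeries]
    markers: dict[str, dict[str, float]]  # subject -> {period: marker ms}
    vas: pd.DataFrame  # subjects x periods, NaN = missing
    gender: dict[str, str]  # subject -> "f" | "m"
    spec: CohortSpec


def generate_window(
    spec: PeriodSpec,
    seed: int | np.random.Generator | None = None,
    t_start: float = 0.0,
    duration_ms: float = WINDOW_MS,
) -> BeatSeries:
    """Generate one window's beat series by stepping the instantaneous tachogram.

    Beats are emitted from ``t_start`` (ms) until ``t_start + duration_ms``.
    Modulation phases are drawn uniformly from the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
    dur_s = duration_ms / 1000.0

    # worst-case baseline must stay positive
    floor = spec.base_rr - abs(spec.drift) - spec.a_lf - spec.a_hf
    if floor <= 5 * spec.noise_sd:
        raise ValueError(
            f"{spec.label}: instantaneous RR can reach {floor:.0f} ms; "
            "parameters risk a non-positive interval"
        )

    times = []
    labels = []
    t = 0.0  # seconds within window
    while t < dur_s:
        r = (
            spec.base_rr
            + spec.drift * (t / dur_s - 0.5)
            + spec.a_lf * np.sin(2 * np.pi * spec.f_lf * t + phi1)
            + spec.a_hf * np.sin(2 * np.pi * spec.f_hf * t + phi2)
            + rng.normal(0.0, spec.noise_sd)
        )
        if r <= 0:
            raise ValueError(f"{spec.label}: non-positive instantaneous RR")
        times.append(t_start + t * 1000.0)
        ectopic = spec.ectopic_prob > 0 and rng.random() < spec.ectopic_prob
        labels.append("V" if ectopic else "N")
        t += r / 1000.0
    if labels:
        labels[0] = labels[-1] = "N"  # keep normal anchors at the edges
    return BeatSeries(np.asarray(times), np.asarray(labels), subject_id="")


def generate_subject(
    spec: CohortSpec, subject_index: int, rng: np.random.Generator
) -> tuple[BeatSeries, dict[str, float]]:
    """Concatenate the nine period windows for one subject, with markers."""
    offset = rng.normal(0.0, spec.between_subject_sd)
    times = []
    labels = []
    markers = {}
    t0 = 0.0
    for period in spec.periods:
        pspec = replace(
            period,
            base_rr=period.base_rr + offset
            + rng.normal(0.0, spec.period_jitter_sd),
            ectopic_prob=spec.ectopic_prob,
        )
        w = generate_window(pspec, seed=rng, t_start=t0)
        times.append(w.beat_times)
        labels.append(w.beat_labels)
        t0 += WINDOW_MS
        markers[period.label] = t0
    beats = BeatSeries(
        np.concatenate(times),
        np.concatenate(labels),
        subject_id=f"S{subject_index:02d}",
    )
    return beats, markers


def generate_cohort(spec: CohortSpec = CohortSpec()) -> SyntheticCohort:
    """Generate the full cohort from a single master seed.

    Each subject gets an independent substream spawned from the master seed,
    so regenerating subject i alone reproduces its data exactly.
    """
    master = np.random.SeedSequence(spec.seed)
    subject_seeds = master.spawn(spec.n_subjects)

    beats = {}
    markers = {}
    vas_rows = {}
    gender = {}
    for i, sseed in enumerate(subject_seeds):
        rng = np.random.default_rng(sseed)
        b, m = generate_subject(spec, i, rng)
        beats[b.subject_id] = b
        markers[b.subject_id] = m
        gender[b.subject_id] = "f" if i < spec.n_female else "m"
        scores = {}
        for period in spec.periods:
            if rng.random() < spec.vas_missing_prob:
                scores[period.label] = np.nan
            else:
                raw = rng.normal(period.vas_mu, period.vas_sd)
                scores[period.label] = float(np.clip(raw, 0.0, 100.0))
        vas_rows[b.subject_id] = scores

    vas = pd.DataFrame.from_dict(vas_rows, orient="index")[list(PERIOD_LABELS)]
    vas.index.name = "subject"
    return SyntheticCohort(beats=beats, markers=markers, vas=vas,
                           gender=gender, spec=spec)
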
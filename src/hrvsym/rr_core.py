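"""Domain types for beat and RR-interval series.

The pipeline starts from annotated R-peak times (a :class:`BeatSeries`), not raw
ECG.  Ectopic (ventricular/supraventricular) and artifact beats are replaced by
interpolated beat times before the RR tachogram is formed, so downstream
statistics operate on normal-to-normal (NN) intervals.  Analysis windows are
the 5-minute stretches preceding each protocol marker (T1..T9).

All times are milliseconds from recording start; internal indexing is 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Beat annotation codes: normal, ventricular, supraventricular, artifact.
BEAT_LABELS = ("N", "V", "S", "A")

#: Protocol period labels in order (waiting, stress test, recovery).
PERIOD_LABELS = ("T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9")

#: Analysis window duration in ms (5 minutes).
WINDOW_MS = 300_000

#: Physiologic plausibility guard for a single RR interval (ms).
RR_GUARD = (200.0, 3000.0)


class EmptySeriesError(ValueError):
    """Raised when a series is too short for the requested operation."""


class ValidationError(ValueError):
    """Raised when input data violates a structural invariant."""


@dataclass(frozen=True)
class BeatSeries:
    """R-peak times with per-beat annotations.

    Parameters
    ----------
    beat_times : array of float
        Milliseconds from recording start, strictly increasing, all >= 0.
    beat_labels : array of str
        One of ``N`` (normal), ``V`` (ventricular), ``S`` (supraventricular),
        ``A`` (artifact) per beat.
    subject_id : str
        Opaque identifier carried through the pipeline.
    """

    beat_times: np.ndarray
    beat_labels: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.beat_times, dtype=float)
        labels = np.asarray(self.beat_labels, dtype="U1")
        object.__setattr__(self, "beat_times", times)
        object.__setattr__(self, "beat_labels", labels)
        if times.ndim != 1:
            raise ValidationError("beat_times must be 1-dimensional")
        if labels.shape != times.shape:
            raise ValidationError(
                f"beat_labels length {labels.size} != beat_times length {times.size}"
            )
        if times.size and times[0] < 0:
            raise ValidationError("beat_times must be non-negative")
        bad = np.flatnonzero(np.diff(times) <= 0)
        if bad.size:
            raise ValidationError(
                f"beat_times not strictly increasing at index {bad[0] + 1} "
                f"(t[{bad[0]}]={times[bad[0]]:g}, t[{bad[0] + 1}]={times[bad[0] + 1]:g})"
            )
        unknown = set(np.unique(labels)) - set(BEAT_LABELS)
        if unknown:
            raise ValidationError(f"unknown beat labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return self.beat_times.size


@dataclass(frozen=True)
class RRSeries:
    """RR-interval tachogram: interval durations and their onset times.

    ``start_times[i]`` is the onset of interval ``i``; when derived from a
    :class:`BeatSeries`, ``start_times[i+1] - start_times[i] == rr[i]``.
    """

    rr: np.ndarray
    start_times: np.ndarray
    window_label: str | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr, dtype=float)
        st = np.asarray(self.start_times, dtype=float)
        object.__setattr__(self, "rr", rr)
        object.__setattr__(self, "start_times", st)
        if rr.shape != st.shape or rr.ndim != 1:
            raise ValidationError("rr and start_times must be 1-d and equal length")
        if rr.size and rr.min() <= 0:
            raise ValidationError("all RR intervals must be positive")
        if rr.size and (rr.min() < RR_GUARD[0] or rr.max() > RR_GUARD[1]):
            warnings.warn(
                f"RR intervals outside physiologic guard {RR_GUARD} ms "
                f"(range {rr.min():.0f}-{rr.max():.0f} ms)",
                stacklevel=3,
            )
        if self.window_label is not None and self.window_label not in PERIOD_LABELS:
            raise ValidationError(f"unknown window label {self.window_label!r}")

    def __len__(self) -> int:
        return self.rr.size


@dataclass(frozen=True)
class DifferenceSeries:
    """First differences of a tachogram: drr[i] = rr[i+1] - rr[i]."""

    drr: np.ndarray
    rr0: float = 0.0  # first parent RR interval, kept so the parent is recoverable

    def __post_init__(self) -> None:
        object.__setattr__(self, "drr", np.asarray(self.drr, dtype=float))

    def __len__(self) -> int:
        return self.drr.size

    def reconstruct(self) -> np.ndarray:
        """Recover the parent RR values from rr0 and the cumulative sum."""
        return np.concatenate(([self.rr0], self.rr0 + np.cumsum(self.drr)))


@dataclass(frozen=True)
class AnalysisWindow:
    """A 5-minute analysis period ending at a protocol marker."""

    marker_time: float
    label: str
    duration: float = WINDOW_MS

    def __post_init__(self) -> None:
        if self.label not in PERIOD_LABELS:
            raise ValidationError(f"unknown window label {self.label!r}")

    @property
    def start(self) -> float:
        return self.marker_time - self.duration


@dataclass
class EctopicReport:
    """Bookkeeping from :func:`replace_ectopic`."""

    n_replaced: int = 0
    n_trimmed: int = 0
    warnings: list[str] = field(default_factory=list)


def beats_to_rr(beats: BeatSeries) -> RRSeries:
    """Form the RR tachogram as successive differences of beat times.

    rr[i] = beat_times[i+1] - beat_times[i]; start_times[i] = beat_times[i].
    """
    if len(beats) < 2:
        raise EmptySeriesError("need at least 2 beats to form RR intervals")
    return RRSeries(
        rr=np.diff(beats.beat_times),
        start_times=beats.beat_times[:-1],
        subject_id=beats.subject_id,
    )


def replace_ectopic(beats: BeatSeries) -> tuple[BeatSeries, EctopicReport]:
    """Replace ectopic/artifact beat times by linearly interpolated times.

    For a run of m non-normal beats between normal anchors at times t_a, t_b
    the replaced times are ``t_a + j*(t_b - t_a)/(m+1)`` (j = 1..m), i.e.
    linear interpolation of beat index vs. time.  Labels become normal.
    Non-normal beats at the series edges (no flanking anchor) are trimmed.
    """
    report = EctopicReport()
    times = beats.beat_times.copy()
    labels = beats.beat_labels.copy()
    normal = labels == "N"

    if not normal.any():
        raise ValidationError("series contains no normal beats")

    first, last = np.flatnonzero(normal)[[0, -1]]
    if first > 0 or last < len(beats) - 1:
        report.n_trimmed = int(first + (len(beats) - 1 - last))
        report.warnings.append(
            f"trimmed {report.n_trimmed} non-normal beat(s) at series edges"
        )
        times = times[first : last + 1]
        labels = labels[first : last + 1]
        normal = normal[first : last + 1]

    n_ectopic = int((~normal).sum())
    if n_ectopic:
        frac = n_ectopic / labels.size
        if frac > 0.05:
            report.warnings.append(
                f"{frac:.1%} of beats are non-normal (> 5%); "
                "interpolation may distort the tachogram"
            )
        idx = np.arange(labels.size)
        # anchor interpolation on normal beats only; edges are normal by now
        times = np.where(
            normal, times, np.interp(idx, idx[normal], times[normal])
        )
        labels = np.full_like(labels, "N")
        report.n_replaced = n_ectopic

    for msg in report.warnings:
        warnings.warn(msg, stacklevel=2)
    return BeatSeries(times, labels, beats.subject_id), report


def extract_window(rr: RRSeries, window: AnalysisWindow) -> RRSeries:
    """Select the intervals whose onsets fall in [marker - 5 min, marker).

    Membership is by interval onset in a half-open interval so that adjacent
    windows never share an interval.
    """
    if window.start < rr.start_times[0] - 1e-9:
        raise ValidationError(
            f"window {window.label} starts at {window.start:g} ms, "
            f"before the recording ({rr.start_times[0]:g} ms)"
        )
    mask = (rr.start_times >= window.start) & (rr.start_times < window.marker_time)
    if not mask.any():
        raise EmptySeriesError(f"no intervals fall inside window {window.label}")
    return RRSeries(
        rr=rr.rr[mask],
        start_times=rr.start_times[mask],
        window_label=window.label,
        subject_id=rr.subject_id,
    )


def diff(rr: RRSeries) -> DifferenceSeries:
    """First-difference series dRR_i = RR_{i+1} - RR_i (length N-1)."""
    if len(rr) < 2:
        raise EmptySeriesError("need at least 2 RR intervals to difference")
    return DifferenceSeries(drr=np.diff(rr.rr), rr0=float(rr.rr[0]))


def windows_from_markers(markers: dict[str, float]) -> list[AnalysisWindow]:
    """Build AnalysisWindows from a {label: marker_time_ms} mapping, in T order."""
    out = []
    for label in PERIOD_LABELS:
        if label in markers:
            out.append(AnalysisWindow(marker_time=float(markers[label]), label=label))
    return out
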
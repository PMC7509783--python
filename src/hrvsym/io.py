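"""Readers and writers for the plain-text interchange formats.

Formats
-------
tachogram
    One RR interval per line, in ms; ``#``-prefixed comment lines allowed.
beat annotations
    CSV with columns ``time_ms,label``; label in {N, V, S, A}.
markers
    CSV with columns ``label,time_ms``; labels T1..T9.
VAS scores
    CSV with columns ``subject,period,score``; missing scores are simply
    absent rows (or empty cells).
cohort matrix
    CSV with rows = subjects, columns = T1..T9, empty cell = missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .rr_core import PERIOD_LABELS, BeatSeries, RRSeries, ValidationError


def read_tachogram(path: str | Path, unit: str = "ms") -> RRSeries:
    """Read a plain-text tachogram (one RR interval per line).

    ``unit`` may be ``"ms"`` (default) or ``"s"``; seconds are converted.
    Interval onsets are reconstructed by cumulative summation from 0.
    """
    scale = {"ms": 1.0, "s": 1000.0}[unit]
    values = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            values.append(float(line) * scale)
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: not a number: {line!r}") from exc
    rr = np.asarray(values)
    starts = np.concatenate(([0.0], np.cumsum(rr[:-1]))) if rr.size else rr
    return RRSeries(rr=rr, start_times=starts)


def write_tachogram(rr: RRSeries, path: str | Path) -> None:
    lines = ["# RR intervals (ms), one per line"]
    lines += [f"{v:.6g}" for v in rr.rr]
    Path(path).write_text("\n".join(lines) + "\n")


def read_beats(path: str | Path, subject_id: str = "") -> BeatSeries:
    """Read an annotated beat CSV (``time_ms,label``)."""
    df = pd.read_csv(path)
    missing = {"time_ms", "label"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    try:
        return BeatSeries(
            beat_times=df["time_ms"].to_numpy(dtype=float),
            beat_labels=df["label"].astype(str).str.strip().to_numpy(),
            subject_id=subject_id or Path(path).stem,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_beats(beats: BeatSeries, path: str | Path) -> None:
    pd.DataFrame({"time_ms": beats.beat_times, "label": beats.beat_labels}).to_csv(
        path, index=False
    )


def read_markers(path: str | Path) -> dict[str, float]:
    """Read a marker CSV (``label,time_ms``) into an ordered {label: time} dict."""
    df = pd.read_csv(path)
    missing = {"label", "time_ms"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    markers = {}
    for _, row in df.iterrows():
        label = str(row["label"]).strip()
        if label not in PERIOD_LABELS:
            raise ValidationError(f"{path}: unknown marker label {label!r}")
        markers[label] = float(row["time_ms"])
    return {lab: markers[lab] for lab in PERIOD_LABELS if lab in markers}


def write_markers(markers: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"label": list(markers), "time_ms": list(markers.values())}
    ).to_csv(path, index=False)


def read_vas(path: str | Path) -> pd.DataFrame:
    """Read VAS scores into a subjects x periods DataFrame (NaN = missing)."""
    df = pd.read_csv(path)
    missing = {"subject", "period", "score"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    wide = df.pivot_table(index="subject", columns="period", values="score")
    return wide.reindex(columns=[c for c in PERIOD_LABELS if c in wide.columns])


def write_vas(wide: pd.DataFrame, path: str | Path) -> None:
    long = wide.stack().rename("score").reset_index()
    long.columns = ["subject", "period", "score"]
    long.to_csv(path, index=False)


def read_cohort_matrix(path: str | Path) -> pd.DataFrame:
    """Read a subjects x periods parameter table (empty cell = missing)."""
    return pd.read_csv(path, index_col=0)


def write_cohort_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path)
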
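"""Survey nonstationarity across all subject-windows: how often is the raw
RR series flagged nonstationary (heuristic segmentation and/or RWS test),
and how often does its difference series pass both diagnostics?

Spectral HRV assumes stationarity; this survey quantifies how rarely a
stress protocol satisfies it — and that the first-difference transform
restores it, which is what makes the symbolic-dynamics parameters robust.

Reads ``results/subject_windows/`` (from 02) and writes
``results/stationarity_survey.csv``.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--windows-dir", type=Path,
                        default=Path("results/subject_windows"))
    parser.add_argument("--out", type=Path,
                        default=Path("results/stationarity_survey.csv"))
    args = parser.parse_args()

    files = sorted(args.windows_dir.glob("subject_*_windows.csv"))
    if not files:
        sys.exit(f"no window tables in {args.windows_dir}; "
                 "run analysis/02_subject_windows.py first")

    frames = []
    for path in files:
        df = pd.read_csv(path, index_col=0)
        df["subject"] = path.name.removeprefix("subject_").removesuffix(
            "_windows.csv")
        frames.append(df)
    table = pd.concat(frames)

    per_period = table.groupby(table.index).agg(
        n_windows=("stationary_flag", "size"),
        rr_nonstationary=("stationary_flag", lambda s: int((~s).sum())),
        median_n_segments=("n_segments", "median"),
        drr_stationary=("d_stationary_flag", "sum"),
        median_drr_segments=("d_n_segments", "median"),
    )
    per_period.index.name = "period"
    args.out.parent.mkdir(parents=True, exist_ok=True)
    per_period.to_csv(args.out)

    total = len(table)
    rr_ns = int((~table["stationary_flag"].astype(bool)).sum())
    drr_ok = int(table["d_stationary_flag"].astype(bool).sum())
    print(per_period.to_string())
    print(f"\nRR series nonstationary in {rr_ns}/{total} windows "
          f"({100 * rr_ns / total:.1f}%)")
    print(f"difference series stationary in {drr_ok}/{total} windows "
          f"({100 * drr_ok / total:.1f}%)")
    print(f"summary in {args.out}")


if __name__ == "__main__":
    main()
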
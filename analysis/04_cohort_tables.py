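"""Cohort-level statistics: per-period median/IQR tables with omnibus
Friedman (Skillings-Mack for the incomplete VAS scores) p-values and
Holm-adjusted pairwise significance lists, plus per-period gender contrasts.

Reads the cohort data (01) and re-runs the per-subject analysis, then writes
one ``cohort_<parameter>_table.csv`` per parameter, an omnibus summary and
gender-contrast tables to ``results/cohort_tables/``.
"""

import argparse
import sys
import warnings
from pathlib import Path

import pandas as pd

from hrvsym import io as hio
from hrvsym.pipeline import AnalysisConfig, run_cohort, run_subject


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--data-dir", type=Path,
                        default=Path("results/cohort_data"))
    parser.add_argument("--out-dir", type=Path,
                        default=Path("results/cohort_tables"))
    args = parser.parse_args()

    beat_files = sorted(args.data_dir.glob("*_beats.csv"))
    if not beat_files:
        sys.exit(f"no cohort data in {args.data_dir}; "
                 "run analysis/01_simulate_cohort.py first")

    cfg = AnalysisConfig(seed=args.seed)
    reports = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for beats_path in beat_files:
            sid = beats_path.name.removesuffix("_beats.csv")
            beats = hio.read_beats(beats_path, subject_id=sid)
            markers = hio.read_markers(args.data_dir / f"{sid}_markers.csv")
            reports.append(run_subject(beats, markers, cfg))

    vas_path = args.data_dir / "vas.csv"
    vas = hio.read_vas(vas_path) if vas_path.exists() else None
    gender = None
    gender_path = args.data_dir / "gender.csv"
    if gender_path.exists():
        gender = pd.read_csv(gender_path, index_col=0)["gender"].to_dict()

    result = run_cohort(reports, vas=vas, gender=gender, cfg=cfg)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    for name, table in result.tables.items():
        table.rename_axis("period").to_csv(
            args.out_dir / f"cohort_{name}_table.csv")
    for name, table in result.gender.items():
        table.rename_axis("period").to_csv(
            args.out_dir / f"gender_{name}_table.csv")
    result.summary.to_csv(args.out_dir / "cohort_omnibus_summary.csv")

    print(result.summary.to_string())
    med = result.tables
    print("\nstress signature (cohort medians):")
    for name in ("mean_rr_ms", "rmssd_ms", "p0v_pct", "p0v_tau_pct", "vas"):
        t = med[name]["median"]
        print(f"  {name:12s}  T1 {t['T1']:8.1f}   T4 {t['T4']:8.1f}   "
              f"T9 {t['T9']:8.1f}")
    print(f"\ntables in {args.out_dir}")


if __name__ == "__main__":
    main()
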
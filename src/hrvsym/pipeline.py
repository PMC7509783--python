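"""Per-subject window analysis and cohort-level aggregation.

``run_subject`` executes the full per-window chain in recording order:
ectopic correction -> RR extraction -> per 5-min window: time-domain
parameters, spectral parameters, both symbolic encodings, and both
stationarity diagnostics.  ``run_cohort`` pivots the per-subject reports into
subjects x periods matrices, applies the natural-logarithm transform to the
skewed spectral powers, and runs the nonparametric statistics layer
(Friedman / Skillings-Mack omnibus, Wilcoxon-Holm post-hoc, Mann-Whitney
gender contrasts), emitting summary tables shaped like the classic
per-period median/IQR/significance listings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rr_core, symbolic, time_domain
from .cohort_stats import (
    ALPHA,
    CohortMatrix,
    PosthocResult,
    TestResult,
    describe,
    friedman,
    mann_whitney,
    posthoc,
    skillings_mack,
)
from .frequency_domain import SpectralConfig, band_powers, resample_tachogram
from .rr_core import BeatSeries, EmptySeriesError, ValidationError
from .stationarity import rws_test, segment

#: Parameters tested on the natural-log scale (right-skewed distributions).
LN_TRANSFORMED = ("lf_ms2", "hf_ms2", "lf_hf")

#: Per-window parameter columns produced by run_subject.
PARAMETER_COLUMNS = (
    "mean_rr_ms", "sdnn_ms", "rmssd_ms",
    "lf_ms2", "hf_ms2", "ln_lf", "ln_hf", "lf_hf", "lf_pct", "hf_pct",
    "total_power_ms2",
    "p0v_pct", "p1v_pct", "p2v_pct",
    "p0v_tau_pct", "p1v_tau_pct", "p2v_tau_pct",
    "n_segments", "rws_p_mean", "rws_p_var", "stationary_flag",
    "d_n_segments", "d_rws_p_mean", "d_rws_p_var", "d_stationary_flag",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunables of the per-window analysis chain."""

    tau_ms: float = 35.0
    window_ms: float = rr_core.WINDOW_MS
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    min_seg_len: int = 40
    seg_significance: float = 0.95
    rws_n_sub: int = 8
    rws_sub_len: int = 50
    sdnn_ddof: int = 1
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "spectral" in d:
            d["spectral"] = SpectralConfig(**d["spectral"])
        return cls(**d)


@dataclass
class SubjectReport:
    """Per-window parameter rows for one subject, keyed by period label."""

    subject_id: str
    windows: pd.DataFrame  # index = period labels, columns = PARAMETER_COLUMNS
    n_ectopic_replaced: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class CohortResult:
    """Cohort statistics bundle for all parameters."""

    matrices: dict[str, CohortMatrix]
    omnibus: dict[str, TestResult]
    posthoc: dict[str, PosthocResult]
    tables: dict[str, pd.DataFrame]  # per-period median / q25 / q75 / pairs
    gender: dict[str, pd.DataFrame]  # per-period Mann-Whitney p per parameter
    summary: pd.DataFrame


def analyze_window(rr: rr_core.RRSeries, cfg: AnalysisConfig,
                   rws_seed: int) -> dict:
    """All per-window parameters for one extracted 5-min RR series."""
    td = time_domain.time_domain(rr, ddof=cfg.sdnn_ddof)
    row: dict[str, float] = {
        "mean_rr_ms": td.mean_rr,
        "sdnn_ms": td.sdnn,
        "rmssd_ms": td.rmssd,
        "n_intervals": td.n_intervals,
    }

    try:
        _, uniform = resample_tachogram(rr, cfg.spectral)
        spec = band_powers(uniform, cfg.spectral)
    except EmptySeriesError:
        spec = None
    if spec is not None and spec.valid:
        row.update(
            lf_ms2=spec.lf, hf_ms2=spec.hf, ln_lf=spec.ln_lf, ln_hf=spec.ln_hf,
            lf_hf=spec.lf_hf_ratio, lf_pct=spec.lf_pct, hf_pct=spec.hf_pct,
            total_power_ms2=spec.total_power,
        )
    else:
        row.update({k: np.nan for k in ("lf_ms2", "hf_ms2", "ln_lf", "ln_hf",
                                        "lf_hf", "lf_pct", "hf_pct",
                                        "total_power_ms2")})

    d = rr_core.diff(rr)
    ps = symbolic.pattern_distribution(symbolic.encode_sign(d))
    pt = symbolic.pattern_distribution(symbolic.encode_threshold(d, cfg.tau_ms))
    row.update(
        p0v_pct=ps.p0v_pct, p1v_pct=ps.p1v_pct, p2v_pct=ps.p2v_pct,
        p0v_tau_pct=pt.p0v_pct, p1v_tau_pct=pt.p1v_pct, p2v_tau_pct=pt.p2v_pct,
        tau_ms=cfg.tau_ms,
    )

    seg = segment(rr.rr, cfg.min_seg_len, cfg.seg_significance)
    rws = rws_test(rr.rr, cfg.rws_n_sub, cfg.rws_sub_len, seed=rws_seed)
    row.update(
        n_segments=seg.n_segments, rws_p_mean=rws.p_mean, rws_p_var=rws.p_var,
        stationary_flag=seg.stationary and rws.stationary,
    )
    dseg = segment(d.drr, cfg.min_seg_len, cfg.seg_significance)
    drws = rws_test(d.drr, cfg.rws_n_sub, cfg.rws_sub_len, seed=rws_seed + 1)
    row.update(
        d_n_segments=dseg.n_segments, d_rws_p_mean=drws.p_mean,
        d_rws_p_var=drws.p_var,
        d_stationary_flag=dseg.stationary and drws.stationary,
    )
    return row


def run_subject(
    beats: BeatSeries,
    markers: dict[str, float],
    cfg: AnalysisConfig = AnalysisConfig(),
) -> SubjectReport:
    """Analyze one subject: ectopic correction, RR extraction, per-window chain.

    A window the recording does not cover is reported as a missing row (the
    run continues); structural errors in the input still raise.
    """
    corrected, ect_report = rr_core.replace_ectopic(beats)
    rr = rr_core.beats_to_rr(corrected)
    report = SubjectReport(
        subject_id=beats.subject_id,
        windows=pd.DataFrame(),
        n_ectopic_replaced=ect_report.n_replaced,
        warnings=list(ect_report.warnings),
    )

    rows = {}
    for i, window in enumerate(rr_core.windows_from_markers(markers)):
        try:
            wrr = rr_core.extract_window(rr, window)
            # derive a per-window RWS seed from config seed + window position
            rows[window.label] = analyze_window(
                wrr, cfg, rws_seed=cfg.seed * 1000 + i * 2
            )
        except (EmptySeriesError, ValidationError) as exc:
            report.warnings.append(f"{window.label}: {exc}")
            rows[window.label] = {}
    report.windows = pd.DataFrame.from_dict(rows, orient="index")
    return report


def run_cohort(
    reports: list[SubjectReport],
    vas: pd.DataFrame | None = None,
    gender: dict[str, str] | None = None,
    cfg: AnalysisConfig = AnalysisConfig(),
    parameters: tuple[str, ...] | None = None,
) -> CohortResult:
    """Aggregate subject reports into cohort matrices and run the statistics.

    Spectral powers listed in :data:`LN_TRANSFORMED` are rank-tested on the
    ln scale (the descriptive tables keep ln units for those parameters, as
    is conventional).  VAS, which may have missing cells, is tested with
    Skillings-Mack; complete HRV parameters use Friedman.
    """
    if len(reports) < 2:
        raise ValueError("cohort analysis needs at least 2 subjects")
    if parameters is None:
        parameters = (
            "mean_rr_ms", "sdnn_ms", "rmssd_ms",
            "lf_ms2", "hf_ms2", "lf_hf", "lf_pct", "hf_pct",
            "p0v_pct", "p1v_pct", "p2v_pct",
            "p0v_tau_pct", "p1v_tau_pct", "p2v_tau_pct",
        )

    matrices: dict[str, CohortMatrix] = {}
    omnibus: dict[str, TestResult] = {}
    post: dict[str, PosthocResult] = {}
    tables: dict[str, pd.DataFrame] = {}
    gender_tables: dict[str, pd.DataFrame] = {}

    wide_all = {}
    for param in parameters:
        wide = pd.DataFrame(
            {r.subject_id: r.windows.get(param, pd.Series(dtype=float))
             for r in reports}
        ).T
        wide = wide.reindex(columns=[c for c in rr_core.PERIOD_LABELS
                                     if c in wide.columns])
        if wide.notna().sum().sum() == 0:
            warnings.warn(f"parameter {param!r} has no observations; skipped")
            continue
        name = param
        if param in LN_TRANSFORMED:
            name = "ln_" + param
            with np.errstate(divide="ignore"):
                wide = np.log(wide.where(wide > 0))
        wide_all[name] = wide

    if vas is not None:
        wide_all["vas"] = vas.copy()

    for name, wide in wide_all.items():
        m = CohortMatrix(values=wide, parameter_name=name)
        matrices[name] = m
        if wide.isna().any().any():
            res = skillings_mack(m)
        else:
            res = friedman(m)
        omnibus[name] = res
        post[name] = posthoc(m, res)
        tables[name] = _period_table(m, res, post[name])
        if gender:
            gender_tables[name] = _gender_table(m, gender)

    summary = pd.DataFrame(
        {
            "parameter": list(omnibus),
            "method": [omnibus[k].method for k in omnibus],
            "statistic": [omnibus[k].statistic for k in omnibus],
            "df": [omnibus[k].df for k in omnibus],
            "p": [omnibus[k].p for k in omnibus],
            "n_significant_pairs": [
                len(post[k].significant_pairs) for k in omnibus
            ],
        }
    ).set_index("parameter")
    return CohortResult(
        matrices=matrices, omnibus=omnibus, posthoc=post, tables=tables,
        gender=gender_tables, summary=summary,
    )


def _period_table(m: CohortMatrix, omnibus: TestResult,
                  post: PosthocResult) -> pd.DataFrame:
    """Median / IQR / significant-partners rows per period."""
    rows = {}
    sig = post.significant_pairs
    for label in m.period_labels:
        med, q25, q75 = describe(m.values[label])
        partners = sorted(
            {a if b == label else b for a, b in sig if label in (a, b)}
        )
        rows[label] = {
            "median": med, "q25": q25, "q75": q75,
            "omnibus_p": omnibus.p,
            "significant_vs": ",".join(partners),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _gender_table(m: CohortMatrix, gender: dict[str, str]) -> pd.DataFrame:
    """Per-period Mann-Whitney contrast between gender groups."""
    rows = {}
    g = pd.Series(gender).reindex(m.values.index)
    for label in m.period_labels:
        col = m.values[label]
        a = col[g == "f"].dropna()
        b = col[g == "m"].dropna()
        if len(a) == 0 or len(b) == 0:
            rows[label] = {"p": np.nan, "median_f": np.nan, "median_m": np.nan}
            continue
        rows[label] = {
            "p": mann_whitney(a, b).p,
            "median_f": float(a.median()),
            "median_m": float(b.median()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
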
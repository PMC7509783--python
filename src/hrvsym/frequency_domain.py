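"""Frequency-domain HRV: the fixed spectral recipe for 5-min tachograms.

The tachogram (an unevenly sampled series: one RR value per beat, plotted at
the interval onset) is interpolated to a uniform 4 Hz grid with a cubic
spline, linearly detrended, Hanning-windowed, zero-padded to 2048 points and
Fourier transformed.  The one-sided power spectrum is rescaled by a single
factor so that its total equals the variance of the detrended series — this
makes band powers window-function independent and expresses them in ms².

Band powers: LF 0.04–0.15 Hz, HF 0.15–0.4 Hz (half-open [low, high) bins, so
the shared 0.15 Hz edge is counted once, in HF).  Derived quantities: natural
logarithms of LF and HF, LF/HF, and LF%/HF% relative to total power (all bins
above 0 Hz, i.e. including the VLF range below 0.04 Hz by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

from .rr_core import EmptySeriesError, RRSeries


@dataclass(frozen=True)
class SpectralConfig:
    """Spectral estimation settings (defaults are the standard recipe)."""

    resample_hz: float = 4.0
    n_fft: int = 2048
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.4)
    interpolation: str = "cubic"  # or "linear"
    include_vlf_in_total: bool = True

    def __post_init__(self) -> None:
        if self.lf_band[1] != self.hf_band[0]:
            raise ValueError("LF upper edge must equal HF lower edge")
        if not self.lf_band[0] < self.lf_band[1] < self.hf_band[1]:
            raise ValueError("bands must be ordered and non-degenerate")


@dataclass(frozen=True)
class SpectralResult:
    """Band powers (ms²) and derived ratios for one window.

    ``lf_pct``/``hf_pct``/``lf_hf_ratio``/``ln_*`` are NaN when undefined
    (zero-variance input or an empty band), with ``valid`` flagging it.
    """

    total_power: float
    lf: float
    hf: float
    ln_lf: float
    ln_hf: float
    lf_hf_ratio: float
    lf_pct: float
    hf_pct: float
    valid: bool = True


def resample_tachogram(
    rr: RRSeries, cfg: SpectralConfig = SpectralConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate the tachogram onto a uniform grid at ``cfg.resample_hz``.

    Returns ``(t, x)``: grid times in seconds (relative to the first interval
    onset) and interpolated RR values in ms.  The grid spans only the knot
    range — no extrapolation.
    """
    if len(rr) < 4:
        raise EmptySeriesError("resampling needs at least 4 intervals")
    t_knots = (rr.start_times - rr.start_times[0]) / 1000.0  # s
    if t_knots[-1] < 2.0:
        raise EmptySeriesError("tachogram spans less than 2 s")
    step = 1.0 / cfg.resample_hz
    t = np.arange(0.0, t_knots[-1] + 1e-12, step)
    if cfg.interpolation == "cubic":
        x = CubicSpline(t_knots, rr.rr)(t)
    else:
        x = interp1d(t_knots, rr.rr)(t)
    return t, x


def band_powers(
    x: np.ndarray, cfg: SpectralConfig = SpectralConfig()
) -> SpectralResult:
    """Estimate LF/HF band powers from a uniformly resampled tachogram.

    Steps: least-squares linear detrend; Hanning window; zero-pad to
    ``cfg.n_fft``; one-sided power spectrum; global rescale so total power
    equals the variance (ddof=1) of the detrended series; half-open band
    sums; derived logs, ratio and percentages.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n > cfg.n_fft:
        raise ValueError(f"series length {n} exceeds n_fft={cfg.n_fft}")
    if n < 4:
        raise EmptySeriesError("band_powers needs at least 4 samples")

    t = np.arange(n)
    detrended = x - np.polyval(np.polyfit(t, x, 1), t)
    variance = float(np.var(detrended, ddof=1))
    # numerically-zero variance (constant or purely linear input) is "no power"
    var_floor = 1e-20 * max(1.0, float(np.mean(x)) ** 2)
    if variance <= var_floor or not np.isfinite(variance):
        nan = float("nan")
        return SpectralResult(0.0, 0.0, 0.0, nan, nan, nan, nan, nan, valid=False)

    tapered = detrended * np.hanning(n)
    spec = np.abs(np.fft.rfft(tapered, n=cfg.n_fft)) ** 2
    freqs = np.fft.rfftfreq(cfg.n_fft, d=1.0 / cfg.resample_hz)

    positive = freqs > 0
    raw_total = spec[positive].sum()
    scale = variance / raw_total
    power = spec * scale  # per-bin power, ms²; sums (not densities) by design

    def band_sum(lo: float, hi: float) -> float:
        return float(power[(freqs >= lo) & (freqs < hi)].sum())

    lf = band_sum(*cfg.lf_band)
    hf = band_sum(*cfg.hf_band)
    if cfg.include_vlf_in_total:
        total = float(power[positive].sum())
    else:
        total = float(power[(freqs >= cfg.lf_band[0])].sum())

    ln_lf = math.log(lf) if lf > 0 else float("nan")
    ln_hf = math.log(hf) if hf > 0 else float("nan")
    ratio = lf / hf if hf > 0 else float("nan")
    return SpectralResult(
        total_power=total,
        lf=lf,
        hf=hf,
        ln_lf=ln_lf,
        ln_hf=ln_hf,
        lf_hf_ratio=ratio,
        lf_pct=100.0 * lf / total,
        hf_pct=100.0 * hf / total,
        valid=True,
    )


def spectral_analysis(
    rr: RRSeries, cfg: SpectralConfig = SpectralConfig()
) -> SpectralResult:
    """Full recipe: resample, then band powers."""
    _, x = resample_tachogram(rr, cfg)
    return band_powers(x, cfg)
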
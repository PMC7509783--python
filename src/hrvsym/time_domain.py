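"""Classical time-domain HRV parameters per analysis window."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rr_core import EmptySeriesError, RRSeries


@dataclass(frozen=True)
class TimeDomainResult:
    """Mean RR, SDNN and RMSSD of one analysis window, in ms."""

    mean_rr: float
    sdnn: float
    rmssd: float
    n_intervals: int


def time_domain(rr: RRSeries, ddof: int = 1) -> TimeDomainResult:
    """Compute mean RR, SDNN and RMSSD.

    SDNN is the standard deviation of the intervals (sample convention,
    denominator N-1, configurable via ``ddof``); RMSSD is the root mean
    square of successive interval differences.
    """
    if len(rr) < 2:
        raise EmptySeriesError("time-domain parameters need at least 2 intervals")
    x = rr.rr
    return TimeDomainResult(
        mean_rr=float(np.mean(x)),
        sdnn=float(np.std(x, ddof=ddof)),
        rmssd=float(np.sqrt(np.mean(np.diff(x) ** 2))),
        n_intervals=len(rr),
    )
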
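"""Binary symbolic dynamics of RR-interval differences.

Two coarse-grainings of the difference series dRR:

sign encoding
    0 for dRR >= 0 (heart-rate deceleration or no change), 1 for dRR < 0
    (acceleration).  Parameter-free.
threshold encoding
    0 for |dRR| < tau, 1 for |dRR| >= tau: small versus large beat-to-beat
    changes.  Default tau = 35 ms, roughly 5% of a typical grand-average RR
    interval.

Every overlapping word of length 3 is classified by the number of symbol
changes between successive positions: 0V (000, 111), 1V (001, 100, 110, 011)
or 2V (101, 010).  The relative frequencies P0V%/P1V%/P2V% are the HRV
parameters: high P0V% tracks sympathetic dominance, high P1V% parasympathetic
modulation.  Because the encodings are functions of the difference series,
they are insensitive to the slow baseline shifts that break the stationarity
assumption of spectral HRV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rr_core import DifferenceSeries, EmptySeriesError

WORD_LENGTH = 3

#: Category of each of the 8 binary words, by number of adjacent symbol changes.
CATEGORIES = ("0V", "1V", "2V")


@dataclass(frozen=True)
class SymbolicSequence:
    """A binary symbol sequence with its encoding provenance."""

    symbols: np.ndarray
    encoding: str  # "sign" or "threshold"
    tau: float | None = None  # ms; present iff encoding == "threshold"

    def __post_init__(self) -> None:
        s = np.asarray(self.symbols, dtype=np.int8)
        object.__setattr__(self, "symbols", s)
        if s.size and not np.isin(s, (0, 1)).all():
            raise ValueError("symbol alphabet must be {0, 1}")

    def __len__(self) -> int:
        return self.symbols.size


@dataclass(frozen=True)
class PatternDistribution:
    """Counts and percentages of 0V/1V/2V words in a symbolic sequence."""

    n0v: int
    n1v: int
    n2v: int
    n_words: int
    encoding: str
    tau: float | None = None

    @property
    def p0v_pct(self) -> float:
        return 100.0 * self.n0v / self.n_words

    @property
    def p1v_pct(self) -> float:
        return 100.0 * self.n1v / self.n_words

    @property
    def p2v_pct(self) -> float:
        return 100.0 * self.n2v / self.n_words


def encode_sign(d: DifferenceSeries) -> SymbolicSequence:
    """Sign encoding: 0 where dRR >= 0, 1 where dRR < 0."""
    if len(d) < 1:
        raise EmptySeriesError("cannot encode an empty difference series")
    return SymbolicSequence(symbols=(d.drr < 0).astype(np.int8), encoding="sign")


def encode_threshold(d: DifferenceSeries, tau: float = 35.0) -> SymbolicSequence:
    """Threshold encoding: 0 where |dRR| < tau, 1 where |dRR| >= tau."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if len(d) < 1:
        raise EmptySeriesError("cannot encode an empty difference series")
    return SymbolicSequence(
        symbols=(np.abs(d.drr) >= tau).astype(np.int8), encoding="threshold", tau=tau
    )


def classify_word(word) -> str:
    """Classify a length-3 binary word by its number of adjacent changes."""
    w = np.asarray(word, dtype=np.int8)
    if w.shape != (WORD_LENGTH,):
        raise ValueError(f"word must have exactly {WORD_LENGTH} symbols")
    if not np.isin(w, (0, 1)).all():
        raise ValueError("word alphabet must be {0, 1}")
    changes = int(np.count_nonzero(np.diff(w)))
    return CATEGORIES[changes]


def pattern_distribution(s: SymbolicSequence) -> PatternDistribution:
    """Count categories over all overlapping length-3 words (step 1)."""
    if len(s) < WORD_LENGTH:
        raise EmptySeriesError(
            f"need at least {WORD_LENGTH} symbols, got {len(s)}"
        )
    changes = np.abs(np.diff(s.symbols))  # 1 where adjacent symbols differ
    n_changes_per_word = changes[:-1] + changes[1:]  # 0, 1 or 2 per word
    counts = np.bincount(n_changes_per_word, minlength=3)
    return PatternDistribution(
        n0v=int(counts[0]),
        n1v=int(counts[1]),
        n2v=int(counts[2]),
        n_words=len(s) - WORD_LENGTH + 1,
        encoding=s.encoding,
        tau=s.tau,
    )
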
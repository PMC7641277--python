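"""Baroreflex sequence analysis on beat-aligned SBP and RR series.

A spontaneous baroreflex sequence is three consecutive beats of monotone
systolic-blood-pressure change (each step at least 0.5 mmHg) accompanied by
same-direction RR changes (each at least 2 ms) one beat later; the slope of
the RR-on-SBP regression over the triple estimates baroreflex gain, and the
triple is kept only if |r| > 0.85.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import BeatSeries, SanephysError


@dataclass
class BaroSequence:
    start_beat: int
    kind: str                 # "up" | "down"
    sbp: tuple                # mmHg triple
    rr: tuple                 # ms triple (lagged)
    slope: float              # ms/mmHg
    r: float


@dataclass
class SequenceResult:
    up_sequences: list = field(default_factory=list)
    down_sequences: list = field(default_factory=list)

    @property
    def n_up(self) -> int:
        return len(self.up_sequences)

    @property
    def n_down(self) -> int:
        return len(self.down_sequences)

    @property
    def mean_slope_up(self) -> float:
        if not self.up_sequences:
            return float("nan")
        return float(np.mean([s.slope for s in self.up_sequences]))

    @property
    def mean_slope_down(self) -> float:
        if not self.down_sequences:
            return float("nan")
        return float(np.mean([s.slope for s in self.down_sequences]))

    def summary(self) -> str:
        return (
            f"up: n={self.n_up}, slope {self.mean_slope_up:.2f} ms/mmHg | "
            f"down: n={self.n_down}, slope {self.mean_slope_down:.2f} ms/mmHg"
        )


def _excluded(i: int, j: int, exclusions) -> bool:
    """Whether beat range [i, j] intersects an excluded (start, end) interval."""
    for a, b in exclusions:
        if i <= b and j >= a:
            return True
    return False


def scan_sequences(
    beats: BeatSeries,
    sbp_threshold: float = 0.5,
    rr_threshold: float = 2.0,
    delay: int = 1,
    min_r: float = 0.85,
    exclusions: tuple = (),
) -> SequenceResult:
    """Scan every beat triple for up and down baroreflex sequences.

    Overlapping qualifying triples each count as separate sequences.
    ``exclusions`` is a list of (start_beat, end_beat) intervals (inclusive)
    marking arrhythmic sections to skip.
    """
    if beats.sbp_mmhg is None:
        raise SanephysError("beat series has no SBP column")
    sbp = beats.sbp_mmhg
    rr = beats.rr_ms
    n = beats.n_beats
    result = SequenceResult()

    for i in range(n - 2 - delay):
        j = i + 2 + delay
        if _excluded(i, j, exclusions):
            continue
        ds = np.diff(sbp[i:i + 3])
        dr = np.diff(rr[i + delay:i + delay + 3])
        if np.all(ds >= sbp_threshold) and np.all(dr >= rr_threshold):
            kind = "up"
        elif np.all(ds <= -sbp_threshold) and np.all(dr <= -rr_threshold):
            kind = "down"
        else:
            continue
        x = sbp[i:i + 3]
        y = rr[i + delay:i + delay + 3]
        fit = stats.linregress(x, y)
        if abs(fit.rvalue) <= min_r:
            continue
        seq = BaroSequence(
            start_beat=i, kind=kind, sbp=tuple(x), rr=tuple(y),
            slope=float(fit.slope), r=float(fit.rvalue),
        )
        (result.up_sequences if kind == "up" else result.down_sequences).append(seq)
    return result
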
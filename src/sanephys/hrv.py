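"""Heart-rate and heart-rate-variability analysis of murine RR series.

The frequency-domain pipeline mirrors the standard telemetric-ECG workflow
for mice: a 103 s RR tachogram is cubic-spline resampled on a 50 ms grid
(20 Hz), linearly detrended, split into three half-overlapping 1024-sample
stretches, Hamming-windowed, and the averaged one-sided periodogram is
integrated over the murine bands VLF 0-0.4 Hz, LF 0.4-1.5 Hz and
HF 1.5-4.0 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline
from scipy.signal import detrend as _linear_detrend

from .core import BeatSeries, SanephysError

SEGMENT_S = 103.0      # tachogram length entering the spectral pipeline
RESAMPLE_DT = 0.050    # s; 20 Hz spline resampling
NFFT = 1024            # samples per Hamming window
N_WINDOWS = 3          # half-overlapping windows
BANDS = {"vlf": (0.0, 0.4), "lf": (0.4, 1.5), "hf": (1.5, 4.0)}
TP_BAND = (0.0, 4.0)


@dataclass
class TimeDomainResult:
    sdnn: float      # ms
    rmssd: float     # ms
    mean_hr: float   # bpm
    min_hr: float    # bpm
    max_hr: float    # bpm

    def summary(self) -> str:
        return (
            f"SDNN {self.sdnn:.2f} ms | RMSSD {self.rmssd:.2f} ms | "
            f"HR mean {self.mean_hr:.1f} / min {self.min_hr:.1f} / "
            f"max {self.max_hr:.1f} bpm"
        )


@dataclass
class PsdResult:
    freq: np.ndarray    # Hz
    power: np.ndarray   # ms^2/Hz, one-sided
    tp: float           # ms^2, 0-4 Hz
    vlf: float
    lf: float
    hf: float

    def band_peak(self, lo: float, hi: float) -> float:
        """Frequency of the power maximum within [lo, hi]."""
        m = (self.freq >= lo) & (self.freq <= hi)
        return float(self.freq[m][np.argmax(self.power[m])])


def summarize_rate(rr: BeatSeries, histogram: bool = False,
                   window_s: float = 10.0):
    """Mean/min/max heart rate from 10-s mean-HR windows, with an optional
    50-bin histogram of those window means over 150-950 bpm."""
    if rr.n_beats == 0:
        raise SanephysError("empty beat series")
    if rr.duration < 2 * window_s:
        raise SanephysError("need at least 20 s of beats for min/max heart rate")
    hr = 60000.0 / rr.rr_ms
    t = rr.t_s - rr.t_s[0]
    win = np.floor(t / window_s).astype(int)
    means = pd.Series(hr).groupby(win).mean().to_numpy()
    res = TimeDomainResult(
        sdnn=float(np.std(rr.rr_ms, ddof=1)) if rr.n_beats > 1 else 0.0,
        rmssd=_rmssd(rr.rr_ms),
        mean_hr=float(np.mean(means)),
        min_hr=float(np.min(means)),
        max_hr=float(np.max(means)),
    )
    if histogram:
        counts, edges = np.histogram(means, bins=50, range=(150.0, 950.0))
        return res, (counts, edges)
    return res


def _rmssd(rr_ms: np.ndarray) -> float:
    d = np.diff(rr_ms)
    if d.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(d * d)))


def time_domain(rr: BeatSeries, segment_minutes: float = 10.0,
                n_segments: int = 3) -> TimeDomainResult:
    """SDNN and RMSSD computed per segment, then averaged across segments."""
    seg_s = segment_minutes * 60.0
    t = rr.t_s - rr.t_s[0]
    if rr.duration < seg_s * n_segments - 1e-9:
        raise SanephysError(
            f"series too short for {n_segments} x {segment_minutes} min segments"
        )
    sdnns, rmssds = [], []
    for k in range(n_segments):
        m = (t >= k * seg_s) & (t < (k + 1) * seg_s)
        seg = rr.rr_ms[m]
        if seg.size < 2:
            raise SanephysError("segment contains fewer than 2 beats")
        sdnns.append(float(np.std(seg, ddof=1)))
        rmssds.append(_rmssd(seg))
    hr = 60000.0 / rr.rr_ms
    return TimeDomainResult(
        sdnn=float(np.mean(sdnns)),
        rmssd=float(np.mean(rmssds)),
        mean_hr=float(np.mean(hr)),
        min_hr=float(np.min(hr)),
        max_hr=float(np.max(hr)),
    )


def _band_integrator(freq: np.ndarray, power: np.ndarray):
    """Cumulative trapezoidal integral, interpolated at arbitrary edges, so
    that adjacent bands tile exactly (additivity to numerical precision)."""
    cum = cumulative_trapezoid(power, freq, initial=0.0)

    def integral(lo: float, hi: float) -> float:
        return float(np.interp(hi, freq, cum) - np.interp(lo, freq, cum))

    return integral


def spectral(rr: BeatSeries) -> PsdResult:
    """Power spectral density of a 103 s RR tachogram (ms^2/Hz) and murine
    band powers (ms^2)."""
    t = rr.t_s
    if np.any(np.diff(t) <= 0):
        raise SanephysError("beat times must be strictly increasing")
    if rr.duration < SEGMENT_S:
        raise SanephysError(f"need a contiguous segment of {SEGMENT_S:.0f} s")
    t0 = t[0]
    grid = t0 + np.arange(SEGMENT_S / RESAMPLE_DT) * RESAMPLE_DT
    # 103 s at 20 Hz gives 2060 samples; three half-overlapping 1024-sample
    # windows need 2048 of them
    need = NFFT + (N_WINDOWS - 1) * NFFT // 2
    assert grid.size >= need, "resampled segment shorter than the FFT layout"
    m = t <= grid[-1] + RESAMPLE_DT
    spline = CubicSpline(t[m], rr.rr_ms[m])
    x = spline(grid)[:need]
    x = _linear_detrend(x, type="linear")

    fs = 1.0 / RESAMPLE_DT
    w = np.hamming(NFFT)
    scale = 1.0 / (fs * np.sum(w * w))
    psds = []
    for k in range(N_WINDOWS):
        seg = x[k * NFFT // 2:k * NFFT // 2 + NFFT]
        spec = np.fft.rfft(w * seg)
        p = scale * np.abs(spec) ** 2
        p[1:-1] *= 2.0  # one-sided
        psds.append(p)
    power = np.mean(psds, axis=0)
    freq = np.fft.rfftfreq(NFFT, d=RESAMPLE_DT)

    integral = _band_integrator(freq, power)
    vlf = integral(*BANDS["vlf"])
    lf = integral(*BANDS["lf"])
    hf = integral(*BANDS["hf"])
    tp = integral(*TP_BAND)
    return PsdResult(freq=freq, power=power, tp=tp, vlf=vlf, lf=lf, hf=hf)


def poincare(rr: BeatSeries, n_points: int = 20000) -> pd.DataFrame:
    """Lagged RR pairs (RR_n, RR_n+1), first ``n_points`` of them."""
    x = rr.rr_ms[:-1]
    y = rr.rr_ms[1:]
    return pd.DataFrame({"rr_n": x[:n_points], "rr_n1": y[:n_points]})


def detect_pauses(rr: BeatSeries, reference_mean: float) -> pd.DataFrame:
    """Sinus pauses: beats whose RR strictly exceeds twice the reference
    mean RR."""
    if reference_mean <= 0:
        raise ValueError("reference_mean must be positive")
    idx = np.flatnonzero(rr.rr_ms > 2.0 * reference_mean)
    return pd.DataFrame({"beat": idx, "t_s": rr.t_s[idx], "rr_ms": rr.rr_ms[idx]})


def clean_rr(rr: BeatSeries, n_sd: float = 4.0) -> BeatSeries:
    """Optional artifact filter: drop beats with RR outside mean +/- n_sd SD."""
    mu, sd = np.mean(rr.rr_ms), np.std(rr.rr_ms)
    keep = np.abs(rr.rr_ms - mu) <= n_sd * sd
    sbp = rr.sbp_mmhg[keep] if rr.sbp_mmhg is not None else None
    return BeatSeries(rr_ms=rr.rr_ms[keep], t_s=rr.t_s[keep], sbp_mmhg=sbp)
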
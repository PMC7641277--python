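"""Core in-memory containers shared across the analysis modules.

Conventions used throughout the package: time in seconds, RR intervals in
milliseconds, membrane potential in millivolts, current in picoamperes,
pressure in mmHg, distances in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SanephysError(Exception):
    """Base class for domain errors raised by this package."""


class FitError(SanephysError):
    """A curve fit failed or the data lack the assumed structure."""


@dataclass
class UniformTrace:
    """Evenly sampled time series (membrane potential or current).

    Parameters
    ----------
    values : ndarray
        Sample values (mV for voltage, pA for current).
    sampling_rate : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    units : str
        Unit label, e.g. ``"mV"`` or ``"pA"``.
    """

    values: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    units: str = "mV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("UniformTrace values must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n samples at 1/fs spacing)."""
        return self.n / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.sampling_rate

    def slice(self, t_start: float, t_stop: float) -> "UniformTrace":
        """Sub-trace covering [t_start, t_stop) in seconds."""
        i0 = max(0, int(np.ceil((t_start - self.t0) * self.sampling_rate)))
        i1 = min(self.n, int(np.ceil((t_stop - self.t0) * self.sampling_rate)))
        return UniformTrace(
            self.values[i0:i1],
            self.sampling_rate,
            t0=self.t0 + i0 / self.sampling_rate,
            units=self.units,
        )


@dataclass
class BeatSeries:
    """Per-beat table: beat index, beat time (s), RR (ms), optional SBP (mmHg)."""

    rr_ms: np.ndarray
    t_s: np.ndarray
    sbp_mmhg: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.t_s = np.asarray(self.t_s, dtype=float)
        if self.rr_ms.shape != self.t_s.shape:
            raise ValueError("rr_ms and t_s must have equal length")
        if self.sbp_mmhg is not None:
            self.sbp_mmhg = np.asarray(self.sbp_mmhg, dtype=float)
            if self.sbp_mmhg.shape != self.rr_ms.shape:
                raise ValueError("sbp_mmhg must match rr_ms length")

    @property
    def n_beats(self) -> int:
        return self.rr_ms.size

    @property
    def duration(self) -> float:
        """Span of beat times in seconds."""
        if self.n_beats == 0:
            return 0.0
        return float(self.t_s[-1] - self.t_s[0])

    @classmethod
    def from_rr(cls, rr_ms, t_start: float = 0.0, sbp_mmhg=None) -> "BeatSeries":
        """Build from RR intervals alone; beat times are cumulative RR sums."""
        rr_ms = np.asarray(rr_ms, dtype=float)
        t = t_start + np.cumsum(rr_ms) / 1000.0
        return cls(rr_ms=rr_ms, t_s=t, sbp_mmhg=sbp_mmhg)

    def to_frame(self) -> pd.DataFrame:
        d = {"beat": np.arange(self.n_beats), "t_s": self.t_s, "rr_ms": self.rr_ms}
        if self.sbp_mmhg is not None:
            d["sbp_mmhg"] = self.sbp_mmhg
        return pd.DataFrame(d)


@dataclass
class FrameStack:
    """2D + time fluorescence stack.

    ``frames`` has shape (n_frames, n_rows, n_cols); ``pitch_um`` is the pixel
    pitch and ``frame_rate`` the acquisition rate in Hz.
    """

    frames: np.ndarray
    pitch_um: float
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, n_rows, n_cols)")
        if self.pitch_um <= 0 or self.frame_rate <= 0:
            raise ValueError("pitch_um and frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * 1000.0 / self.frame_rate


@dataclass
class Episode:
    """One firing or nonfiring interval of a pacemaker trace."""

    start: float
    end: float
    mode: str  # "firing" | "nonfiring"
    delta_vm: float | None = None  # mV, nonfiring episodes only
    edge_truncated: bool = False

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class EpisodeSegmentation:
    """Firing/nonfiring partition of a trace with per-episode statistics."""

    episodes: list[Episode] = field(default_factory=list)
    pct_nonfiring: float = 0.0
    cell_class: str = "permanent"  # "permanent" | "episodic"
    mean_mdp: float = float("nan")

    @property
    def nonfiring_episodes(self) -> list[Episode]:
        return [e for e in self.episodes if e.mode == "nonfiring"]

    @property
    def delta_vms(self) -> list[float]:
        return [e.delta_vm for e in self.nonfiring_episodes if e.delta_vm is not None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.start, e.end, e.mode) for e in self.episodes],
            columns=["start_s", "end_s", "mode"],
        )
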
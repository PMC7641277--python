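"""Action-potential detection, per-cycle features, and firing/nonfiring
segmentation of pacemaker-cell recordings.

Segmentation follows the episodic-firing rules used for long perforated-patch
recordings: silent stretches of at least 3.5 s whose membrane potential stays
within +/-10 mV of the cell's average MDP count as nonfiring episodes, the
cell is classed "episodic" if any such episode reaches 10 s, and the
depolarization across each episode (delta Vm) is read from the potentials
just after episode onset and just before firing resumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Episode, EpisodeSegmentation, SanephysError, UniformTrace

MIN_EPISODE_S = 3.5     # shortest nonfiring episode admitted to statistics
EPISODIC_CLASS_S = 10.0  # silent duration that classifies a cell as episodic
MDP_GATE_MV = 10.0      # silent potential must stay within +/- this of mean MDP
REFRACTORY_S = 0.030    # AP detection refractory guard
_EDGE_OFFSET_S = 0.10   # offset of the delta-Vm read-out from episode edges
_EDGE_AVG_S = 0.10      # averaging window length for the delta-Vm read-out


class InsufficientAps(SanephysError):
    pass


@dataclass
class ApFeatures:
    """Per-recording action-potential features."""

    ap_times: np.ndarray          # s
    firing_rate_hz: float         # AP/s, firing episodes only
    firing_rate_per_min: float    # AP/min
    mdp_per_cycle: np.ndarray     # mV, minimum between consecutive APs
    sdd_slope: float              # mV/s, linear fit over the diastolic window
    averaged_ap: UniformTrace | None = None


def detect_aps(trace: UniformTrace) -> np.ndarray:
    """Detect action potentials; returns event times (s).

    Events are placed at the sample of maximum upstroke velocity. An
    amplitude gate requires the upstroke to cross the midpoint between the
    diastolic floor and the peak, and a 30 ms refractory guard prevents
    double counting. A flat trace yields an empty array.
    """
    if trace.sampling_rate < 1000.0:
        raise ValueError("sampling rate must be >= 1 kHz")
    v = trace.values
    if v.size < 3:
        return np.empty(0)
    lo = np.percentile(v, 0.5)
    hi = np.percentile(v, 99.9)
    if hi - lo < 15.0:  # mV; no AP-sized excursions
        return np.empty(0)
    mid = 0.5 * (lo + hi)

    above = v >= mid
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        return np.empty(0)
    dv = np.gradient(v)
    fs = trace.sampling_rate
    win = max(1, int(round(0.003 * fs)))
    times = []
    last = -np.inf
    for c in crossings:
        i0, i1 = max(0, c - win), min(v.size, c + win + 1)
        peak_i = i0 + int(np.argmax(dv[i0:i1]))
        t = trace.t0 + peak_i / fs
        if t - last >= REFRACTORY_S:
            times.append(t)
            last = t
    return np.asarray(times)


def _cycle_pairs(ap_times: np.ndarray):
    """Consecutive AP pairs that belong to the same firing episode."""
    for a, b in zip(ap_times[:-1], ap_times[1:]):
        if b - a < MIN_EPISODE_S:
            yield a, b


def ap_features(
    trace: UniformTrace,
    ap_times: np.ndarray,
    avg_window_s: float = 0.05,
) -> ApFeatures:
    """Firing rate, per-cycle MDP, SDD slope, and the averaged AP.

    All quantities are computed from constant-firing stretches only:
    inter-AP intervals of at least 3.5 s are treated as mode transitions and
    excluded.
    """
    ap_times = np.asarray(ap_times, dtype=float)
    if ap_times.size < 3:
        raise InsufficientAps("need at least 3 action potentials")
    fs = trace.sampling_rate
    v = trace.values

    intervals = np.diff(ap_times)
    firing = intervals[intervals < MIN_EPISODE_S]
    if firing.size < 2:
        raise InsufficientAps("fewer than 2 firing-mode intervals")
    rate_hz = 1.0 / float(np.mean(firing))

    def idx(t):
        return int(round((t - trace.t0) * fs))

    mdps = []
    slopes = []
    for a, b in _cycle_pairs(ap_times):
        i0, i1 = idx(a), idx(b)
        if i1 - i0 < 4:
            continue
        seg = v[i0:i1]
        mdp_i = i0 + int(np.argmin(seg))
        mdps.append(v[mdp_i])
        # diastolic window: MDP to takeoff (dV/dt > 3x median diastolic dV/dt)
        dia = v[mdp_i:i1]
        if dia.size >= 4:
            dvdt = np.gradient(dia) * fs
            med = np.median(dvdt)
            if med > 0:
                above = np.flatnonzero(dvdt > 3.0 * med)
                take = above[0] if above.size else dia.size - 1
                if take >= 3:
                    tt = np.arange(take) / fs
                    slopes.append(float(np.polyfit(tt, dia[:take], 1)[0]))

    avg = None
    half = int(round(avg_window_s * fs))
    wins = []
    for t in ap_times:
        i = idx(t)
        if i - half >= 0 and i + half < v.size:
            wins.append(v[i - half:i + half])
    if wins:
        avg = UniformTrace(np.mean(wins, axis=0), fs, t0=-avg_window_s,
                           units=trace.units)

    return ApFeatures(
        ap_times=ap_times,
        firing_rate_hz=rate_hz,
        firing_rate_per_min=60.0 * rate_hz,
        mdp_per_cycle=np.asarray(mdps),
        sdd_slope=float(np.mean(slopes)) if slopes else float("nan"),
        averaged_ap=avg,
    )


def _smooth(v: np.ndarray, fs: float, win_s: float = 0.025) -> np.ndarray:
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(v, max(1, int(round(win_s * fs))))


def _refine_gap(trace: UniformTrace, v_s: np.ndarray,
                t_a: float | None, t_b: float | None):
    """Locate the silent interval inside an inter-AP gap.

    Onset: the first time after the last AP at which the (smoothed) potential
    reaches within 1 mV of the gap minimum — the end of that AP's
    repolarization. Termination: the diastolic takeoff of the first new AP,
    found by scanning backward from it while the local slope exceeds three
    times the median slope of the silent stretch. ``None`` marks a trace
    edge.
    """
    fs = trace.sampling_rate
    t_end = trace.t0 + trace.duration

    def idx(t):
        return int(np.clip(round((t - trace.t0) * fs), 0, v_s.size - 1))

    ia = idx(t_a) if t_a is not None else 0
    ib = idx(t_b) if t_b is not None else v_s.size - 1
    gap = v_s[ia:ib + 1]
    if gap.size < 4:
        return (t_a if t_a is not None else trace.t0,
                t_b if t_b is not None else t_end)

    if t_a is None:
        i_start = ia
    else:
        below = np.flatnonzero(gap <= gap.min() + 1.0)
        i_start = ia + int(below[0])

    if t_b is None:
        i_end = ib
    else:
        # local slope from a 50 ms central difference on the smoothed trace
        k = max(1, int(round(0.025 * fs)))
        lo, hi = max(ia, i_start), ib
        seg = v_s[lo:hi + 1]
        if seg.size > 2 * k + 2:
            slope = (seg[2 * k:] - seg[:-2 * k]) * fs / (2.0 * k)
            mid = slope[len(slope) // 4: max(len(slope) // 4 + 1,
                                             3 * len(slope) // 4)]
            gate = max(3.0 * abs(float(np.median(mid))), 5.0)  # mV/s
            j = len(slope) - 1
            while j > 0 and slope[j] > gate:
                j -= 1
            i_end = lo + k + j
        else:
            i_end = ib

    return trace.t0 + i_start / fs, trace.t0 + i_end / fs


def _edge_potential(trace: UniformTrace, t_center: float) -> float:
    """Mean potential over a 100 ms window centred at ``t_center``."""
    sub = trace.slice(t_center - _EDGE_AVG_S / 2.0, t_center + _EDGE_AVG_S / 2.0)
    return float(np.mean(sub.values))


def segment_modes(trace: UniformTrace, ap_times: np.ndarray) -> EpisodeSegmentation:
    """Partition a trace into firing and nonfiring episodes.

    Silent inter-AP gaps of >= 3.5 s whose mean potential lies within
    +/-10 mV of the trace's average firing MDP become nonfiring episodes;
    each episode's delta Vm is the magnitude of the depolarization between
    its onset and termination. Episodes truncated by the recording edges are
    counted in the nonfiring-time percentage but excluded from duration and
    delta-Vm statistics. The cell is "episodic" iff any episode reaches 10 s.
    """
    ap_times = np.asarray(ap_times, dtype=float)
    if ap_times.size == 0:
        raise SanephysError("no firing detected: cell class undefined")
    total = trace.duration
    if total < 30.0:
        raise SanephysError("trace must be >= 30 s for mode classification")
    fs = trace.sampling_rate
    v = trace.values

    mdps = []
    for a, b in _cycle_pairs(ap_times):
        i0 = int(round((a - trace.t0) * fs))
        i1 = int(round((b - trace.t0) * fs))
        if i1 > i0:
            mdps.append(float(np.min(v[i0:i1])))
    if not mdps:
        raise SanephysError("no firing-mode cycles to estimate the mean MDP")
    mean_mdp = float(np.mean(mdps))

    # candidate silent gaps: between APs, plus the trace edges
    t_end = trace.t0 + trace.duration
    candidates = []
    if ap_times[0] - trace.t0 >= MIN_EPISODE_S:
        candidates.append((None, ap_times[0]))
    for a, b in zip(ap_times[:-1], ap_times[1:]):
        if b - a >= MIN_EPISODE_S:
            candidates.append((a, b))
    if t_end - ap_times[-1] >= MIN_EPISODE_S:
        candidates.append((ap_times[-1], None))

    v_s = _smooth(v, fs)
    nonfiring: list[Episode] = []
    for t_a, t_b in candidates:
        start, end = _refine_gap(trace, v_s, t_a, t_b)
        if end - start < MIN_EPISODE_S:
            continue
        i0 = int(round((start - trace.t0) * fs))
        i1 = int(round((end - trace.t0) * fs))
        seg_mean = float(np.mean(v[i0:i1]))
        if abs(seg_mean - mean_mdp) > MDP_GATE_MV:
            continue
        truncated = t_a is None or t_b is None
        dvm = None
        if not truncated:
            v_on = _edge_potential(trace, start + _EDGE_OFFSET_S)
            v_off = _edge_potential(trace, end - _EDGE_OFFSET_S)
            dvm = abs(v_off - v_on)
        nonfiring.append(Episode(start=start, end=end, mode="nonfiring",
                                 delta_vm=dvm, edge_truncated=truncated))

    # firing episodes tile the remainder
    episodes: list[Episode] = []
    cursor = trace.t0
    for ep in nonfiring:
        if ep.start > cursor:
            episodes.append(Episode(start=cursor, end=ep.start, mode="firing"))
        episodes.append(ep)
        cursor = ep.end
    if cursor < t_end:
        episodes.append(Episode(start=cursor, end=t_end, mode="firing"))

    t_nonfiring = sum(e.duration for e in nonfiring)
    pct = 100.0 * t_nonfiring / total
    episodic = any(e.duration >= EPISODIC_CLASS_S for e in nonfiring)
    return EpisodeSegmentation(
        episodes=episodes,
        pct_nonfiring=pct,
        cell_class="episodic" if episodic else "permanent",
        mean_mdp=mean_mdp,
    )


def episode_duration_stats(seg: EpisodeSegmentation) -> np.ndarray:
    """Durations (s) of nonfiring episodes admitted to statistics."""
    return np.array([
        e.duration for e in seg.nonfiring_episodes if not e.edge_truncated
    ])


def dose_response(rates: pd.DataFrame, basal: float) -> pd.DataFrame:
    """Percentage reduction of firing rate vs drug concentration.

    ``rates`` has columns (concentration, firing_rate); reduction is
    100*(1 - rate/basal), ordered by concentration.
    """
    if basal <= 0:
        raise ValueError("basal firing rate must be positive")
    conc = rates.iloc[:, 0].to_numpy(dtype=float)
    rate = rates.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(conc)
    return pd.DataFrame({
        "concentration": conc[order],
        "pct_reduction": 100.0 * (1.0 - rate[order] / basal),
    })
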
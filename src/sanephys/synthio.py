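"""Synthetic-data generators for sinoatrial electrophysiology analyses.

Every generator is deterministic given its spec and an integer seed, and each
one is paired with an analysis operation elsewhere in the package that can
recover the programmed parameters (round-trip property). The pacemaker
generator emulates the episodic firing/nonfiring cycle of single SAN cells:
firing bouts of stylized action potentials whose maximum diastolic potential
(MDP) drifts from a bout-onset to a bout-end value, separated by silent
episodes during which the membrane slowly depolarizes back toward the firing
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import BeatSeries, FrameStack, UniformTrace

# Bout-average calibration: during a firing bout the cycle-averaged membrane
# potential sits a fixed offset above the cycle MDP (an MDP of -67 mV yields a
# -51 mV cycle average; an MDP of -75 mV yields -59 mV). The AP duty cycle is
# solved per cycle so the waveform meets this constraint exactly.
BOUT_AVG_OFFSET_MV = 16.0

# Shortest nonfiring episode admitted to episode statistics (s); episode
# durations are drawn from a normal distribution truncated at this floor.
MIN_EPISODE_S = 3.5

_UPSTROKE_S = 0.002  # AP upstroke duration (s), half-cosine rise


# ---------------------------------------------------------------------------
# Preset / spec types
# ---------------------------------------------------------------------------

@dataclass
class PacemakerPreset:
    """Statistical description of one pacemaker-cell phenotype.

    ``frac_nonfiring`` is the long-run silent-time fraction of an *episodic*
    cell; ``episodic_cell_prob`` is the probability that a cell (one generated
    trace) adopts the episodic pattern at all, so the population-mean silent
    fraction is the product of the two.
    """

    name: str = "wt"
    firing_rate: float = 5.0          # AP/s during firing bouts
    mdp_onset: float = -67.0          # mV, MDP at bout onset
    mdp_end: float = -75.0            # mV, MDP at bout end
    ap_peak: float = 25.0             # mV
    sdd_slope: float = 100.0          # mV/s, slow diastolic depolarization
    delta_vm: float = 8.0             # mV, depolarization across a silent episode
    delta_vm_cell_sd: float = 1.0     # mV, between-cell SD of delta_vm
    mean_episode_s: float = 16.0      # s
    episode_sd_s: float = 6.0         # s
    frac_nonfiring: float = 0.0       # silent fraction of an episodic cell
    episodic_cell_prob: float = 0.0   # probability a cell is episodic
    noise_sd: float = 0.0             # mV
    ljp_offset: float = 0.0           # mV, liquid-junction-potential shift

    def __post_init__(self) -> None:
        if not (self.mdp_end < self.mdp_onset < self.ap_peak):
            raise ValueError("require mdp_end < mdp_onset < ap_peak")
        if not (0.0 <= self.frac_nonfiring < 1.0):
            raise ValueError("frac_nonfiring must lie in [0, 1)")
        if self.frac_nonfiring > 0 and self.mean_episode_s < MIN_EPISODE_S:
            raise ValueError(f"mean_episode_s must be >= {MIN_EPISODE_S} s")
        if not (0.0 <= self.episodic_cell_prob <= 1.0):
            raise ValueError("episodic_cell_prob must lie in [0, 1]")
        if self.firing_rate <= 0 or self.sdd_slope <= 0:
            raise ValueError("firing_rate and sdd_slope must be positive")


@dataclass
class ChannelPreset:
    """Boltzmann activation and exponential-kinetics parameters of an HCN
    channel condition (genotype x cAMP x holding potential)."""

    name: str = "wt_nocamp_hp55"
    v05: float = -100.1      # mV, half-maximal activation voltage
    k: float = 10.0          # mV, slope factor
    imax: float = 1.0        # normalized (or pA for raw traces)
    imin: float = 0.0
    tau1: float = 1.0        # s, slow activation time constant
    tau2: float = 0.1        # s, fast activation time constant
    a1_frac: float = 0.7     # fraction of amplitude carried by tau1
    delay: float = 0.0       # s, initial delay before exponential onset
    holding_potential: float = -55.0  # mV

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("slope factor k must be positive")
        if not (0.0 <= self.a1_frac <= 1.0):
            raise ValueError("a1_frac must lie in [0, 1]")
        if not (self.tau1 > self.tau2 > 0):
            raise ValueError("require tau1 > tau2 > 0")

    def activation(self, vm) -> np.ndarray:
        """Steady-state activation current at test potential(s) ``vm``.

        Hyperpolarization-activated sigmoid: value is ``imax`` at very
        negative potentials, ``imin`` at depolarized ones, and halfway at
        ``v05``.
        """
        vm = np.asarray(vm, dtype=float)
        return self.imin + (self.imax - self.imin) / (
            1.0 + np.exp((vm - self.v05) / self.k)
        )


@dataclass
class RrGenSpec:
    """RR-tachogram generator: mean level plus LF and HF sinusoidal
    modulation, white noise, and optional injected sinus pauses."""

    mean_rr: float = 100.0   # ms
    lf_amp: float = 0.0      # ms
    lf_freq: float = 1.0     # Hz
    hf_amp: float = 0.0      # ms
    hf_freq: float = 2.5     # Hz
    white_sd: float = 0.0    # ms
    n_beats: int = 1200
    pause_times: tuple = ()  # beat indices receiving a pause
    pause_factor: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        for f in (self.lf_freq, self.hf_freq):
            if not (0.0 <= f <= 4.0):
                raise ValueError("modulation frequencies must lie in [0, 4] Hz")
        if self.n_beats < 10:
            raise ValueError("n_beats must be >= 10")


@dataclass
class BaroGenSpec:
    """Beat-aligned SBP/RR generator with programmed 3-beat baroreflex
    sequences (RR responding at a fixed 1-beat delay)."""

    n_beats: int = 600
    n_up: int = 5
    n_down: int = 5
    slope_up: float = 4.0     # ms/mmHg
    slope_down: float = 4.0   # ms/mmHg
    step_mmHg: float = 2.0    # SBP increment per beat inside a sequence
    delay_beats: int = 1
    sbp_noise: float = 0.0    # mmHg
    rr_noise: float = 0.0     # ms
    base_sbp: float = 120.0   # mmHg
    base_rr: float = 100.0    # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_mmHg < 0.5:
            raise ValueError("step_mmHg must be >= 0.5 for detectable sequences")
        if self.slope_up < 0 or self.slope_down < 0:
            raise ValueError("slopes must be non-negative")


@dataclass
class SactGenSpec:
    """Premature-atrial-stimulation table generator.

    For coupling intervals A1A2 >= ``reset_onset`` the return cycle is fully
    compensatory (A2A3 = 2*SCL - A1A2); below it the premature beat resets the
    node and the return cycle plateaus at SCL + 2*SACT; couplings at or below
    ``snerp`` fail to capture the atrium.
    """

    scl: float = 200.0         # ms, spontaneous sinus cycle length (A1A1)
    sact: float = 25.0         # ms, sinoatrial conduction time
    reset_onset: float = 180.0  # ms, longest A1A2 that resets the node
    snerp: float = 80.0        # ms, no atrial capture at or below this A1A2
    jitter_sd: float = 0.0     # ms
    couplings: tuple = ()      # A1A2 values; default: scan (snerp, scl)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.snerp < self.reset_onset < self.scl):
            raise ValueError("require snerp < reset_onset < scl")
        if self.sact <= 0:
            raise ValueError("sact must be positive")


# ---------------------------------------------------------------------------
# Pacemaker trace generator
# ---------------------------------------------------------------------------

@dataclass
class PacemakerEvents:
    """Ground-truth event log emitted alongside a generated trace."""

    ap_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    cycle_mdps: np.ndarray = field(default_factory=lambda: np.empty(0))
    silent_episodes: list = field(default_factory=list)  # (start, end, v0, v1)
    is_episodic: bool = False

    @property
    def episode_durations(self) -> np.ndarray:
        return np.array([e[1] - e[0] for e in self.silent_episodes])


def _sdd_duration(p_height: float, slope: float, cycle_s: float) -> float:
    """Solve for the SDD duration that makes the cycle-average potential sit
    BOUT_AVG_OFFSET_MV above the cycle MDP.

    The per-cycle waveform is: linear SDD (slope mV/s) from the MDP, a
    half-cosine upstroke of fixed duration to the AP peak, and a linear
    repolarization back to the MDP. Averaging that shape over the cycle gives
    a quadratic in the SDD duration t:

        s*t**2 + (s*t_up - P)*t + T*(P - 2*u) = 0

    with s the SDD slope, P the peak-to-MDP height, T the cycle length, u the
    target offset.
    """
    s, P, T, u = slope, p_height, cycle_s, BOUT_AVG_OFFSET_MV
    t_up = _UPSTROKE_S
    a, b, c = s, s * t_up - P, T * (P - 2.0 * u)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ValueError(
            "cannot calibrate waveform: cycle too short or peak too low for "
            f"the {u} mV bout-average offset"
        )
    t = (-b - math.sqrt(disc)) / (2.0 * a)
    if not (0.0 < t < T - t_up):
        t = (-b + math.sqrt(disc)) / (2.0 * a)
    if not (0.0 < t < T - t_up):
        raise ValueError("waveform calibration produced no admissible SDD duration")
    return t


def _fill_cycle(values, fs, t_start, mdp, mdp_next, peak, slope, cycle_s):
    """Write one AP cycle starting at ``t_start`` into ``values`` (in place).

    Returns the programmed AP time (moment of maximal upstroke velocity).
    """
    t_sdd = _sdd_duration(peak - mdp, slope, cycle_s)
    t_up = _UPSTROKE_S
    t_rep = cycle_s - t_sdd - t_up
    v_take = mdp + slope * t_sdd
    n_total = values.size

    def seg_idx(a, b):
        i0 = max(0, int(math.ceil(a * fs - 1e-9)))
        i1 = min(n_total, int(math.ceil(b * fs - 1e-9)))
        return i0, i1

    # SDD: linear rise from the MDP
    i0, i1 = seg_idx(t_start, t_start + t_sdd)
    if i1 > i0:
        tt = np.arange(i0, i1) / fs - t_start
        values[i0:i1] = mdp + slope * tt
    # upstroke: half-cosine from takeoff to peak
    u_start = t_start + t_sdd
    i0, i1 = seg_idx(u_start, u_start + t_up)
    if i1 > i0:
        u = (np.arange(i0, i1) / fs - u_start) / t_up
        values[i0:i1] = v_take + (peak - v_take) * 0.5 * (1.0 - np.cos(np.pi * u))
    # repolarization: linear descent to the next cycle's MDP
    r_start = u_start + t_up
    i0, i1 = seg_idx(r_start, t_start + cycle_s)
    if i1 > i0:
        tt = np.arange(i0, i1) / fs - r_start
        values[i0:i1] = peak + (mdp_next - peak) * tt / t_rep
    return u_start + t_up / 2.0


def _fill_silence(values, fs, t_start, t_end, v0, v1):
    """Smoothstep depolarization from v0 to v1 over the silent episode."""
    n_total = values.size
    i0 = max(0, int(math.ceil(t_start * fs - 1e-9)))
    i1 = min(n_total, int(math.ceil(t_end * fs - 1e-9)))
    if i1 <= i0:
        return
    u = np.clip((np.arange(i0, i1) / fs - t_start) / (t_end - t_start), 0.0, 1.0)
    values[i0:i1] = v0 + (v1 - v0) * (3.0 * u * u - 2.0 * u ** 3)


def gen_pacemaker_trace(
    preset: PacemakerPreset,
    duration: float,
    sampling_rate: float = 1000.0,
    seed: int = 0,
    return_events: bool = False,
):
    """Generate a synthetic pacemaker-cell membrane-potential trace.

    The trace alternates firing bouts (whole AP cycles whose MDP drifts
    linearly from ``mdp_onset`` to ``mdp_end``) with silent episodes (smooth
    depolarization by the cell's delta_vm starting from ``mdp_end``). Episode
    durations are drawn from a normal distribution truncated below at 3.5 s;
    the firing-bout duration paired with each episode is chosen so the
    long-run silent fraction equals ``frac_nonfiring``. Whether the cell is
    episodic at all is a Bernoulli draw with ``episodic_cell_prob``.
    """
    if sampling_rate < 1000.0:
        raise ValueError("sampling_rate must be >= 1 kHz")
    cycle_s = 1.0 / preset.firing_rate
    if duration < cycle_s:
        raise ValueError("duration must contain at least one firing cycle")

    rng = np.random.default_rng(seed)
    fs = float(sampling_rate)
    n = int(round(duration * fs))
    values = np.empty(n, dtype=float)

    episodic = (
        preset.frac_nonfiring > 0.0 and rng.random() < preset.episodic_cell_prob
    )
    cell_delta = preset.delta_vm
    if episodic and preset.delta_vm_cell_sd > 0:
        cell_delta = max(0.5, preset.delta_vm + preset.delta_vm_cell_sd * rng.standard_normal())

    ap_times: list[float] = []
    cycle_mdps: list[float] = []
    silent: list[tuple] = []

    def run_bout(t0: float, n_cycles: int, drift: bool) -> float:
        t = t0
        for c in range(n_cycles):
            frac = c / max(1, n_cycles - 1) if drift else 0.0
            mdp = preset.mdp_onset + (preset.mdp_end - preset.mdp_onset) * frac
            frac_next = min(1.0, (c + 1) / max(1, n_cycles - 1)) if drift else 0.0
            mdp_next = preset.mdp_onset + (preset.mdp_end - preset.mdp_onset) * frac_next
            if t >= duration:
                break
            ap_t = _fill_cycle(
                values, fs, t, mdp, mdp_next, preset.ap_peak,
                preset.sdd_slope, cycle_s,
            )
            if ap_t < duration:
                ap_times.append(ap_t)
                cycle_mdps.append(mdp)
            t += cycle_s
        return t

    if not episodic:
        n_cycles = int(math.ceil(duration / cycle_s))
        run_bout(0.0, n_cycles, drift=False)
    else:
        f = preset.frac_nonfiring
        lo = (MIN_EPISODE_S - preset.mean_episode_s) / preset.episode_sd_s
        t = 0.0
        while t < duration:
            d_sil = float(stats.truncnorm.rvs(
                lo, np.inf, loc=preset.mean_episode_s,
                scale=preset.episode_sd_s, random_state=rng,
            ))
            bout_s = d_sil * (1.0 - f) / f
            n_cycles = max(1, int(round(bout_s / cycle_s)))
            t = run_bout(t, n_cycles, drift=True)
            if t >= duration:
                break
            s_end = t + d_sil
            v0 = preset.mdp_end
            v1 = v0 + cell_delta
            _fill_silence(values, fs, t, min(s_end, duration), v0, v1)
            silent.append((t, min(s_end, duration), v0, v1))
            t = s_end

    if preset.noise_sd > 0:
        values += preset.noise_sd * rng.standard_normal(n)
    values += preset.ljp_offset

    trace = UniformTrace(values, fs, units="mV")
    if return_events:
        ev = PacemakerEvents(
            ap_times=np.asarray(ap_times),
            cycle_mdps=np.asarray(cycle_mdps),
            silent_episodes=silent,
            is_episodic=episodic,
        )
        return trace, ev
    return trace


# ---------------------------------------------------------------------------
# Voltage-clamp generators
# ---------------------------------------------------------------------------

def gen_activation_dataset(
    preset: ChannelPreset,
    test_potentials,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Steady-state activation dataset: tail current vs test potential.

    Noiseless output lies exactly on the sigmoid defined by (v05, k, imin,
    imax); Gaussian noise of SD ``noise_sd`` (normalized units) is added per
    point when requested.
    """
    vm = np.asarray(test_potentials, dtype=float)
    if vm.size < 6:
        raise ValueError("need at least 6 test potentials spanning the curve")
    i = preset.activation(vm)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i = i + noise_sd * rng.standard_normal(vm.size)
    return pd.DataFrame({"vm_mv": vm, "current": i})


def gen_current_trace(
    preset: ChannelPreset,
    duration: float,
    sampling_rate: float = 10000.0,
    order: int = 2,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> UniformTrace:
    """Exponential current time-course I(t) = Iss + sum_j A_j exp(-t'/tau_j).

    ``t'`` is time after the preset's initial delay; samples before the delay
    hold the onset value. Amplitudes derive from the preset: the total
    relaxing amplitude is ``imax - imin`` with steady state ``imin``; for
    order 2 the split is ``a1_frac`` on tau1.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if duration <= 5.0 * preset.tau1:
        raise ValueError("duration must exceed 5*tau1")
    fs = float(sampling_rate)
    t = np.arange(int(round(duration * fs))) / fs
    amp = preset.imax - preset.imin
    iss = preset.imin
    tp = np.maximum(t - preset.delay, 0.0)
    if order == 1:
        ideal = iss + amp * np.exp(-tp / preset.tau1)
    else:
        a1 = preset.a1_frac * amp
        a2 = (1.0 - preset.a1_frac) * amp
        ideal = iss + a1 * np.exp(-tp / preset.tau1) + a2 * np.exp(-tp / preset.tau2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ideal = ideal + noise_sd * rng.standard_normal(t.size)
    return UniformTrace(ideal, fs, units="pA")


# ---------------------------------------------------------------------------
# RR tachogram generator
# ---------------------------------------------------------------------------

def gen_rr_series(spec: RrGenSpec) -> BeatSeries:
    """Generate an RR tachogram with sinusoidal LF/HF modulation.

    RR_i = mean + lf_amp*sin(2*pi*lf*t_i) + hf_amp*sin(2*pi*hf*t_i) + noise,
    evaluated at the time of the preceding beat; beat times are cumulative RR
    sums. Listed pause beats are multiplied by ``pause_factor`` afterwards.
    """
    rng = np.random.default_rng(spec.seed)
    rr = np.empty(spec.n_beats)
    t = 0.0
    for i in range(spec.n_beats):
        val = (
            spec.mean_rr
            + spec.lf_amp * math.sin(2.0 * math.pi * spec.lf_freq * t)
            + spec.hf_amp * math.sin(2.0 * math.pi * spec.hf_freq * t)
        )
        if spec.white_sd > 0:
            val += spec.white_sd * rng.standard_normal()
        rr[i] = val
        t += val / 1000.0
    for idx in spec.pause_times:
        rr[idx] *= spec.pause_factor
    if np.any(rr <= 0):
        raise ValueError("generated RR intervals must be positive")
    return BeatSeries.from_rr(rr)


# ---------------------------------------------------------------------------
# SBP/RR baroreflex sequence generator
# ---------------------------------------------------------------------------

def gen_bp_rr(spec: BaroGenSpec) -> BeatSeries:
    """Generate a beat-aligned SBP + RR series with programmed sequences.

    Each programmed sequence is three consecutive beats of monotone SBP change
    of ``step_mmHg`` per beat, with the RR interval responding one beat later
    at the programmed slope. A lead-in beat held at the first sequence level
    guarantees that exactly one 3-beat triple qualifies per programmed
    sequence; intervening beats are flat baseline.
    """
    n_seq = spec.n_up + spec.n_down
    block = 6 + 3  # lead-in + 3 SBP beats (+ lagged RR tail) + buffer
    if n_seq * block + 4 > spec.n_beats:
        raise ValueError("programmed sequences do not fit into n_beats")
    rng = np.random.default_rng(spec.seed)

    sbp = np.full(spec.n_beats, spec.base_sbp)
    rr = np.full(spec.n_beats, spec.base_rr)

    kinds = ["up"] * spec.n_up + ["down"] * spec.n_down
    rng.shuffle(kinds)
    if n_seq:
        starts = np.linspace(2, spec.n_beats - block, n_seq).astype(int)
    else:
        starts = np.array([], dtype=int)

    d = spec.delay_beats
    for j, kind in zip(starts, kinds):
        sign = 1.0 if kind == "up" else -1.0
        slope = spec.slope_up if kind == "up" else spec.slope_down
        levels = sign * spec.step_mmHg * np.arange(1, 4)
        sbp[j - 1] = spec.base_sbp + levels[0]      # lead-in at first level
        sbp[j:j + 3] = spec.base_sbp + levels
        rr_levels = slope * levels                  # same sign as SBP change
        rr[j + d - 1] = spec.base_rr + rr_levels[0]
        rr[j + d:j + d + 3] = spec.base_rr + rr_levels

    if spec.sbp_noise > 0:
        sbp = sbp + spec.sbp_noise * rng.standard_normal(spec.n_beats)
    if spec.rr_noise > 0:
        rr = rr + spec.rr_noise * rng.standard_normal(spec.n_beats)
    return BeatSeries.from_rr(rr, sbp_mmhg=sbp)


# ---------------------------------------------------------------------------
# Premature-stimulation table generator
# ---------------------------------------------------------------------------

def gen_premature_stim(spec: SactGenSpec, allow_no_capture: bool = False) -> pd.DataFrame:
    """Premature-atrial-stimulation table (A1A1, A1A2, A2A3, A3A4 in ms).

    Return cycles follow the two-zone model: fully compensatory
    (A2A3 = 2*SCL - A1A2) for late couplings, reset plateau
    (A2A3 = SCL + 2*SACT) for early ones. Couplings at or below the
    sinoatrial-node entrance refractory point (``snerp``) do not capture the
    atrium and are rejected unless ``allow_no_capture`` drops them silently.
    """
    couplings = np.asarray(
        spec.couplings if len(spec.couplings) else
        np.arange(spec.scl - 10.0, spec.snerp + 5.0, -10.0),
        dtype=float,
    )
    bad = couplings <= spec.snerp
    if bad.any():
        if not allow_no_capture:
            raise ValueError("couplings at or below snerp do not capture the atrium")
        couplings = couplings[~bad]
    if np.any(couplings >= spec.scl):
        raise ValueError("premature couplings must be shorter than the SCL")
    rng = np.random.default_rng(spec.seed)

    a2a3 = np.where(
        couplings >= spec.reset_onset,
        2.0 * spec.scl - couplings,           # compensatory zone
        spec.scl + 2.0 * spec.sact,           # reset plateau
    )
    n = couplings.size
    a1a1 = np.full(n, spec.scl)
    a3a4 = np.full(n, spec.scl)
    if spec.jitter_sd > 0:
        a1a1 = a1a1 + spec.jitter_sd * rng.standard_normal(n)
        a2a3 = a2a3 + spec.jitter_sd * rng.standard_normal(n)
        a3a4 = a3a4 + spec.jitter_sd * rng.standard_normal(n)
    return pd.DataFrame(
        {"a1a1_ms": a1a1, "a1a2_ms": couplings, "a2a3_ms": a2a3, "a3a4_ms": a3a4}
    )


# ---------------------------------------------------------------------------
# Optical wave-stack generator
# ---------------------------------------------------------------------------

def gen_wave_stack(
    grid: tuple[int, int] = (20, 20),
    pitch_um: float = 100.0,
    origin: tuple[int, int] = (0, 0),
    velocity_um_ms: float = 100.0,
    frame_rate: float = 2000.0,
    upstroke_ms: float = 4.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FrameStack:
    """Planar/radial wave of fluorescence upstrokes across a pixel grid.

    Each pixel's (raw, voltage-dye style, downward) upstroke is a sigmoid
    centred at distance(origin)/velocity after a fixed 10 ms pre-pad; the
    mapping module inverts and normalizes before timing upstrokes.
    """
    if velocity_um_ms <= 0:
        raise ValueError("velocity must be positive")
    nr, nc = grid
    r0, c0 = origin
    if not (0 <= r0 < nr and 0 <= c0 < nc):
        raise ValueError("origin lies outside the pixel grid")
    rows, cols = np.mgrid[0:nr, 0:nc]
    dist = np.hypot(rows - r0, cols - c0) * pitch_um
    t_act = dist / velocity_um_ms + 10.0  # ms, 10 ms pre-pad

    t_max = float(t_act.max()) + 6.0 * upstroke_ms + 10.0
    n_frames = int(math.ceil(t_max * frame_rate / 1000.0))
    t = np.arange(n_frames) * 1000.0 / frame_rate  # ms
    # logistic upstroke; width parameter makes 10-90% rise ~= upstroke_ms
    w = upstroke_ms / 4.394
    sig = 1.0 / (1.0 + np.exp(-(t[:, None, None] - t_act[None, :, :]) / w))
    frames = 1.0 - sig  # raw dye signal deflects downward on depolarization
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + noise_sd * rng.standard_normal(frames.shape)
    stack = FrameStack(frames, pitch_um=pitch_um, frame_rate=frame_rate)
    stack.true_activation_ms = t_act - t_act.min()  # ground truth for tests
    return stack
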
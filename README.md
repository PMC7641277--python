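# sanephys

Analysis toolkit for sinoatrial-node (SAN) electrophysiology and cardiac
biosignals, built around the episodic firing/nonfiring behaviour of murine
pacemaker cells. It is aimed at cellular electrophysiologists and
cardiovascular physiologists who need a scripted, testable version of the
measurements usually done interactively in acquisition software:

* **`clampfit`** — voltage-clamp curve fitting: steady-state activation
  curves with the Boltzmann sigmoid
  `I(V) = I_min + (I_max − I_min) / (1 + exp((V − V₀.₅)/k))`
  (hyperpolarization-activated orientation, so activation grows with
  hyperpolarization), single/double-exponential kinetics
  `I(t) = I_ss + A₁ e^(−t/τ₁) + A₂ e^(−t/τ₂)` after an initial delay,
  current densities (pA/pF) and T-/L-type calcium-current decomposition.
* **`apseg`** — action-potential detection (maximum upstroke velocity with
  an amplitude gate and 30 ms refractory guard), per-cycle features (firing
  rate, maximum diastolic potential MDP, slow-diastolic-depolarization
  slope, averaged AP), and firing/nonfiring segmentation: silent stretches
  ≥ 3.5 s within ±10 mV of the cell's mean MDP are nonfiring episodes, a
  cell with any episode ≥ 10 s is *episodic*, and ΔVm is the depolarization
  between episode onset and termination.
* **`hrv`** — murine heart-rate variability: SDNN/RMSSD, 10-s heart-rate
  summaries and 50-bin histograms (150–950 bpm), Poincaré pairs, sinus-pause
  detection (RR > 2× reference mean), and the spectral pipeline: 103 s RR
  tachogram → cubic-spline resampling at 50 ms → linear detrend → three
  half-overlapping Hamming-windowed 1024-point FFTs → band powers for
  VLF 0–0.4, LF 0.4–1.5, HF 1.5–4.0 Hz.
* **`baro`** — baroreflex sequence method: 3-beat runs of monotone systolic
  blood pressure change (≥ 0.5 mmHg/beat) with same-direction RR changes
  (≥ 2 ms) at a 1-beat delay; slope of RR on SBP (kept if |r| > 0.85)
  estimates baroreflex gain.
* **`eps`** — programmed stimulation: SNRT/cSNRT, sinoatrial conduction
  time from premature atrial stimulation (compensatory zone
  A1A2 + A2A3 = 2·A1A1 vs reset zone, SACT = (A2A3 − A1A1)/2 at the first
  deviating coupling), AV conduction and latency curves with the functional
  refractory period (min V1V2), and effective refractory periods from S1S2
  tables.
* **`mapping`** — optical activation maps (per-pixel time of maximal dF/dt
  of the inverted, normalized fluorescence), leading-pacemaker localization,
  optical SACT between ROIs, normalized pacemaker shift, ΔF/F₀ and
  subthreshold-cell density.
* **`synthio` + `presets`** — synthetic-data generators for every analysis
  above, with a shipped preset library (`wt`, `hcn4fea`, ±isoproterenol
  pacemaker phenotypes; per-holding-potential channel presets). Every
  generator is seed-reproducible and each programmed parameter is
  recoverable by the matching analysis, which is how the package tests
  itself in the absence of animal recordings.

## Worked example

```python
import numpy as np
from sanephys import synthio, presets, apseg
from sanephys.clampfit import fit_boltzmann

# 1) fit a steady-state activation curve
chan = presets.channel_preset("wt_camp_hp55")
data = synthio.gen_activation_dataset(chan, np.arange(-140, -39, 10.0))
fit = fit_boltzmann(data)
print(fit.summary())

# 2) segment an episodic pacemaker recording
cell = presets.pacemaker_preset("hcn4fea")
trace = synthio.gen_pacemaker_trace(cell, duration=600.0, seed=2)
seg = apseg.segment_modes(trace, apseg.detect_aps(trace))
print(f"{seg.cell_class}: {seg.pct_nonfiring:.1f}% nonfiring, "
      f"mean dVm {np.mean(seg.delta_vms):.2f} mV")
```

Output:

```
Boltzmann activation fit
  V0.5 :     -82.10 mV
  k    :      10.00 mV
  Imin :    -0.0000
  Imax :     1.0000
  RSS  :  4.234e-18  (n = 11)
episodic: 40.0% nonfiring, mean dVm 6.62 mV
```

The first block recovers the preset's half-activation voltage (−82.1 mV)
and slope factor exactly, because the noiseless dataset lies on the fitted
sigmoid. The second block classifies the synthetic mutant cell as episodic,
spending 40% of the recording in the nonfiring mode with a mean
depolarization of ~6.6 mV across episodes (this cell's ΔVm draw; the
population mean is 7.17 mV).

A command-line interface mirrors the library:

```bash
sanephys gen pacemaker --preset hcn4fea --duration 600 --seed 2 --out cell.h5
sanephys ap segment --in cell.h5
```

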
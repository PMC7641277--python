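# Methods

This note documents the models, numerical choices and limitations behind
`sanephys`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic pacemaker-cell model

Single SAN pacemaker cells can alternate between a *firing* mode (rhythmic
action potentials) and a *nonfiring* mode: the membrane slowly
hyperpolarizes during firing, firing stops, the cell sits at a
hyperpolarized potential for seconds to a minute while slowly depolarizing,
and firing then resumes. `synthio.gen_pacemaker_trace` emulates exactly
this phenomenology — it is a descriptive waveform model, **not** a
conductance-based (Hodgkin–Huxley-type) simulation.

**Firing bouts.** Each cycle of length `1/firing_rate` is a stylized AP:
a linear slow-diastolic-depolarization (SDD) ramp from the cycle MDP, a
2 ms half-cosine upstroke to `ap_peak`, and a linear repolarization to the
next cycle's MDP. Across a bout the MDP drifts linearly from `mdp_onset`
(−67 mV by default) to `mdp_end` (−75 mV). The cycle-averaged membrane
potential is constrained to sit 16 mV above the cycle MDP (so −51 mV at
bout onset, −59 mV at bout end); because the waveform's cycle average is a
quadratic function of the SDD duration, that duration is solved in closed
form per cycle, making the calibration exact rather than tuned. The AP
peak (+25 mV) is a calibration artifact of the stylized shape, not a
measured value.

**Nonfiring episodes.** Episode durations are drawn from a normal
distribution truncated below at 3.5 s (the shortest episode admitted to
statistics). During an episode the membrane depolarizes from `mdp_end` by
the cell's ΔVm along a smoothstep (zero slope at both ends, so the
onset/termination potentials are well defined against noise). The firing
bout paired with each episode lasts `D·(1−f)/f` for silent fraction `f`
(`frac_nonfiring`), so the long-run silent fraction converges to `f`
without any feedback control.

**Population structure.** Whether a cell is episodic at all is a Bernoulli
draw with `episodic_cell_prob`; a non-episodic cell fires permanently. The
preset `frac_nonfiring` is therefore the silent fraction of an *episodic*
cell, and the population-mean percent nonfiring time is the product of the
two fields (wild type: 0.1524 × 0.42 → 6.4%; the cAMP-insensitive mutant:
0.4189 × 0.90 → 37.7%). Between-cell variability of ΔVm is modelled as a
per-trace Gaussian offset (`delta_vm_cell_sd`, default 1 mV, consistent
with a reported SEM of ≈0.36 mV over 9 cells); episode-duration SDs (10 s
mutant, 6 s wild type) are generator choices matched to the reported
standard errors of episode durations. Recording noise is white Gaussian
(0.5 mV default, typical of perforated-patch recordings). A liquid-
junction-potential offset field exists on the preset (default 0) and is
applied uniformly when emitting traces.

**What the generator does not emulate.** AP-shape details (no APD50/90
structure), beating-rate drift within bouts, gradual (rather than abrupt)
mode transitions, gap-junction-coupled network effects, and arrhythmias
(junctional escape, AV dissociation). Passing the round-trip tests
therefore demonstrates that the *analysis* operations implement their
definitions correctly on signals with the assumed statistical structure;
it does not validate them against the full variability of real recordings.

## Segmentation rules and their edge cases

* A silent inter-AP gap ≥ 3.5 s becomes a nonfiring episode only if its
  mean potential lies within ±10 mV of the cell's mean firing MDP
  (computed per trace over all firing cycles).
* Episode onset is the end of the last AP's repolarization (first time the
  smoothed trace comes within 1 mV of the gap minimum); termination is the
  diastolic takeoff of the first new AP (backward scan from the AP while
  the 50 ms local slope exceeds 3× the median slope of the silent
  stretch). ΔVm is read as 100 ms means centred 100 ms inside each
  boundary, keeping AP transients out of the estimate.
* The 10 s threshold decides only the *cell class* (episodic vs
  permanent); episodes of 3.5–10 s still enter duration statistics and the
  percent-nonfiring time. Episodes truncated by the recording edges count
  toward percent nonfiring but are excluded from duration and ΔVm
  statistics (they are right/left-censored).
* Firing episodes tile the remainder of the trace, so firing + nonfiring
  time equals the trace duration exactly (asserted by tests).

## Voltage-clamp fitting

The Boltzmann model is the standard logistic sigmoid in the
hyperpolarization-activated orientation; V₀.₅ is the half-maximal point by
construction. Fits use bounded least squares (`scipy.optimize.curve_fit`)
with the half-range crossing as the V₀.₅ guess and k = 10 mV; k is bounded
positive. Flat datasets and zero-amplitude fits raise "no sigmoid
structure" rather than returning garbage. Exponential fits estimate the
initial delay as the time of 10% total amplitude change unless supplied;
an order-2 fit of single-exponential data is returned flagged
`degenerate` (τ₂ ≈ τ₁ or vanishing second amplitude), not raised. Linear
leak subtraction fits a line through the two most depolarized test
potentials. Tail-current normalization divides by the largest measured
current, so the fitted `imax` may slightly exceed 1 when the most negative
test potential does not fully activate the conductance.

## HRV spectral pipeline

RR values are assigned to the time of the terminating beat. 103 s of
tachogram resampled at 50 ms gives 2060 samples, of which the first 2048
feed three half-overlapping 1024-point Hamming windows (the layout is
asserted at runtime). Detrending is linear over the 2048-sample stretch.
The PSD is one-sided, window-power compensated, in ms²/Hz. Band powers use
a cumulative trapezoidal integral interpolated at the exact band edges, so
VLF + LF + HF = TP to numerical precision by construction. Frequency
resolution is 20 Hz/1024 ≈ 0.0195 Hz; spectral-peak tests use one grid bin
as their tolerance. The 50% window overlap implements "half overlapping";
SDNN uses the sample standard deviation (ddof = 1). Callers supply
pre-cleaned sinus-rhythm series; `clean_rr` (mean ± 4 SD) is available but
off by default.

## Baroreflex, stimulation and mapping choices

* Overlapping qualifying beat triples each count as separate sequences; a
  4-beat ramp yields two. Thresholds are inclusive (≥ 0.5 mmHg, ≥ 2 ms).
  The generator inserts a lead-in beat at the first sequence level so that
  each programmed sequence corresponds to exactly one qualifying triple.
* The compensatory-pause identity is tested with ε = 5 ms (≈2.5% of a
  200 ms murine sinus cycle). SACT uses the first deviating coupling by
  default; the plateau mean over all reset-zone rows is available
  (`use_plateau_mean`) and is what the jitter-robustness tests use, since
  averaging over the plateau is the natural noise-resistant estimator. The
  A3A4/A1A1 automaticity comparison is exposed as a diagnostic ratio
  without a threshold.
* Activation time is the maximum temporal derivative of the inverted,
  normalized fluorescence (not a 50% crossing). The signal is boxcar-
  smoothed over 5 frames and the sub-frame time is the centroid of the
  derivative lobe above half its peak — unbiased for symmetric upstrokes
  and far more noise-tolerant than a raw argmax. Pixels with less than 20%
  of the stack's maximum amplitude are masked. Maps are referenced to the
  earliest valid pixel.
* Subthreshold-cell identification is visual in practice; the operation
  only normalizes supplied counts by the imaged area. The confocal field
  is interpreted as a 440 µm × 440 µm square.

## Problem sizes

Ensemble statistics use 600 s traces sampled at 1 kHz — long enough that
episode-duration censoring at the trace edges is negligible (measured bias
< 0.2 s) — with 50 traces per genotype in the acceptance script and 10 per
genotype in the test suite; waveform-calibration checks use 10 kHz
sampling to keep corner quantization below 0.1 mV. All runs complete in
seconds to a few minutes on one CPU.

## Known limitations

* The stylized AP makes no claim about upstroke velocity, APD or rate
  adaptation; only MDP, averages and SDD slope are meaningful.
* Percent-nonfiring estimates for weakly episodic populations have large
  between-ensemble variance (the Bernoulli cell-class draw dominates).
* The spectral pipeline assumes stationarity over the 103 s segment and a
  strictly monotone beat-time axis; ectopy and artifacts must be removed
  upstream.
* `compute_sact` assumes a clean two-zone response; real curves with
  gradual transitions may need the plateau-mean estimator and a wider ε.
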
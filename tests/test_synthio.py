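"""Generator contracts: closed forms, reproducibility, programmed events."""

import dataclasses

import numpy as np
import pytest

from sanephys import synthio
from sanephys.synthio import (
    BaroGenSpec,
    ChannelPreset,
    PacemakerPreset,
    RrGenSpec,
    SactGenSpec,
    gen_activation_dataset,
    gen_bp_rr,
    gen_current_trace,
    gen_pacemaker_trace,
    gen_premature_stim,
    gen_rr_series,
    gen_wave_stack,
)


class TestPacemakerTrace:
    def test_permanent_preset_fires_continuously(self, quiet_wt):
        trace, ev = gen_pacemaker_trace(quiet_wt, 60.0, 1000.0, seed=0,
                                        return_events=True)
        assert not ev.is_episodic
        assert len(ev.silent_episodes) == 0
        # no inter-AP gap longer than one firing cycle
        assert np.max(np.diff(ev.ap_times)) < 1.5 / quiet_wt.firing_rate

    def test_first_cycle_average_potential(self, quiet_wt):
        """A bout starting at an MDP of -67 mV averages -51 mV over its
        first firing cycle."""
        trace = gen_pacemaker_trace(quiet_wt, 2.0, 10000.0, seed=0)
        cycle = trace.slice(0.0, 1.0 / quiet_wt.firing_rate)
        assert np.mean(cycle.values) == pytest.approx(-51.0, abs=0.05)

    def test_episode_durations_match_event_log(self, fea_preset):
        """Empirical mean episode duration agrees with the preset mean
        within 2 SE of the sampled episode lengths."""
        preset = dataclasses.replace(fea_preset, episodic_cell_prob=1.0)
        durs = []
        for seed in range(30):
            _, ev = gen_pacemaker_trace(preset, 600.0, 1000.0, seed=seed,
                                        return_events=True)
            # exclude episodes truncated by the end of the recording
            durs.extend(e[1] - e[0] for e in ev.silent_episodes
                        if e[1] < 600.0)
        durs = np.asarray(durs)
        se = durs.std(ddof=1) / np.sqrt(durs.size)
        assert abs(durs.mean() - preset.mean_episode_s) < 2.0 * se + 0.2

    def test_silent_fraction_converges(self, fea_preset):
        """Long-run silent fraction approaches the preset frac_nonfiring."""
        preset = dataclasses.replace(fea_preset, episodic_cell_prob=1.0)
        fracs = []
        for seed in range(10):
            _, ev = gen_pacemaker_trace(
                preset, 10.0 * preset.mean_episode_s / preset.frac_nonfiring,
                1000.0, seed=seed, return_events=True)
            total = 10.0 * preset.mean_episode_s / preset.frac_nonfiring
            fracs.append(sum(e[1] - e[0] for e in ev.silent_episodes) / total)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - preset.frac_nonfiring) < 3.0 * se + 0.01

    def test_bit_reproducible(self, fea_preset):
        a = gen_pacemaker_trace(fea_preset, 30.0, 1000.0, seed=7)
        b = gen_pacemaker_trace(fea_preset, 30.0, 1000.0, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_rejects_bad_inputs(self, quiet_wt):
        with pytest.raises(ValueError):
            PacemakerPreset(frac_nonfiring=1.0)
        with pytest.raises(ValueError):
            gen_pacemaker_trace(quiet_wt, 0.05, 1000.0, seed=0)


class TestActivationDataset:
    def test_half_activation_at_v05(self):
        p = ChannelPreset(v05=-100.0, k=10.0)
        ds = gen_activation_dataset(p, np.arange(-140.0, -39.0, 10.0))
        row = ds[ds.vm_mv == -100.0]
        assert row.current.iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_noiseless_matches_closed_form(self):
        p = ChannelPreset(v05=-82.1, k=8.0, imin=0.05, imax=0.95)
        vm = np.arange(-140.0, -39.0, 10.0)
        ds = gen_activation_dataset(p, vm)
        expected = 0.05 + 0.9 / (1.0 + np.exp((vm + 82.1) / 8.0))
        np.testing.assert_allclose(ds.current.to_numpy(), expected, rtol=1e-9)

    def test_rejects_nonpositive_k(self):
        with pytest.raises(ValueError):
            ChannelPreset(k=0.0)


class TestCurrentTrace:
    def test_order1_closed_form(self):
        p = ChannelPreset(imin=2.0, imax=5.0, tau1=0.5, tau2=0.05, delay=0.0)
        tr = gen_current_trace(p, 3.0, 1000.0, order=1)
        i = int(0.5 * 1000)
        assert tr.values[i] == pytest.approx(2.0 + 3.0 * np.exp(-1.0), rel=1e-6)

    def test_delay_holds_onset_value(self):
        p = ChannelPreset(imin=0.0, imax=1.0, tau1=0.4, tau2=0.04, delay=0.05)
        tr = gen_current_trace(p, 3.0, 1000.0, order=2)
        np.testing.assert_allclose(tr.values[:50], 1.0, rtol=1e-12)

    def test_rejects_bad_order(self):
        p = ChannelPreset()
        with pytest.raises(ValueError):
            gen_current_trace(p, 10.0, 1000.0, order=3)


class TestRrSeries:
    def test_constant_when_unmodulated(self):
        s = RrGenSpec(mean_rr=100.0, n_beats=50)
        beats = gen_rr_series(s)
        np.testing.assert_allclose(beats.rr_ms, 100.0)

    def test_single_pause(self):
        s = RrGenSpec(mean_rr=100.0, n_beats=50, pause_times=(20,),
                      pause_factor=2.5)
        beats = gen_rr_series(s)
        assert np.sum(beats.rr_ms == 250.0) == 1
        assert np.sum(beats.rr_ms == 100.0) == 49

    def test_lf_modulation_concentrates_lf_power(self):
        s = RrGenSpec(mean_rr=100.0, n_beats=1200, lf_amp=5.0, lf_freq=1.0)
        beats = gen_rr_series(s)
        # direct periodogram oracle on a nearest-beat resampled series
        t = np.arange(0.0, beats.t_s[-1], 0.05)
        x = beats.rr_ms[np.searchsorted(beats.t_s, t).clip(0, beats.n_beats - 1)]
        x = x - x.mean()
        f = np.fft.rfftfreq(x.size, 0.05)
        p = np.abs(np.fft.rfft(x)) ** 2
        peak = f[np.argmax(p)]
        assert 0.4 <= peak <= 1.5

    def test_rejects_nonpositive_rr(self):
        s = RrGenSpec(mean_rr=100.0, n_beats=50, pause_times=(5,),
                      pause_factor=-1.0)
        with pytest.raises(ValueError):
            gen_rr_series(s)


class TestBpRr:
    def test_zero_sequences(self):
        beats = gen_bp_rr(BaroGenSpec(n_up=0, n_down=0, n_beats=100))
        assert np.allclose(beats.sbp_mmhg, beats.sbp_mmhg[0])

    def test_rejects_overfull_layout(self):
        with pytest.raises(ValueError):
            gen_bp_rr(BaroGenSpec(n_up=50, n_down=50, n_beats=100))


class TestPrematureStim:
    def test_two_zone_arithmetic(self):
        spec = SactGenSpec(scl=200.0, sact=25.0, reset_onset=180.0, snerp=80.0,
                           couplings=(190.0, 120.0))
        table = gen_premature_stim(spec)
        comp = table[table.a1a2_ms == 190.0].iloc[0]
        reset = table[table.a1a2_ms == 120.0].iloc[0]
        assert comp.a2a3_ms == 2 * 200.0 - 190.0  # 210, compensatory
        assert reset.a2a3_ms == 200.0 + 2 * 25.0  # 250, reset plateau
        assert comp.a3a4_ms == 200.0

    def test_rejects_subthreshold_coupling(self):
        spec = SactGenSpec(couplings=(70.0,))
        with pytest.raises(ValueError):
            gen_premature_stim(spec)
        assert gen_premature_stim(spec, allow_no_capture=True).empty


class TestWaveStack:
    def test_activation_time_scales_with_distance(self):
        stack = gen_wave_stack(grid=(1, 11), pitch_um=100.0, origin=(0, 0),
                               velocity_um_ms=100.0)
        t = stack.true_activation_ms
        # pixels 1000 um apart at 100 um/ms differ by 10 ms
        assert t[0, 10] - t[0, 0] == pytest.approx(10.0)

    def test_reproducible_and_origin_earliest(self):
        a = gen_wave_stack(grid=(8, 8), origin=(2, 3), noise_sd=0.02, seed=5)
        b = gen_wave_stack(grid=(8, 8), origin=(2, 3), noise_sd=0.02, seed=5)
        assert np.array_equal(a.frames, b.frames)
        t = a.true_activation_ms
        assert np.unravel_index(np.argmin(t), t.shape) == (2, 3)

    def test_rejects_origin_outside_grid(self):
        with pytest.raises(ValueError):
            gen_wave_stack(grid=(4, 4), origin=(5, 0))
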
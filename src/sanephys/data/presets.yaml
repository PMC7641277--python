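# Preset library.
#
# Pacemaker presets encode the episodic-firing statistics of single murine
# SAN cells per genotype/condition: delta_vm (mV, depolarization across a
# nonfiring episode), mean/SD of episode durations (s), the silent-time
# fraction of an episodic cell (frac_nonfiring), and the probability that a
# cell is episodic at all (episodic_cell_prob). The population-mean percent
# nonfiring time is the product frac_nonfiring * episodic_cell_prob
# (wt: 0.1524 * 0.42 = 6.4 %; hcn4fea: 0.4189 * 0.90 = 37.7 %).
#
# Channel presets encode Boltzmann activation parameters per genotype x cAMP
# x holding potential; slope factors default to 10 mV.

pacemaker:
  wt:
    firing_rate: 5.0
    mdp_onset: -67.0
    mdp_end: -75.0
    ap_peak: 25.0
    sdd_slope: 100.0
    delta_vm: 8.16
    delta_vm_cell_sd: 1.0
    mean_episode_s: 16.2
    episode_sd_s: 6.0
    frac_nonfiring: 0.1524
    episodic_cell_prob: 0.42
    noise_sd: 0.5
    ljp_offset: 0.0
  hcn4fea:
    firing_rate: 5.0
    mdp_onset: -67.0
    mdp_end: -75.0
    ap_peak: 25.0
    sdd_slope: 100.0
    delta_vm: 7.17
    delta_vm_cell_sd: 1.0
    mean_episode_s: 28.9
    episode_sd_s: 10.0
    frac_nonfiring: 0.4189
    episodic_cell_prob: 0.90
    noise_sd: 0.5
    ljp_offset: 0.0
  wt_iso:            # isoproterenol abolishes nonfiring in wild type
    firing_rate: 6.5
    mdp_onset: -67.0
    mdp_end: -75.0
    ap_peak: 25.0
    sdd_slope: 130.0
    delta_vm: 8.16
    delta_vm_cell_sd: 1.0
    mean_episode_s: 16.2
    episode_sd_s: 6.0
    frac_nonfiring: 0.0
    episodic_cell_prob: 0.0
    noise_sd: 0.5
    ljp_offset: 0.0
  hcn4fea_iso:       # 57.1 % of mutant cells remain episodic under iso
    firing_rate: 5.8
    mdp_onset: -67.0
    mdp_end: -75.0
    ap_peak: 25.0
    sdd_slope: 120.0
    delta_vm: 7.17
    delta_vm_cell_sd: 1.0
    mean_episode_s: 28.9
    episode_sd_s: 10.0
    frac_nonfiring: 0.4189
    episodic_cell_prob: 0.571
    noise_sd: 0.5
    ljp_offset: 0.0
  wt_trip8b:         # illustrative: CDR block induces pronounced nonfiring
    firing_rate: 5.0
    mdp_onset: -67.0
    mdp_end: -75.0
    ap_peak: 25.0
    sdd_slope: 100.0
    delta_vm: 8.5
    delta_vm_cell_sd: 1.0
    mean_episode_s: 32.0
    episode_sd_s: 10.0
    frac_nonfiring: 0.45
    episodic_cell_prob: 1.0
    noise_sd: 0.5
    ljp_offset: 0.0

channel:
  wt_nocamp_hp55: {v05: -100.1, k: 10.0, holding_potential: -55.0,
                   imax: 1.0, imin: 0.0, tau1: 1.0, tau2: 0.1,
                   a1_frac: 0.7, delay: 0.05}
  wt_nocamp_hp65: {v05: -90.7, k: 10.0, holding_potential: -65.0,
                   imax: 1.0, imin: 0.0, tau1: 1.0, tau2: 0.1,
                   a1_frac: 0.7, delay: 0.05}
  wt_nocamp_hp75: {v05: -77.6, k: 10.0, holding_potential: -75.0,
                   imax: 1.0, imin: 0.0, tau1: 1.0, tau2: 0.1,
                   a1_frac: 0.7, delay: 0.05}
  wt_camp_hp55:   {v05: -82.1, k: 10.0, holding_potential: -55.0,
                   imax: 1.0, imin: 0.0, tau1: 0.7, tau2: 0.08,
                   a1_frac: 0.7, delay: 0.05}
  wt_camp_hp65:   {v05: -62.0, k: 10.0, holding_potential: -65.0,
                   imax: 1.0, imin: 0.0, tau1: 0.7, tau2: 0.08,
                   a1_frac: 0.7, delay: 0.05}
  wt_camp_hp75:   {v05: -51.3, k: 10.0, holding_potential: -75.0,
                   imax: 1.0, imin: 0.0, tau1: 0.7, tau2: 0.08,
                   a1_frac: 0.7, delay: 0.05}
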
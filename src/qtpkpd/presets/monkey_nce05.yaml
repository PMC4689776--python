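species: monkey
compound: NCE05
species_params:
  qtc0_ms: 367.0
  sex_effect_ms: 0.0
  alpha: 0.55
  amp_ms: 7.6
  phase_h: 0.0
  slope_ms_per_nM: 0.022
  bsv: {qtc0: 0.052, alpha: 0.019, amp: 0.026, phase: 0.032, slope: 0.42}
  resid_sd_ms: 7.4
pk:
  structure: interpolated
  ka_per_h: 1.0
  cl_L_per_h: 3.814
  vc_L: 38.14
  f_by_dose: {default: 1.0}
  bsv_cl: 0.25
  mw_g_per_mol: 450.0
design:
  n_subjects: 6
  sex_ratio: 0.5
  dose_levels: [0, 25, 40]
  dose_unit: mg_per_kg
  weight_range_kg: [2.8, 6.8]
  crossover: true
  pk_sample_times_h: [1.5, 4, 8, 24]
  ecg_sample_times_h: [-1.17, -1.0, -0.83, -0.67, -0.5, 0.5, 1, 2, 3, 4, 6, 8, 12,
    16, 20, 24]
  rr_baseline_ms: 500.0
  rr_circadian_frac: 0.08
  rr_noise_frac: 0.03
  rr_phase_h: 4.0
  dose_clock_h: 8.0
  balance_n_per_phase: null
cmax_ref_nM: 8660.0
lloq_nM: 0.0
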
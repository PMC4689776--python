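species: human
compound: moxifloxacin
species_params:
  qtc0_ms: 399.0
  sex_effect_ms: 8.0
  alpha: 0.4
  amp_ms: 2.4
  phase_h: 10.0
  slope_ms_per_nM: 0.0039
  bsv: {qtc0: 0.0501, alpha: 0.41, amp: 0.053, phase: 0.18, slope: 0.41}
  resid_sd_ms: 5.3
pk:
  structure: twocpt_zero_plus_first_order
  d1_h: 0.629
  ka_per_h: 2.21
  cl_L_per_h: 13.41
  vc_L: 122.0
  vp_L: 55.4
  q_L_per_h: 78.4
  f_by_dose: {default: 1.0}
  bsv_cl: 0.0269
  mw_g_per_mol: 401.43
design:
  n_subjects: 24
  sex_ratio: 0.64
  dose_levels: [0, 400]
  dose_unit: mg
  crossover: true
  pk_sample_times_h: [0.25, 0.5, 1, 1.5, 2, 2.5, 3, 4, 6, 8, 10, 12, 24]
  ecg_sample_times_h: [-0.17, 0.33, 0.67, 1, 1.5, 2, 3, 4, 6, 8, 12, 16, 24, 36, 48]
  rr_baseline_ms: 900.0
  rr_circadian_frac: 0.1
  rr_noise_frac: 0.04
  rr_phase_h: 4.0
  dose_clock_h: 8.0
  balance_n_per_phase: null
cmax_ref_nM: 10300.0
lloq_nM: 0.0
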
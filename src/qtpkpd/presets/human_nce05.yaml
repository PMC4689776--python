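species: human
compound: NCE05
species_params:
  qtc0_ms: 378.0
  sex_effect_ms: 0.0
  alpha: 0.26
  amp_ms: 4.2
  phase_h: 8.1
  slope_ms_per_nM: 0.0052
  bsv: {qtc0: 0.052, alpha: 0.19, amp: 0.082, phase: 0.16, slope: 0.37}
  resid_sd_ms: 16.0
pk:
  structure: onecpt_first_order
  ka_per_h: 1.0
  cl_L_per_h: 51.1
  vc_L: 511.0
  f_by_dose: {default: 1.0}
  bsv_cl: 0.2
  mw_g_per_mol: 450.0
design:
  n_subjects: 24
  sex_ratio: 1.0
  dose_levels: [1, 4, 14, 30]
  dose_unit: mg
  crossover: false
  pk_sample_times_h: [0.33, 0.67, 1, 1.5, 2, 3, 4, 6, 8, 12, 16, 24, 36, 48]
  ecg_sample_times_h: [-0.17, 0.33, 0.67, 1, 1.5, 2, 3, 4, 6, 8, 12, 16, 24, 36, 48]
  rr_baseline_ms: 900.0
  rr_circadian_frac: 0.1
  rr_noise_frac: 0.04
  rr_phase_h: 4.0
  dose_clock_h: 8.0
  balance_n_per_phase: null
cmax_ref_nM: 101.0
lloq_nM: 5.0
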
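species: dog
compound: moxifloxacin
species_params:
  qtc0_ms: 240.0
  sex_effect_ms: 0.0
  alpha: 0.28
  amp_ms: 4.6
  phase_h: 23.1
  slope_ms_per_nM: 0.00056
  bsv: {qtc0: 0.0646, alpha: 0.86, amp: 0.098, phase: 0.13, slope: 0.25}
  resid_sd_ms: 9.4
pk:
  structure: onecpt_first_order
  ka_per_h: 1.78
  cl_L_per_h: 3.39
  vc_L: 43.23
  f_by_dose: {default: 7.54}
  bsv_cl: 0.21
  mw_g_per_mol: 401.43
design:
  n_subjects: 8
  sex_ratio: 1.0
  dose_levels: [0, 3, 10, 30]
  dose_unit: mg_per_kg
  weight_range_kg: [8.0, 12.0]
  crossover: true
  pk_sample_times_h: [0.5, 1, 2, 4, 8, 24, 36, 48]
  ecg_sample_times_h: [-1.0, -0.5, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.25,
    2.5, 2.75, 3.0, 3.25, 3.5, 3.75, 4.0, 4.25, 4.5, 4.75, 5.0, 5.25, 5.5, 5.75, 6.0,
    6.25, 6.5, 6.75, 7.0, 7.25, 7.5, 7.75, 8.0, 8.25, 8.5, 8.75, 9.0, 9.25, 9.5, 9.75,
    10.0, 10.25, 10.5, 10.75, 11.0, 11.25, 11.5, 11.75, 12.0, 12.25, 12.5, 12.75,
    13.0, 13.25, 13.5, 13.75, 14.0, 14.25, 14.5, 14.75, 15.0, 15.25, 15.5, 15.75,
    16.0, 16.25, 16.5, 16.75, 17.0, 17.25, 17.5, 17.75, 18.0, 18.25, 18.5, 18.75,
    19.0, 19.25, 19.5, 19.75, 20.0, 20.25, 20.5, 20.75, 21.0, 21.25, 21.5, 21.75,
    22.0, 22.25, 22.5, 22.75, 23.0, 23.25, 23.5, 23.75]
  rr_baseline_ms: 600.0
  rr_circadian_frac: 0.08
  rr_noise_frac: 0.03
  rr_phase_h: 4.0
  dose_clock_h: 8.0
  balance_n_per_phase: 5
cmax_ref_nM: 112930.0
lloq_nM: 0.0
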
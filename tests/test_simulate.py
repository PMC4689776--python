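"""Synthetic study generator: distributional and structural properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from qtpkpd import (
    DesignSpec,
    SpeciesParams,
    generate_from_preset,
    generate_study,
    load_preset,
    simulate_individual_params,
    simulate_qt,
    simulate_rr_series,
)


class TestIndividualParams:
    def test_zero_bsv_gives_identical_copies(self, flat_params):
        subj = simulate_individual_params(flat_params, 3, seed=0)
        assert len(subj) == 3
        for p in subj:
            assert p["qtc0"] == flat_params.qtc0_ms
            assert p["alpha"] == flat_params.alpha
            assert p["amp"] == flat_params.amp_ms
            assert p["phase"] == flat_params.phase_h
            assert p["slope"] == flat_params.slope_ms_per_nM

    def test_log_sd_of_baseline_matches_bsv_fraction(self, human_mox):
        # human reported between-subject CV of baseline QTc is 5.01%
        subj = simulate_individual_params(human_mox.species_params, 10_000, seed=42)
        log_q = np.log([p["qtc0"] for p in subj])
        assert np.std(log_q) == pytest.approx(0.0501, rel=0.05)

    def test_negative_slope_fraction_matches_normal_tail(self):
        # slope ~ N(mu, 0.37*mu): P(slope < 0) = Phi(-1/0.37) by closed form
        pop = SpeciesParams(qtc0_ms=378, sex_effect_ms=0, alpha=0.26, amp_ms=4.2,
                            phase_h=8.1, slope_ms_per_nM=0.0052,
                            bsv={"slope": 0.37}, resid_sd_ms=16)
        subj = simulate_individual_params(pop, 10_000, seed=7)
        frac_neg = np.mean([p["slope"] < 0 for p in subj])
        assert frac_neg == pytest.approx(stats.norm.cdf(-1.0 / 0.37), abs=0.005)

    def test_moments_converge_to_generating_bsv(self, human_mox):
        subj = simulate_individual_params(human_mox.species_params, 10_000, seed=3)
        b = human_mox.species_params.bsv
        assert np.std(np.log([p["alpha"] for p in subj])) == pytest.approx(b["alpha"], rel=0.05)
        assert np.std(np.log([p["amp"] for p in subj])) == pytest.approx(b["amp"], rel=0.05)

    def test_sex_effect_added_for_females(self, flat_params):
        flat_params.sex_effect_ms = 8.0
        subj = simulate_individual_params(flat_params, 2, seed=0, sexes=["M", "F"])
        assert subj[1]["qtc0"] - subj[0]["qtc0"] == pytest.approx(8.0)

    def test_rejects_bad_inputs(self, flat_params):
        with pytest.raises(ValueError):
            simulate_individual_params(flat_params, 0, seed=0)
        with pytest.raises(ValueError):
            SpeciesParams(qtc0_ms=-1, sex_effect_ms=0, alpha=0.4, amp_ms=1,
                          phase_h=1, slope_ms_per_nM=0)


class TestRRSeries:
    def test_constant_without_variability(self, simple_design):
        simple_design.rr_circadian_frac = 0.0
        simple_design.rr_noise_frac = 0.0
        rr = simulate_rr_series(simple_design, [0, 6, 12, 18], seed=0)
        assert np.allclose(rr, simple_design.rr_baseline_ms)

    def test_cosine_peak_at_rr_phase(self, simple_design):
        simple_design.rr_noise_frac = 0.0
        rr = simulate_rr_series(simple_design, [simple_design.rr_phase_h], seed=0)
        assert rr[0] == pytest.approx(1100.0)

    def test_series_bounded_by_circadian_plus_noise(self, simple_design):
        t = np.linspace(0, 24, 200)
        rr = simulate_rr_series(simple_design, t, seed=5)
        lo = simple_design.rr_baseline_ms * (1 - 0.1 - 4 * 0.03)
        hi = simple_design.rr_baseline_ms * (1 + 0.1 + 4 * 0.03)
        assert rr.min() > lo and rr.max() < hi

    def test_rejects_non_positive_rr(self, simple_design):
        simple_design.rr_circadian_frac = 0.999999
        with pytest.raises(ValueError):
            DesignSpec(**{**vars(simple_design), "rr_circadian_frac": 1.5})


class TestQTModel:
    def test_baseline_at_rr_one_second(self, flat_params):
        p = dict(qtc0=399.0, alpha=0.40, amp=0.0, phase=0.0, slope=0.0)
        qt = simulate_qt(p, [1000.0], [12.0], [0.0], 0.0, seed=0)
        assert qt[0] == pytest.approx(399.0)

    def test_power_law_correction_at_faster_heart_rate(self):
        p = dict(qtc0=399.0, alpha=0.40, amp=0.0, phase=0.0, slope=0.0)
        qt = simulate_qt(p, [640.0], [12.0], [0.0], 0.0, seed=0)
        assert qt[0] == pytest.approx(399.0 * 0.64 ** 0.40, rel=1e-12)

    def test_linear_drug_effect_adds_slope_times_conc(self):
        p0 = dict(qtc0=399.0, alpha=0.40, amp=0.0, phase=0.0, slope=0.0)
        p1 = dict(p0, slope=0.0039)
        base = simulate_qt(p0, [640.0], [12.0], [10300.0], 0.0, seed=0)[0]
        qt = simulate_qt(p1, [640.0], [12.0], [10300.0], 0.0, seed=0)[0]
        assert qt - base == pytest.approx(0.0039 * 10300.0)  # 40.17 ms

    def test_noise_free_evaluation_is_exact(self):
        p = dict(qtc0=350.0, alpha=0.3, amp=5.0, phase=9.0, slope=0.002)
        t = np.linspace(0, 24, 13)
        rr = np.full_like(t, 800.0)
        conc = np.linspace(0, 500, 13)
        expected = (350.0 * 0.8 ** 0.3 + 5.0 * np.cos(2 * np.pi * (t - 9.0) / 24.0)
                    + 0.002 * conc)
        assert np.allclose(simulate_qt(p, rr, t, conc, 0.0, seed=0), expected)

    def test_placebo_day_mean_equals_corrected_baseline(self):
        # cosine integrates to zero over a uniformly sampled 24-h day
        p = dict(qtc0=400.0, alpha=0.40, amp=6.0, phase=10.0, slope=0.0)
        t = np.arange(0, 24, 0.25)
        rr = np.full_like(t, 850.0)
        qt = simulate_qt(p, rr, t, np.zeros_like(t), 0.0, seed=0)
        assert qt.mean() == pytest.approx(400.0 * 0.85 ** 0.40, abs=1e-9)

    def test_rejects_non_positive_rr(self):
        p = dict(qtc0=399.0, alpha=0.4, amp=0.0, phase=0.0, slope=0.0)
        with pytest.raises(ValueError):
            simulate_qt(p, [0.0], [0.0], [0.0], 0.0, seed=0)


class TestGenerateStudy:
    def test_placebo_only_study_has_zero_concentrations(self, flat_params, simple_design):
        simple_design.dose_levels = [0]
        from qtpkpd.params import PKModelSpec
        pk = PKModelSpec(structure="onecpt_first_order", ka_per_h=1.0,
                         cl_L_per_h=5.0, vc_L=50.0, mw_g_per_mol=400.0)
        ds = generate_study(flat_params, pk, simple_design, seed=1)
        assert (ds.df["CONC"] == 0).all()

    def test_same_seed_is_byte_identical(self, human_mox, tmp_path):
        a = generate_from_preset(human_mox, 11)
        b = generate_from_preset(human_mox, 11)
        a.to_csv(tmp_path / "a.csv")
        b.to_csv(tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_parallel_human_design_shape(self):
        # 24 subjects in parallel groups of 6 across four dose levels, each
        # observed on the 15-point ECG grid
        preset = load_preset("human_nce05")
        ds = generate_from_preset(preset, 2)
        assert ds.n_subjects == 24
        assert len(ds.df) == 24 * 15
        assert ds.df.groupby("ID")["DOSE"].nunique().eq(1).all()
        assert sorted(ds.df["DOSE"].unique()) == [1, 4, 14, 30]
        # the 1 mg arm falls below the LLOQ and is zeroed (baseline arm)
        assert (ds.df.loc[ds.df["DOSE"] == 1, "CONC"] == 0).all()

    @pytest.mark.parametrize("name", ["dog_moxifloxacin", "monkey_moxifloxacin",
                                      "human_moxifloxacin", "monkey_nce05", "human_nce05"])
    def test_all_presets_satisfy_dataset_invariants(self, name):
        ds = generate_from_preset(load_preset(name), 5)
        ds.validate()  # raises on violation
        assert ds.meta["seed"] == 5

    def test_empty_dose_list_rejected(self, flat_params, simple_design):
        from qtpkpd.params import PKModelSpec
        simple_design.dose_levels = []
        pk = PKModelSpec(structure="onecpt_first_order", ka_per_h=1.0,
                         cl_L_per_h=5.0, vc_L=50.0, mw_g_per_mol=400.0)
        with pytest.raises(ValueError):
            generate_study(flat_params, pk, simple_design, seed=1)


@settings(max_examples=25, deadline=None)
@given(phase=st.floats(0, 23.99), bsv_phase=st.floats(0, 0.5),
       seed=st.integers(0, 2**31 - 1))
def test_simulated_phases_stay_wrapped(phase, bsv_phase, seed):
    pop = SpeciesParams(qtc0_ms=400, sex_effect_ms=0, alpha=0.4, amp_ms=2,
                        phase_h=phase, slope_ms_per_nM=0.001,
                        bsv={"phase": bsv_phase}, resid_sd_ms=5)
    subj = simulate_individual_params(pop, 50, seed=seed)
    ph = np.array([p["phase"] for p in subj])
    assert np.all((ph >= 0) & (ph < 24))
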
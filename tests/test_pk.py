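"""PK prediction layer: closed forms vs ODE oracles, interpolation, BLQ, balancing."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from qtpkpd import (
    ConcProfile,
    apply_blq,
    balance_phases,
    interpolate_profile,
    load_preset,
    predict_onecpt,
    predict_twocpt_zero_first,
    time_of_peak,
)
from qtpkpd.params import PKModelSpec


@pytest.fixture
def dog_pk():
    # reported dog disposition: Ka 1.78/h, CL 3.39 L/h, Vc 43.23 L
    return PKModelSpec(structure="onecpt_first_order", ka_per_h=1.78,
                       cl_L_per_h=3.39, vc_L=43.23, mw_g_per_mol=401.43)


@pytest.fixture
def human_pk():
    # reported human disposition: D1 0.629 h, Ka 2.21/h, CL 13.41 L/h,
    # Vc 122 L, Vp 55.4 L, Q 78.4 L/h
    return PKModelSpec(structure="twocpt_zero_plus_first_order", d1_h=0.629,
                       ka_per_h=2.21, cl_L_per_h=13.41, vc_L=122.0, vp_L=55.4,
                       q_L_per_h=78.4, mw_g_per_mol=401.43)


class TestOneCompartment:
    def test_zero_dose_gives_zero_profile(self, dog_pk):
        prof = predict_onecpt(dog_pk, 0.0, [0, 1, 2, 4])
        assert np.all(prof.conc_nM == 0)

    def test_closed_form_matches_ode_integration(self, dog_pk):
        times = np.array([0.25, 0.5, 1, 2, 4, 8, 12, 24, 36, 48], float)
        prof = predict_onecpt(dog_pk, 300.0, times)
        ka, ke = dog_pk.ka_per_h, dog_pk.cl_L_per_h / dog_pk.vc_L
        amount0 = 300.0 / dog_pk.mw_g_per_mol * 1e6

        def rhs(t, y):
            return [-ka * y[0], ka * y[0] - ke * y[1]]

        sol = solve_ivp(rhs, (0, 48), [amount0, 0.0], t_eval=times,
                        rtol=1e-10, atol=1e-12)
        oracle = sol.y[1] / dog_pk.vc_L
        assert np.allclose(prof.conc_nM, oracle, rtol=1e-3)

    def test_monotone_decay_after_peak(self, dog_pk):
        tmax = time_of_peak(dog_pk)
        t = np.linspace(tmax, 96, 300)
        conc = predict_onecpt(dog_pk, 100.0, t).conc_nM
        assert np.all(np.diff(conc) < 0)
        assert conc[-1] < 1e-2 * conc[0]

    def test_flip_flop_limit_is_continuous(self):
        near = PKModelSpec(structure="onecpt_first_order", ka_per_h=0.1 + 1e-10,
                           cl_L_per_h=1.0, vc_L=10.0, mw_g_per_mol=400.0)
        equal = PKModelSpec(structure="onecpt_first_order", ka_per_h=0.1,
                            cl_L_per_h=1.0, vc_L=10.0, mw_g_per_mol=400.0)
        t = [1.0, 5.0, 20.0]
        assert np.allclose(predict_onecpt(near, 10, t).conc_nM,
                           predict_onecpt(equal, 10, t).conc_nM, rtol=1e-6)

    def test_dose_level_bioavailability_lookup(self, dog_pk):
        dog_pk.f_by_dose = {"default": 1.0, 30: 0.5}
        full = predict_onecpt(dog_pk, 300.0, [2.0], dose_level=3).conc_nM[0]
        half = predict_onecpt(dog_pk, 300.0, [2.0], dose_level=30).conc_nM[0]
        assert half == pytest.approx(0.5 * full)


class TestTwoCompartment:
    def test_zero_dose_gives_zero_profile(self, human_pk):
        assert np.all(predict_twocpt_zero_first(human_pk, 0.0, [1, 2]).conc_nM == 0)

    def test_auc_mass_balance(self, human_pk):
        # AUC(0, inf) = F*Dose/CL; trapezoidal AUC to 96 h captures it within 2%
        t = np.linspace(0.01, 96, 1500)
        conc = predict_twocpt_zero_first(human_pk, 400.0, t).conc_nM
        auc = np.trapezoid(conc, t)
        expected = (400.0 / human_pk.mw_g_per_mol * 1e6) / human_pk.cl_L_per_h
        assert auc == pytest.approx(expected, rel=0.02)

    def test_superposition_linearity(self, human_pk):
        t = [0.5, 1, 2, 6, 24]
        c1 = predict_twocpt_zero_first(human_pk, 200.0, t).conc_nM
        c2 = predict_twocpt_zero_first(human_pk, 400.0, t).conc_nM
        assert np.allclose(c2, 2 * c1, rtol=1e-9)

    def test_matrix_exponential_matches_ode_solver(self, human_pk):
        times = np.array([0.25, 0.5, 0.629, 1, 2, 4, 8, 24], float)
        prof = predict_twocpt_zero_first(human_pk, 400.0, times)
        amount = 400.0 / human_pk.mw_g_per_mol * 1e6
        rate = amount / human_pk.d1_h
        ka = human_pk.ka_per_h
        k10 = human_pk.cl_L_per_h / human_pk.vc_L
        k12 = human_pk.q_L_per_h / human_pk.vc_L
        k21 = human_pk.q_L_per_h / human_pk.vp_L

        def rhs(t, y):
            inp = rate if t <= human_pk.d1_h else 0.0
            return [inp - ka * y[0],
                    ka * y[0] - (k10 + k12) * y[1] + k21 * y[2],
                    k12 * y[1] - k21 * y[2]]

        sol = solve_ivp(rhs, (0, 24), [0, 0, 0], t_eval=times, rtol=1e-10,
                        atol=1e-12, max_step=0.05)
        assert np.allclose(prof.conc_nM, sol.y[1] / human_pk.vc_L, rtol=1e-3)


class TestInterpolation:
    def test_identity_at_observation_nodes(self):
        obs = ConcProfile("m1", [1, 2, 4, 8, 24], [10, 40, 30, 12, 1])
        out = interpolate_profile(obs, [1, 2, 4, 8, 24])
        assert np.allclose(out.conc_nM, obs.conc_nM)
        assert out.source == "interpolated"

    def test_log_linear_midpoint_is_geometric_mean(self):
        obs = ConcProfile("m1", [4.0, 8.0], [100.0, 25.0])
        out = interpolate_profile(obs, [6.0])
        assert out.conc_nM[0] == pytest.approx(50.0)

    def test_monkey_sampling_grid_covers_all_ecg_times(self):
        obs = ConcProfile("m1", [0, 1, 2, 4, 8, 24], [0, 300, 500, 350, 180, 20])
        ecg = np.arange(0.25, 24.25, 0.25)
        out = interpolate_profile(obs, ecg)
        assert np.all(np.isfinite(out.conc_nM)) and np.all(out.conc_nM >= 0)

    def test_monotone_in_log_space_between_nodes(self):
        obs = ConcProfile("m1", [2.0, 8.0], [400.0, 50.0])
        out = interpolate_profile(obs, np.linspace(2, 8, 25))
        assert np.all(np.diff(np.log(out.conc_nM)) < 0)

    def test_terminal_extrapolation_uses_last_log_slope(self):
        obs = ConcProfile("m1", [4.0, 8.0], [100.0, 25.0])  # t1/2 = 2 h
        out = interpolate_profile(obs, [12.0])
        assert out.conc_nM[0] == pytest.approx(25.0 / 4.0)

    def test_all_zero_observations_give_zero_output(self):
        obs = ConcProfile("m1", [1, 2, 4], [0, 0, 0])
        assert np.all(interpolate_profile(obs, [1.5, 3]).conc_nM == 0)

    def test_rise_from_zero_is_linear(self):
        obs = ConcProfile("m1", [0.0, 2.0], [0.0, 100.0])
        assert interpolate_profile(obs, [1.0]).conc_nM[0] == pytest.approx(50.0)


class TestBLQ:
    def test_rule_and_identity(self):
        prof = ConcProfile("s", [1, 2, 3], [5.0, 0.4, 0.0])
        assert np.allclose(apply_blq(prof, 0.5).conc_nM, [5.0, 0.0, 0.0])
        assert np.allclose(apply_blq(prof, 0.0).conc_nM, prof.conc_nM)

    def test_idempotent(self):
        prof = ConcProfile("s", [1, 2, 3, 4], [12.0, 3.0, 0.7, 0.0])
        once = apply_blq(prof, 1.0)
        twice = apply_blq(once, 1.0)
        assert np.allclose(once.conc_nM, twice.conc_nM)


class TestBalancePhases:
    def _frame(self, times, occ=1):
        n = len(times)
        return pd.DataFrame({
            "ID": "d1", "SPECIES": "dog", "SEX": "M", "DOSE": 30, "OCC": occ,
            "TIME": times, "CONC": np.linspace(100, 1, n), "RR": 600.0, "QT": 250.0,
        })

    def test_identity_when_quota_exceeds_records(self):
        df = self._frame(np.linspace(0.5, 23.5, 9))
        out = balance_phases(df, tmax_h=2.0, n_per_phase=10)
        assert len(out) == len(df)

    def test_thirty_uniform_records_thinned_to_quota(self):
        df = self._frame(np.linspace(0.4, 24.0, 30))
        out = balance_phases(df, tmax_h=2.0, n_per_phase=5)
        assert len(out) <= 15
        t = out["TIME"].to_numpy()
        assert (t < 1.6).sum() >= 1          # absorption: t < 0.8*tmax
        assert ((t >= 1.6) & (t <= 3.0)).sum() >= 1   # peak window
        assert (t > 3.0).sum() >= 1          # elimination

    def test_placebo_occasion_thinned_by_same_time_rule(self):
        active = self._frame(np.linspace(0.4, 24.0, 30), occ=2)
        placebo = self._frame(np.linspace(0.4, 24.0, 30), occ=1)
        placebo["CONC"] = 0.0
        df = pd.concat([placebo, active], ignore_index=True)
        out = balance_phases(df, tmax_h=2.0, n_per_phase=5)
        t1 = out.loc[out["OCC"] == 1, "TIME"].to_numpy()
        t2 = out.loc[out["OCC"] == 2, "TIME"].to_numpy()
        assert np.array_equal(t1, t2)

    def test_deterministic(self):
        df = self._frame(np.linspace(0.4, 24.0, 30))
        a = balance_phases(df, 2.0, 4)
        b = balance_phases(df, 2.0, 4)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_zero_quota(self):
        with pytest.raises(ValueError):
            balance_phases(self._frame([1.0, 2.0]), 2.0, 0)
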
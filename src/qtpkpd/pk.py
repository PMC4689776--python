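"""Plasma-concentration prediction at ECG assessment times.

Dogs use a closed-form oral one-compartment model and humans a two-compartment
model with sequential zero-order + first-order absorption (solved exactly via
the matrix exponential of the linear three-state system).  Monkey profiles are
interpolated log-linearly between sparse observed samples, standing in for the
deconvolution step used when compartmental modelling gives poor individual
predictions.  BLQ handling (set to zero) and balanced-dataset thinning of
continuous telemetry records live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from .params import PKModelSpec

__all__ = [
    "ConcProfile",
    "predict_onecpt",
    "predict_twocpt_zero_first",
    "interpolate_profile",
    "apply_blq",
    "balance_phases",
    "time_of_peak",
]


@dataclass
class ConcProfile:
    """Concentration-time profile for one subject (nM at hours post dose)."""

    subject_id: str
    times_h: np.ndarray
    conc_nM: np.ndarray
    source: str = "predicted"  # predicted | interpolated | observed

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.conc_nM = np.asarray(self.conc_nM, dtype=float)
        if self.times_h.shape != self.conc_nM.shape:
            raise ValueError("times_h and conc_nM must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times_h must be strictly increasing")
        if np.any(self.conc_nM < 0):
            raise ValueError("conc_nM must be non-negative")


def _dose_to_nmol_factor(dose_mg: float, mw_g_per_mol: float) -> float:
    # mg / (g/mol) = mmol; mmol / L = mM = 1e6 nM
    return dose_mg / mw_g_per_mol * 1e6


def predict_onecpt(spec: PKModelSpec, dose_mg: float, times_h,
                   subject_id: str = "", cl_L_per_h: float | None = None,
                   dose_level=None) -> ConcProfile:
    """Closed-form oral one-compartment profile.

    C(t) = F*Dose*ka / (Vc*(ka-ke)) * (exp(-ke*t) - exp(-ka*t)), ke = CL/Vc,
    converted to nM via the molecular weight.  ``cl_L_per_h`` overrides the
    population clearance (individual value); ``dose_level`` selects the
    dose-indexed bioavailability (defaults to ``dose_mg``).  Negative times
    (pre-dose) yield zero concentration.
    """
    if spec.structure not in ("onecpt_first_order", "interpolated"):
        raise ValueError(f"predict_onecpt requires a one-compartment spec, got {spec.structure!r}")
    times = np.asarray(times_h, dtype=float)
    if dose_mg == 0:
        return ConcProfile(subject_id, times, np.zeros_like(times))
    if dose_mg < 0:
        raise ValueError("dose must be >= 0")
    f = spec.bioavailability(dose_mg if dose_level is None else dose_level)
    cl = spec.cl_L_per_h if cl_L_per_h is None else cl_L_per_h
    ka, vc = spec.ka_per_h, spec.vc_L
    ke = cl / vc
    t = np.clip(times, 0.0, None)
    amount = f * _dose_to_nmol_factor(dose_mg, spec.mw_g_per_mol)  # nmol-scale units
    if np.isclose(ka, ke, rtol=1e-9):
        conc = amount / vc * ka * t * np.exp(-ka * t)
    else:
        conc = amount * ka / (vc * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
    conc = np.where(times < 0, 0.0, np.clip(conc, 0.0, None))
    return ConcProfile(subject_id, times, conc)


def _twocpt_matrices(spec: PKModelSpec, cl: float):
    ka, vc, vp, q = spec.ka_per_h, spec.vc_L, spec.vp_L, spec.q_L_per_h
    k10, k12, k21 = cl / vc, q / vc, q / vp
    return np.array([
        [-ka, 0.0, 0.0],
        [ka, -(k10 + k12), k21],
        [0.0, k12, -k21],
    ])


def predict_twocpt_zero_first(spec: PKModelSpec, dose_mg: float, times_h,
                              subject_id: str = "", cl_L_per_h: float | None = None,
                              dose_level=None) -> ConcProfile:
    """Two-compartment disposition with zero-order input (duration D1) into a
    depot followed by first-order (Ka) absorption.

    The three-state linear ODE (depot, central, peripheral amounts) is solved
    exactly with matrix exponentials: constant-rate input on [0, D1] via the
    augmented-matrix form, homogeneous decay afterwards.  ``AUC(0, inf)``
    equals ``F*Dose/CL`` by mass balance.
    """
    if spec.structure != "twocpt_zero_plus_first_order":
        raise ValueError("spec structure must be twocpt_zero_plus_first_order")
    times = np.asarray(times_h, dtype=float)
    if np.any(times < -168):
        raise ValueError("times before -168 h rejected")
    if dose_mg == 0:
        return ConcProfile(subject_id, times, np.zeros_like(times))
    if dose_mg < 0:
        raise ValueError("dose must be >= 0")
    f = spec.bioavailability(dose_mg if dose_level is None else dose_level)
    cl = spec.cl_L_per_h if cl_L_per_h is None else cl_L_per_h
    d1 = spec.d1_h
    amount = f * _dose_to_nmol_factor(dose_mg, spec.mw_g_per_mol)
    rate = amount / d1
    A = _twocpt_matrices(spec, cl)
    b = np.array([rate, 0.0, 0.0])
    # augmented matrix: d/dt [x; 1] = [[A, b], [0, 0]] [x; 1] during infusion
    M = np.zeros((4, 4))
    M[:3, :3] = A
    M[:3, 3] = b

    def state_at(t: float) -> np.ndarray:
        if t <= 0:
            return np.zeros(3)
        if t <= d1:
            return (expm(M * t) @ np.array([0.0, 0.0, 0.0, 1.0]))[:3]
        x_d1 = (expm(M * d1) @ np.array([0.0, 0.0, 0.0, 1.0]))[:3]
        return expm(A * (t - d1)) @ x_d1

    conc = np.array([state_at(t)[1] / spec.vc_L for t in times])
    conc = np.clip(conc, 0.0, None)
    conc[times < 0] = 0.0
    return ConcProfile(subject_id, times, conc)


def predict_profile(spec: PKModelSpec, dose_mg: float, times_h, **kw) -> ConcProfile:
    """Dispatch on the declared PK structure (interpolated specs use their
    one-compartment generator form)."""
    if spec.structure == "twocpt_zero_plus_first_order":
        return predict_twocpt_zero_first(spec, dose_mg, times_h, **kw)
    return predict_onecpt(spec, dose_mg, times_h, **kw)


def time_of_peak(spec: PKModelSpec, dose_mg: float = 1.0) -> float:
    """Time of maximum concentration (h); dose-independent for linear PK."""
    if spec.structure in ("onecpt_first_order", "interpolated"):
        ka, ke = spec.ka_per_h, spec.cl_L_per_h / spec.vc_L
        if np.isclose(ka, ke):
            return 1.0 / ka
        return float(np.log(ka / ke) / (ka - ke))
    res = minimize_scalar(
        lambda t: -predict_twocpt_zero_first(spec, dose_mg, [t]).conc_nM[0],
        bounds=(1e-3, 48.0), method="bounded")
    return float(res.x)


def interpolate_profile(observed: ConcProfile, target_times_h) -> ConcProfile:
    """Interpolate sparse observed concentrations to ECG times.

    Log-linear between positive observations (the value at the midpoint is the
    geometric mean), linear on a rise from zero, zero-order hold at zero before
    the first sample, and terminal log-linear extrapolation beyond the last
    sample using the slope of the last two positive points.  Exact at the
    observation nodes.  An all-zero input yields an all-zero output.
    """
    if observed.times_h.size < 2:
        raise ValueError("interpolation requires at least 2 observed points")
    t_obs = observed.times_h
    c_obs = observed.conc_nM
    targets = np.asarray(target_times_h, dtype=float)
    if np.any(np.diff(targets) <= 0):
        raise ValueError("target times must be strictly increasing")
    out = np.zeros_like(targets)
    pos = c_obs > 0
    if not np.any(pos):
        return ConcProfile(observed.subject_id, targets, out, source="interpolated")

    for j, t in enumerate(targets):
        if t <= t_obs[0]:
            # zero-order hold at zero before the first sample (no drug yet)
            out[j] = c_obs[0] if t == t_obs[0] else 0.0
            continue
        if t >= t_obs[-1]:
            if t == t_obs[-1]:
                out[j] = c_obs[-1]
            else:
                ip = np.nonzero(pos)[0]
                if len(ip) >= 2 and c_obs[-1] > 0:
                    i1, i0 = ip[-1], ip[-2]
                    lam = (np.log(c_obs[i0]) - np.log(c_obs[i1])) / (t_obs[i1] - t_obs[i0])
                    out[j] = c_obs[i1] * np.exp(-lam * (t - t_obs[i1]))
                else:
                    out[j] = c_obs[-1]
            continue
        k = int(np.searchsorted(t_obs, t, side="right")) - 1
        t0, t1 = t_obs[k], t_obs[k + 1]
        c0, c1 = c_obs[k], c_obs[k + 1]
        if t == t0:
            out[j] = c0
        elif c0 > 0 and c1 > 0:
            w = (t - t0) / (t1 - t0)
            out[j] = np.exp((1 - w) * np.log(c0) + w * np.log(c1))
        else:  # rise from (or fall to) zero: linear
            out[j] = c0 + (c1 - c0) * (t - t0) / (t1 - t0)
    return ConcProfile(observed.subject_id, targets, np.clip(out, 0.0, None),
                       source="interpolated")


def apply_blq(profile: ConcProfile, lloq_nM: float) -> ConcProfile:
    """Set every concentration below the lower limit of quantification to zero.

    Idempotent; ``lloq_nM = 0`` is the identity.
    """
    if lloq_nM < 0:
        raise ValueError("lloq_nM must be >= 0")
    conc = np.where(profile.conc_nM < lloq_nM, 0.0, profile.conc_nM)
    return ConcProfile(profile.subject_id, profile.times_h.copy(), conc, profile.source)


def _thin_even(idx: np.ndarray, n_keep: int) -> np.ndarray:
    if len(idx) <= n_keep:
        return idx
    pick = np.unique(np.round(np.linspace(0, len(idx) - 1, n_keep)).astype(int))
    return idx[pick]


def balance_phases(df: pd.DataFrame, tmax_h: float, n_per_phase: int) -> pd.DataFrame:
    """Thin continuous telemetry records so absorption, peak and elimination
    phases are equally represented.

    Per subject-occasion, records are partitioned by time since dose into
    absorption (t < 0.8*tmax), peak (0.8*tmax <= t <= 1.5*tmax) and elimination
    (t > 1.5*tmax), keeping at most ``n_per_phase`` records per phase by
    evenly-spaced index thinning.  The rule is purely time-based, so placebo
    occasions are thinned identically.  Deterministic.
    """
    if n_per_phase < 1:
        raise ValueError("n_per_phase must be >= 1")
    lo, hi = 0.8 * tmax_h, 1.5 * tmax_h
    keep: list[np.ndarray] = []
    for _, grp in df.groupby(["ID", "OCC"], sort=False):
        t = grp["TIME"].to_numpy()
        order = np.argsort(t, kind="stable")
        idx = grp.index.to_numpy()[order]
        ts = t[order]
        for mask in (ts < lo, (ts >= lo) & (ts <= hi), ts > hi):
            keep.append(_thin_even(idx[mask], n_per_phase))
    kept = np.concatenate(keep) if keep else np.array([], dtype=int)
    return df.loc[np.sort(kept)].reset_index(drop=True)
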
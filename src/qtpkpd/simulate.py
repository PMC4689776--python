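"""Synthetic study generator.

Generates species-realistic concentration/RR/QT datasets with the statistical
structure the hierarchical QT model assumes: log-normal between-subject
variability on baseline QTc, the RR exponent and the circadian amplitude, a
wrapped-normal circadian phase, a normal concentration-effect slope (so that
negative individual slopes are representable), an additive sex effect on
baseline for females, and additive Gaussian residual error in ms.

RR intervals are generated independently of the QT model (the analysis treats
RR as observed): a circadian cosine around the species resting RR plus
fractional beat-to-beat noise.

Everything is seeded explicitly and the seed plus all generating parameters
are recorded in the dataset meta, so any study is reproducible byte for byte.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import COLUMNS, StudyDataset
from .params import DesignSpec, PKModelSpec, SpeciesParams, StudyPreset
from . import pk as _pk

__all__ = [
    "simulate_individual_params",
    "simulate_rr_series",
    "simulate_qt",
    "generate_study",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_individual_params(pop: SpeciesParams, n: int, seed, sexes=None) -> list[dict]:
    """Draw per-subject parameter sets around the population values.

    ``qtc0``, ``alpha`` and ``amp`` are log-normal with median equal to the
    population value and log-SD equal to the BSV fraction; ``slope`` is normal
    with SD ``|slope| * bsv`` (a credible interval spanning zero stays
    representable); ``phase`` is normal with SD ``phase * bsv`` wrapped onto
    [0, 24).  The sex effect is added to ``qtc0`` for subjects labelled
    ``"F"`` in ``sexes``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if pop.qtc0_ms <= 0:
        raise ValueError("population qtc0 must be positive")
    rng = _as_rng(seed)
    b = pop.bsv
    qtc0 = pop.qtc0_ms * np.exp(rng.normal(0.0, b["qtc0"], n))
    alpha = pop.alpha * np.exp(rng.normal(0.0, b["alpha"], n))
    amp = pop.amp_ms * np.exp(rng.normal(0.0, b["amp"], n))
    phase = np.mod(rng.normal(pop.phase_h, b["phase"] * pop.phase_h, n), 24.0)
    slope = rng.normal(pop.slope_ms_per_nM, abs(pop.slope_ms_per_nM) * b["slope"], n)
    if sexes is not None:
        fem = np.asarray([s == "F" for s in sexes])
        if fem.shape != (n,):
            raise ValueError("sexes must have length n")
        qtc0 = qtc0 + pop.sex_effect_ms * fem
    return [
        dict(qtc0=float(qtc0[i]), alpha=float(alpha[i]), amp=float(amp[i]),
             phase=float(phase[i]), slope=float(slope[i]))
        for i in range(n)
    ]


def simulate_rr_series(design: DesignSpec, times_h, seed) -> np.ndarray:
    """RR interval series (ms) at the given clock times.

    ``rr(t) = rr_baseline * (1 + frac*cos(2*pi*(t - rr_phase)/24)) * (1 + eps)``
    with ``eps ~ N(0, rr_noise_frac)``; draws implying non-positive RR are
    rejected and redrawn (the noise fraction keeps this astronomically rare
    for sensible settings).
    """
    rng = _as_rng(seed)
    t = np.asarray(times_h, dtype=float)
    base = design.rr_baseline_ms * (
        1.0 + design.rr_circadian_frac * np.cos(2 * np.pi * (t - design.rr_phase_h) / 24.0))
    if np.any(base <= 0):
        raise ValueError("circadian fraction implies non-positive RR")
    rr = base * (1.0 + rng.normal(0.0, design.rr_noise_frac, t.shape))
    for _ in range(100):
        bad = rr <= 0
        if not np.any(bad):
            return rr
        rr[bad] = base[bad] * (1.0 + rng.normal(0.0, design.rr_noise_frac, int(bad.sum())))
    raise ValueError("RR noise settings produce non-positive intervals")


def simulate_qt(params: dict, rr_ms, clock_time_h, conc_nM, resid_sd_ms: float, seed) -> np.ndarray:
    """Evaluate the QT model for one subject and add residual noise.

    ``qt = qtc0*(rr/1000)^alpha + amp*cos(2*pi*(t - phase)/24) + slope*conc
    + N(0, resid_sd)``.  RR is normalised to seconds before exponentiation, so
    ``qtc0`` is the QT at RR = 1 s.  With ``resid_sd_ms = 0`` this is an exact
    deterministic evaluation.
    """
    rng = _as_rng(seed)
    rr = np.asarray(rr_ms, dtype=float)
    conc = np.asarray(conc_nM, dtype=float)
    t = np.asarray(clock_time_h, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("rr_ms must be positive")
    if np.any(conc < 0):
        raise ValueError("conc_nM must be non-negative")
    pred = (params["qtc0"] * (rr / 1000.0) ** params["alpha"]
            + params["amp"] * np.cos(2 * np.pi * (t - params["phase"]) / 24.0)
            + params["slope"] * conc)
    if resid_sd_ms == 0:
        return pred
    return pred + rng.normal(0.0, resid_sd_ms, pred.shape)


def _assign_sexes(n: int, sex_ratio: float) -> list[str]:
    n_male = int(round(sex_ratio * n))
    return ["M"] * n_male + ["F"] * (n - n_male)


def _occasions(design: DesignSpec, subject_index: int) -> list[tuple[int, float]]:
    """(occasion, dose_level) pairs for one subject."""
    if design.crossover:
        return [(k + 1, d) for k, d in enumerate(design.dose_levels)]
    n_groups = len(design.dose_levels)
    group = subject_index * n_groups // design.n_subjects
    return [(1, design.dose_levels[group])]


def generate_study(pop: SpeciesParams, pkspec: PKModelSpec, design: DesignSpec,
                   seed, species: str = "sp", compound: str = "drug",
                   lloq_nM: float = 0.0) -> StudyDataset:
    """Generate a complete long-format study dataset.

    Concentrations at ECG times come from the PK layer: compartmental
    prediction for ``onecpt``/``twocpt`` structures, or prediction at the
    sparse PK sampling times followed by log-linear interpolation for
    ``interpolated`` structures (emulating a deconvolution workflow).
    Placebo occasions carry concentration 0.  Deterministic given the seed,
    which is recorded in ``meta`` together with all generating parameters.
    """
    if not list(design.dose_levels):
        raise ValueError("dose_levels must be non-empty")
    rng = _as_rng(seed)
    sexes = _assign_sexes(design.n_subjects, design.sex_ratio)
    subj_params = simulate_individual_params(pop, design.n_subjects, rng, sexes=sexes)
    if design.dose_unit == "mg_per_kg":
        lo, hi = design.weight_range_kg
        weights = rng.uniform(lo, hi, design.n_subjects)
    else:
        weights = np.ones(design.n_subjects)
    cl_ind = pkspec.cl_L_per_h * np.exp(rng.normal(0.0, pkspec.bsv_cl, design.n_subjects))

    ecg_t = np.asarray(design.ecg_sample_times_h, dtype=float)
    rows = []
    for i in range(design.n_subjects):
        sid = f"{species[:1].upper()}{i + 1:03d}"
        for occ, dose_level in _occasions(design, i):
            dose_mg = dose_level * (weights[i] if design.dose_unit == "mg_per_kg" else 1.0)
            if dose_mg == 0:
                conc = np.zeros_like(ecg_t)
            elif pkspec.structure == "interpolated":
                obs = _pk.predict_onecpt(pkspec, dose_mg, design.pk_sample_times_h,
                                         subject_id=sid, cl_L_per_h=cl_ind[i],
                                         dose_level=dose_level)
                conc = _pk.interpolate_profile(obs, ecg_t).conc_nM
            else:
                conc = _pk.predict_profile(pkspec, dose_mg, ecg_t, subject_id=sid,
                                           cl_L_per_h=cl_ind[i],
                                           dose_level=dose_level).conc_nM
            if lloq_nM > 0:
                conc = np.where(conc < lloq_nM, 0.0, conc)
            clock = (design.dose_clock_h + ecg_t) % 24.0
            rr = simulate_rr_series(design, clock, rng)
            qt = simulate_qt(subj_params[i], rr, clock, conc, pop.resid_sd_ms, rng)
            # physiological constraint: redraw residuals where QT >= RR; if the
            # noiseless prediction itself exceeds RR (linear drug effect beyond
            # the refractory ceiling at extreme exposure), truncate at 0.95*RR
            mean_qt = simulate_qt(subj_params[i], rr, clock, conc, 0.0, rng)
            for _ in range(100):
                bad = (qt >= rr) | (qt <= 0)
                if not np.any(bad):
                    break
                nb = int(bad.sum())
                qt[bad] = np.minimum(mean_qt[bad] + rng.normal(0.0, pop.resid_sd_ms, nb),
                                     0.95 * rr[bad])
                qt[bad] = np.maximum(qt[bad], 1.0)
            rows.append(pd.DataFrame({
                "ID": sid, "SPECIES": species, "SEX": sexes[i], "DOSE": dose_level,
                "OCC": occ, "TIME": ecg_t, "CONC": conc, "RR": rr, "QT": qt,
            }))
    df = pd.concat(rows, ignore_index=True)[COLUMNS]
    meta = {
        "seed": seed if not isinstance(seed, np.random.Generator) else "generator",
        "species": species, "compound": compound,
        "dose_clock_h": design.dose_clock_h,
        "species_params": vars(pop).copy(),
        "pk": vars(pkspec).copy(),
        "design": vars(design).copy(),
        "lloq_nM": lloq_nM,
    }
    return StudyDataset(df, meta)


def generate_from_preset(preset: StudyPreset, seed) -> StudyDataset:
    """Generate a study from a shipped species x compound preset."""
    return generate_study(preset.species_params, preset.pk, preset.design, seed,
                          species=preset.species, compound=preset.compound,
                          lloq_nM=preset.lloq_nM)
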
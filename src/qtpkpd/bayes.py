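"""Hierarchical Bayesian estimation of the concentration-QT model.

Model
-----
For record ``j`` of subject ``i``::

    QT_ij ~ Normal( (qtc0_i + sex*female_i) * RR_ij^alpha_i
                    + A_i * cos(2*pi/24 * (t_ij - phi_i))
                    + slope_i * C_ij ,  sigma )

with RR in seconds (so ``qtc0`` is the QT at RR = 1 s), ``t`` the clock time
in hours and ``C`` the plasma concentration in nM.  Random effects follow the
generator's distributions: log-normal on ``qtc0``, ``alpha`` and ``A``
(amplitude constrained positive, which also removes the (A, phi) ->
(-A, phi+12) aliasing), normal on ``phi`` (phase treated on an unwrapped
axis, summarised circularly) and normal on ``slope`` so that individual
slopes may be negative.

Priors are weakly informative and overridable: normal priors on the logs of
positive population parameters, normal(0, 0.1) on the population slope in
ms/nM, half-normal priors on the between-subject SDs and the residual SD.

Sampling
--------
A blocked Metropolis-within-Gibbs sampler: subject-level ``log qtc0``,
``log alpha``, ``log A`` and ``phi`` move by vectorised adaptive random-walk
Metropolis (all subjects in parallel, independent likelihood blocks);
subject slopes, the sex effect and the population means are conjugate normal
Gibbs updates; the half-normal SD parameters move by adaptive Metropolis on
the log scale.  Convergence is assessed by split-chain Gelman-Rubin R-hat and
Geweke z-scores; failure of R-hat < 1.1 flags the fit as non-converged
rather than raising, so pipelines can log and proceed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import StudyDataset

__all__ = [
    "ModelConfig",
    "PosteriorFit",
    "log_likelihood",
    "fit",
    "diagnostics",
    "posterior_summary",
    "gelman_rubin",
    "geweke_z",
]

_W = 2.0 * np.pi / 24.0

POP_PARAMS = ["qtc0", "sex_effect", "alpha", "amp", "phase", "slope",
              "bsv_qtc0", "bsv_alpha", "bsv_amp", "bsv_phase", "bsv_slope", "sigma"]

_DEFAULT_PRIORS = {
    # (location, scale) of normal priors
    "mu_log_qtc0": (math.log(350.0), 1.0),
    "mu_log_alpha": (math.log(0.35), 1.0),
    "mu_log_amp": (math.log(5.0), 1.0),
    "mu_phase": (12.0, 24.0),
    "mu_slope": (0.0, 0.1),
    "sex_effect": (0.0, 10.0),
    # scales of half-normal priors
    "tau_log_qtc0": 0.5,
    "tau_log_alpha": 1.0,
    "tau_log_amp": 1.0,
    "tau_phase": 6.0,
    "tau_slope": 0.05,
    "sigma": 50.0,
}


@dataclass
class ModelConfig:
    """MCMC configuration.  ``period_h`` is fixed at 24 (circadian model)."""

    n_chains: int = 2
    n_warmup: int = 1000
    n_draws: int = 1000
    seed: int = 0
    priors: dict = field(default_factory=dict)
    estimate_sex_effect: str = "auto"  # auto | always | never
    period_h: float = 24.0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (required for Gelman-Rubin)")
        if self.period_h != 24.0:
            raise ValueError("period_h is fixed at 24 h")
        merged = dict(_DEFAULT_PRIORS)
        merged.update(self.priors)
        self.priors = merged


# --------------------------------------------------------------------------- data prep

class _FitData:
    """Dataset unpacked to flat numpy arrays for the sampler."""

    def __init__(self, ds: StudyDataset):
        df = ds.df
        if df["CONC"].isna().any():
            bad = df.index[df["CONC"].isna()].tolist()[:5]
            raise ValueError(
                f"concentration missing at QT times (record rows {bad}); "
                "impute or interpolate concentrations before fitting")
        ids = df["ID"].to_numpy()
        self.subject_ids = list(pd.unique(ids))
        if len(self.subject_ids) < 2:
            raise ValueError("fit requires >= 2 subjects")
        index = {s: k for k, s in enumerate(self.subject_ids)}
        self.g = np.array([index[s] for s in ids])          # record -> subject
        self.S = len(self.subject_ids)
        self.y = df["QT"].to_numpy(float)
        self.conc = df["CONC"].to_numpy(float)
        self.logrr = np.log(df["RR"].to_numpy(float) / 1000.0)
        clock = ds.clock_time_h()
        self.ca = np.cos(_W * clock)
        self.sa = np.sin(_W * clock)
        self.N = len(self.y)
        sex = df.groupby("ID", sort=False)["SEX"].first()
        self.fem = np.array([1.0 if sex[s] == "F" else 0.0 for s in self.subject_ids])
        self.both_sexes = 0 < self.fem.sum() < self.S
        self.sxx = np.bincount(self.g, weights=self.conc ** 2, minlength=self.S)
        self.counts = np.bincount(self.g, minlength=self.S).astype(float)
        # per-subject mean log RR(s): direction of the qtc0-alpha likelihood
        # ridge (QT ~ qtc0 * RR^alpha is flat along dlog qtc0 = -mean(logRR) dalpha)
        self.mean_logrr = (np.bincount(self.g, weights=self.logrr, minlength=self.S)
                           / self.counts)


def _predict(d: _FitData, lq, la, lA, ph, s, sex_eff):
    alpha = np.exp(la)[d.g]
    qtc0 = (np.exp(lq) + sex_eff * d.fem)[d.g]
    circ = np.exp(lA)[d.g] * (d.ca * np.cos(_W * ph)[d.g] + d.sa * np.sin(_W * ph)[d.g])
    return qtc0 * np.exp(alpha * d.logrr) + circ + s[d.g] * d.conc


def log_likelihood(params: dict, ds: StudyDataset) -> float:
    """Gaussian log-likelihood of a dataset under given subject-level parameters.

    ``params`` holds ``"subjects"`` (mapping subject ID -> dict with keys
    ``qtc0, alpha, amp, phase, slope``) and ``"resid_sd_ms"``.  The sum runs
    over records of the normal log-density of observed QT around the model
    prediction; invariant to record order.
    """
    df = ds.df
    if df["CONC"].isna().any():
        rows = df.index[df["CONC"].isna()].tolist()[:5]
        raise ValueError(f"concentration missing at QT times (record rows {rows})")
    sigma = float(params["resid_sd_ms"])
    if sigma <= 0:
        raise ValueError("resid_sd_ms must be positive")
    subjects = params["subjects"]
    total = 0.0
    clock_all = ds.clock_time_h()
    for sid, grp in df.groupby("ID", sort=False):
        p = subjects[sid]
        clock = clock_all[grp.index.to_numpy()]
        pred = (p["qtc0"] * (grp["RR"].to_numpy(float) / 1000.0) ** p["alpha"]
                + p["amp"] * np.cos(_W * (clock - p["phase"]))
                + p["slope"] * grp["CONC"].to_numpy(float))
        r = grp["QT"].to_numpy(float) - pred
        total += float(-0.5 * np.sum(r ** 2) / sigma ** 2
                       - len(r) * math.log(sigma * math.sqrt(2.0 * math.pi)))
    return total


# --------------------------------------------------------------------------- sampler

def _init_state(d: _FitData, priors: dict, rng: np.random.Generator):
    """Data-driven starting values (least squares on a fixed alpha grid)."""
    alpha0 = 0.3
    base_mask = d.conc <= 0
    if not np.any(base_mask):
        base_mask = np.ones(d.N, bool)
    rr_pow = np.exp(alpha0 * d.logrr)
    qtc0_0 = float(np.median(d.y[base_mask] / rr_pow[base_mask]))
    r = d.y - qtc0_0 * rr_pow
    slope0 = 0.0
    if np.any(d.conc > 0):
        slope0 = float(np.sum(d.conc * r) / np.sum(d.conc ** 2))
        r = r - slope0 * d.conc
    X = np.column_stack([d.ca, d.sa])
    coef, *_ = np.linalg.lstsq(X, r, rcond=None)
    A0 = max(float(np.hypot(*coef)), 0.5)
    ph0 = float(np.arctan2(coef[1], coef[0]) / _W % 24.0)
    resid = r - X @ coef
    sigma0 = max(float(np.std(resid)), 1.0)

    jit = lambda sd, size=d.S: rng.normal(0.0, sd, size)
    state = {
        "lq": np.log(max(qtc0_0, 50.0)) + jit(0.05),
        "la": np.log(alpha0) + jit(0.1),
        "lA": np.log(A0) + jit(0.1),
        "ph": ph0 + jit(0.5),
        "s": slope0 * (1.0 + jit(0.1)) + jit(0.05 * abs(slope0) + 1e-5),
        "sex_eff": 0.0,
        "sigma": sigma0,
    }
    state["mu"] = {
        "lq": float(np.mean(state["lq"])), "la": float(np.mean(state["la"])),
        "lA": float(np.mean(state["lA"])), "ph": float(np.mean(state["ph"])),
        "s": float(np.mean(state["s"])),
    }
    state["tau"] = {"lq": 0.1, "la": 0.3, "lA": 0.2, "ph": 1.0,
                    "s": max(0.3 * abs(slope0), 1e-4)}
    return state


def _half_normal_logpdf(x: float, scale: float) -> float:
    return -0.5 * (x / scale) ** 2


def _run_chain(d: _FitData, cfg: ModelConfig, seed: int, estimate_sex: bool):
    rng = np.random.default_rng(seed)
    pri = cfg.priors
    st = _init_state(d, pri, rng)
    lq, la, lA, ph, s = (st[k] for k in ("lq", "la", "lA", "ph", "s"))
    mu, tau = st["mu"], st["tau"]
    sex_eff, sigma = st["sex_eff"], st["sigma"]

    mh_blocks = ["lq", "la", "lA", "ph"]
    prior_mu_key = {"lq": "mu_log_qtc0", "la": "mu_log_alpha",
                    "lA": "mu_log_amp", "ph": "mu_phase", "s": "mu_slope"}
    tau_prior_key = {"lq": "tau_log_qtc0", "la": "tau_log_alpha",
                     "lA": "tau_log_amp", "ph": "tau_phase", "s": "tau_slope"}
    steps = {k: np.full(d.S, 0.05 if k != "ph" else 0.3) for k in mh_blocks}
    steps_scalar = {k: 0.3 for k in ("tau_lq", "tau_la", "tau_lA", "tau_ph", "tau_s", "sigma")}
    steps_nc = {f"nc_tau_{k}": 0.3 for k in ("lq", "la", "lA", "ph", "s")}
    steps_nc.update({f"shift_{k}": v for k, v in
                     (("lq", 0.02), ("la", 0.05), ("lA", 0.1), ("ph", 0.5),
                      ("s", 1e-4))})
    steps_nc["sex_swap"] = 2.0
    steps_nc["ridge_pop"] = 0.05
    steps_ridge = np.full(d.S, 0.1)

    params = {"lq": lq, "la": la, "lA": lA, "ph": ph}
    pred = _predict(d, lq, la, lA, ph, s, sex_eff)
    sse_subj = np.bincount(d.g, weights=(d.y - pred) ** 2, minlength=d.S)

    n_total = cfg.n_warmup + cfg.n_draws
    pop_store = {k: np.empty(cfg.n_draws) for k in POP_PARAMS}
    subj_store = np.empty((cfg.n_draws, d.S, 5), dtype=np.float32)

    err = np.errstate(over="ignore", invalid="ignore")
    err.__enter__()
    for it in range(n_total):
        adapt = it < cfg.n_warmup
        gamma = min(0.05, 2.0 / math.sqrt(it + 1.0)) if adapt else 0.0

        # --- vectorised MH on subject-level blocks
        for key in mh_blocks:
            cur = params[key]
            prop = cur + steps[key] * rng.normal(0.0, 1.0, d.S)
            trial = dict(params)
            trial[key] = prop
            pred_new = _predict(d, trial["lq"], trial["la"], trial["lA"], trial["ph"], s, sex_eff)
            sse_new = np.bincount(d.g, weights=(d.y - pred_new) ** 2, minlength=d.S)
            dprior = (-(prop - mu[key]) ** 2 + (cur - mu[key]) ** 2) / (2.0 * tau[key] ** 2)
            dlog = (sse_subj - sse_new) / (2.0 * sigma ** 2) + dprior
            accept = np.log(rng.uniform(size=d.S)) < dlog
            cur[accept] = prop[accept]
            acc_rec = accept[d.g]
            pred = np.where(acc_rec, pred_new, pred)
            sse_subj = np.where(accept, sse_new, sse_subj)
            if adapt:
                steps[key] = np.exp(np.log(steps[key]) + gamma * (accept - 0.44))

        lq, la, lA, ph = params["lq"], params["la"], params["lA"], params["ph"]

        # --- ridge move: joint (alpha, qtc0) proposal along the flat
        # direction of QT ~ qtc0 * RR^alpha (shear, unit Jacobian), per subject
        dz = steps_ridge * rng.normal(0.0, 1.0, d.S)
        prop_la = la + dz
        prop_lq = lq - (np.exp(prop_la) - np.exp(la)) * d.mean_logrr
        pred_new = _predict(d, prop_lq, prop_la, lA, ph, s, sex_eff)
        sse_new = np.bincount(d.g, weights=(d.y - pred_new) ** 2, minlength=d.S)
        dprior = ((-(prop_la - mu["la"]) ** 2 + (la - mu["la"]) ** 2) / (2.0 * tau["la"] ** 2)
                  + (-(prop_lq - mu["lq"]) ** 2 + (lq - mu["lq"]) ** 2) / (2.0 * tau["lq"] ** 2))
        dlog = (sse_subj - sse_new) / (2.0 * sigma ** 2) + dprior
        accept = np.log(rng.uniform(size=d.S)) < dlog
        la[accept] = prop_la[accept]
        lq[accept] = prop_lq[accept]
        pred = np.where(accept[d.g], pred_new, pred)
        sse_subj = np.where(accept, sse_new, sse_subj)
        if adapt:
            steps_ridge = np.exp(np.log(steps_ridge) + gamma * (accept - 0.44))

        # --- population ridge move: shift every subject's alpha coherently and
        # compensate baselines (and both population means) along the ridge
        delta = steps_nc["ridge_pop"] * rng.normal()
        prop_la = la + delta
        dlq = -(np.exp(prop_la) - np.exp(la)) * d.mean_logrr
        prop_lq = lq + dlq
        pred_new = _predict(d, prop_lq, prop_la, lA, ph, s, sex_eff)
        sse_new_total = float(np.sum((d.y - pred_new) ** 2))
        mu_la_new = mu["la"] + delta
        mu_lq_new = mu["lq"] + float(np.mean(dlq))
        m0a, s0a = pri[prior_mu_key["la"]]
        m0q, s0q = pri[prior_mu_key["lq"]]
        dlog = ((float(np.sum(sse_subj)) - sse_new_total) / (2.0 * sigma ** 2)
                + (-(mu_la_new - m0a) ** 2 + (mu["la"] - m0a) ** 2) / (2.0 * s0a ** 2)
                + (-(mu_lq_new - m0q) ** 2 + (mu["lq"] - m0q) ** 2) / (2.0 * s0q ** 2)
                + (float(np.sum(-(prop_lq - mu_lq_new) ** 2 + (lq - mu["lq"]) ** 2))
                   / (2.0 * tau["lq"] ** 2)))
        ok = math.log(rng.uniform()) < dlog
        if ok:
            la[:] = prop_la
            lq[:] = prop_lq
            mu["la"], mu["lq"] = mu_la_new, mu_lq_new
            pred = pred_new
            sse_subj = np.bincount(d.g, weights=(d.y - pred) ** 2, minlength=d.S)
        if adapt:
            steps_nc["ridge_pop"] = math.exp(
                math.log(steps_nc["ridge_pop"]) + gamma * (float(ok) - 0.44))

        # --- conjugate Gibbs: subject slopes
        pred_wo = pred - s[d.g] * d.conc
        r = d.y - pred_wo
        sxy = np.bincount(d.g, weights=d.conc * r, minlength=d.S)
        var = 1.0 / (d.sxx / sigma ** 2 + 1.0 / tau["s"] ** 2)
        mean = var * (sxy / sigma ** 2 + mu["s"] / tau["s"] ** 2)
        s = mean + np.sqrt(var) * rng.normal(0.0, 1.0, d.S)
        pred = pred_wo + s[d.g] * d.conc
        sse_subj = np.bincount(d.g, weights=(d.y - pred) ** 2, minlength=d.S)

        # --- conjugate Gibbs: sex effect (additive on baseline, females)
        if estimate_sex:
            x = d.fem[d.g] * np.exp(np.exp(la)[d.g] * d.logrr)
            r = d.y - (pred - sex_eff * x)
            sxx = float(np.sum(x * x))
            m0, s0 = pri["sex_effect"]
            var1 = 1.0 / (sxx / sigma ** 2 + 1.0 / s0 ** 2)
            mean1 = var1 * (float(np.sum(x * r)) / sigma ** 2 + m0 / s0 ** 2)
            sex_new = mean1 + math.sqrt(var1) * rng.normal()
            pred = pred + (sex_new - sex_eff) * x
            sex_eff = sex_new
            sse_subj = np.bincount(d.g, weights=(d.y - pred) ** 2, minlength=d.S)

        # --- conjugate Gibbs: population means
        for key, vals in (("lq", lq), ("la", la), ("lA", lA), ("ph", ph), ("s", s)):
            m0, s0 = pri[prior_mu_key[key]]
            var1 = 1.0 / (d.S / tau[key] ** 2 + 1.0 / s0 ** 2)
            mean1 = var1 * (float(np.sum(vals)) / tau[key] ** 2 + m0 / s0 ** 2)
            mu[key] = mean1 + math.sqrt(var1) * rng.normal()

        # --- MH on log scale: between-subject SDs (half-normal priors)
        for key, vals in (("lq", lq), ("la", la), ("lA", lA), ("ph", ph), ("s", s)):
            skey = f"tau_{key}"
            cur = tau[key]
            prop = cur * math.exp(steps_scalar[skey] * rng.normal())
            ss = float(np.sum((vals - mu[key]) ** 2))
            scale = pri[tau_prior_key[key]]

            def logp(t):
                return (-d.S * math.log(t) - ss / (2.0 * t ** 2)
                        + _half_normal_logpdf(t, scale) + math.log(t))

            ok = math.log(rng.uniform()) < logp(prop) - logp(cur)
            if ok:
                tau[key] = prop
            if adapt:
                steps_scalar[skey] = math.exp(
                    math.log(steps_scalar[skey]) + gamma * (float(ok) - 0.44))

        # --- interweaving (non-centred) step for each random-effect SD:
        # holding eta_i = (theta_i - mu)/tau fixed, a change of tau rescales
        # every subject effect, which breaks the centred-parameterisation
        # funnel between tau and the subject effects
        for key in ("lq", "la", "lA", "ph", "s"):
            skey = f"nc_tau_{key}"
            step = steps_nc[skey]
            cur_t = tau[key]
            prop_t = cur_t * math.exp(step * rng.normal())
            vals = params[key] if key in params else s
            eta = (vals - mu[key]) / cur_t
            vals_new = mu[key] + eta * prop_t
            if key == "s":
                pred_new = _predict(d, lq, la, lA, ph, vals_new, sex_eff)
            else:
                trial = dict(params)
                trial[key] = vals_new
                pred_new = _predict(d, trial["lq"], trial["la"], trial["lA"],
                                    trial["ph"], s, sex_eff)
            sse_new_total = float(np.sum((d.y - pred_new) ** 2))
            sse_total = float(np.sum(sse_subj))
            scale = pri[tau_prior_key[key]]
            dlog = ((sse_total - sse_new_total) / (2.0 * sigma ** 2)
                    + _half_normal_logpdf(prop_t, scale) - _half_normal_logpdf(cur_t, scale)
                    + math.log(prop_t) - math.log(cur_t))
            ok = math.log(rng.uniform()) < dlog
            if ok:
                tau[key] = prop_t
                if key == "s":
                    s = vals_new
                else:
                    params[key][:] = vals_new
                    lq, la, lA, ph = params["lq"], params["la"], params["lA"], params["ph"]
                pred = pred_new
                sse_subj = np.bincount(d.g, weights=(d.y - pred) ** 2, minlength=d.S)
            if adapt:
                steps_nc[skey] = math.exp(math.log(steps_nc[skey]) + gamma * (float(ok) - 0.44))

        # --- coherent location shifts: move mu and all subject effects by the
        # same delta (prior on the effects is translation-invariant, so only
        # the likelihood and the mu hyperprior change); keeps the population
        # location mixing even when subject effects are individually sticky
        for key in ("lq", "la", "lA", "ph", "s"):
            skey = f"shift_{key}"
            delta = steps_nc[skey] * rng.normal()
            vals = params[key] if key in params else s
            vals_new = vals + delta
            if key == "s":
                pred_new = _predict(d, lq, la, lA, ph, vals_new, sex_eff)
            else:
                trial = dict(params)
                trial[key] = vals_new
                pred_new = _predict(d, trial["lq"], trial["la"], trial["lA"],
                                    trial["ph"], s, sex_eff)
            sse_new_total = float(np.sum((d.y - pred_new) ** 2))
            sse_total = float(np.sum(sse_subj))
            m0, s0 = pri[prior_mu_key[key]]
            mu_new = mu[key] + delta
            dlog = ((sse_total - sse_new_total) / (2.0 * sigma ** 2)
                    + (-(mu_new - m0) ** 2 + (mu[key] - m0) ** 2) / (2.0 * s0 ** 2))
            ok = math.log(rng.uniform()) < dlog
            if ok:
                mu[key] = mu_new
                if key == "s":
                    s = vals_new
                else:
                    params[key][:] = vals_new
                    lq, la, lA, ph = params["lq"], params["la"], params["lA"], params["ph"]
                pred = pred_new
                sse_subj = np.bincount(d.g, weights=(d.y - pred) ** 2, minlength=d.S)
            if adapt:
                steps_nc[skey] = math.exp(math.log(steps_nc[skey]) + gamma * (float(ok) - 0.44))

        # --- phase wrap move: the model is periodic in 24 h, so (mu_ph,
        # {ph_i}) and (mu_ph +/- 24, {ph_i +/- 24}) are equivalent modes; an
        # MH jump between them (likelihood-invariant, only the mu hyperprior
        # differs) merges the unwrapped-axis copies so chains agree
        shift24 = 24.0 if rng.uniform() < 0.5 else -24.0
        m0, s0 = pri[prior_mu_key["ph"]]
        mu_new = mu["ph"] + shift24
        dlog = (-(mu_new - m0) ** 2 + (mu["ph"] - m0) ** 2) / (2.0 * s0 ** 2)
        if math.log(rng.uniform()) < dlog:
            mu["ph"] = mu_new
            ph += shift24
            params["ph"] = ph

        # --- likelihood-invariant swap between the sex effect and female
        # baselines: sex_eff -> sex_eff + delta with female qtc0_i held fixed
        if estimate_sex and d.fem.sum() > 0:
            delta = steps_nc["sex_swap"] * rng.normal()
            femidx = d.fem > 0
            q_fem = np.exp(lq[femidx])
            if np.all(q_fem - delta > 1.0):
                lq_new = np.log(q_fem - delta)
                m0, s0 = pri["sex_effect"]
                sex_new = sex_eff + delta
                dlog = (np.sum(-(lq_new - mu["lq"]) ** 2 + (lq[femidx] - mu["lq"]) ** 2)
                        / (2.0 * tau["lq"] ** 2)
                        + (-(sex_new - m0) ** 2 + (sex_eff - m0) ** 2) / (2.0 * s0 ** 2)
                        + float(np.sum(lq[femidx] - lq_new)))  # Jacobian
                ok = math.log(rng.uniform()) < dlog
                if ok:
                    lq[femidx] = lq_new
                    sex_eff = sex_new
                if adapt:
                    steps_nc["sex_swap"] = math.exp(
                        math.log(steps_nc["sex_swap"]) + gamma * (float(ok) - 0.44))

        # --- MH on log scale: residual SD (half-normal prior)
        sse = float(np.sum(sse_subj))
        cur = sigma
        prop = cur * math.exp(steps_scalar["sigma"] * rng.normal())

        def logp_sig(t):
            return (-d.N * math.log(t) - sse / (2.0 * t ** 2)
                    + _half_normal_logpdf(t, pri["sigma"]) + math.log(t))

        ok = math.log(rng.uniform()) < logp_sig(prop) - logp_sig(cur)
        if ok:
            sigma = prop
        if adapt:
            steps_scalar["sigma"] = math.exp(
                math.log(steps_scalar["sigma"]) + gamma * (float(ok) - 0.44))

        # --- store post-warmup draws (natural scale)
        if not adapt:
            k = it - cfg.n_warmup
            pop_store["qtc0"][k] = math.exp(mu["lq"])
            pop_store["sex_effect"][k] = sex_eff
            pop_store["alpha"][k] = math.exp(mu["la"])
            pop_store["amp"][k] = math.exp(mu["lA"])
            pop_store["phase"][k] = mu["ph"]
            pop_store["slope"][k] = mu["s"]
            pop_store["bsv_qtc0"][k] = tau["lq"]
            pop_store["bsv_alpha"][k] = tau["la"]
            pop_store["bsv_amp"][k] = tau["lA"]
            pop_store["bsv_phase"][k] = tau["ph"]
            pop_store["bsv_slope"][k] = tau["s"]
            pop_store["sigma"][k] = sigma
            subj_store[k, :, 0] = np.exp(lq) + sex_eff * d.fem
            subj_store[k, :, 1] = np.exp(la)
            subj_store[k, :, 2] = np.exp(lA)
            subj_store[k, :, 3] = ph
            subj_store[k, :, 4] = s

    err.__exit__(None, None, None)
    return pop_store, subj_store


@dataclass
class PosteriorFit:
    """MCMC output: per-chain draws, summaries, diagnostics and provenance.

    ``pop_draws[name]`` has shape ``(n_chains, n_draws)``; ``subject_draws``
    has shape ``(n_chains, n_draws, n_subjects, 5)`` with the last axis
    ordered ``(qtc0, alpha, amp, phase, slope)``.  All summaries are
    recomputable from the stored draws.
    """

    pop_draws: dict
    subject_draws: np.ndarray
    subject_ids: list
    converged: bool
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.pop_draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.pop_draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated for one population parameter."""
        return self.pop_draws[name].reshape(-1)

    def slope_draws(self) -> np.ndarray:
        return self.pooled("slope")

    # ------------------------------------------------------------------ export
    def draws_to_csv(self, path) -> None:
        """One column per population parameter, one row per draw, chain column."""
        cols = {"chain": np.repeat(np.arange(self.n_chains), self.n_draws)}
        cols.update({k: v.reshape(-1) for k, v in self.pop_draws.items()})
        pd.DataFrame(cols).to_csv(path, index=False)


def fit(ds: StudyDataset, cfg: ModelConfig | None = None) -> PosteriorFit:
    """Fit the hierarchical QT model by MCMC.

    Returns draws from the joint posterior of the population parameters,
    between-subject SDs, residual SD and subject-level parameters.
    Reproducible given ``cfg.seed``.  If the Gelman-Rubin R-hat of any
    population parameter is >= 1.1 the fit is returned flagged
    ``converged=False`` (a warning, not an exception).
    """
    cfg = cfg or ModelConfig()
    d = _FitData(ds)
    estimate_sex = {"always": True, "never": False}.get(
        cfg.estimate_sex_effect, d.both_sexes)
    chains = []
    for c in range(cfg.n_chains):
        chains.append(_run_chain(d, cfg, int(cfg.seed) * 1009 + 7919 * c + 1, estimate_sex))
    pop = {k: np.stack([ch[0][k] for ch in chains]) for k in POP_PARAMS}
    subj = np.stack([ch[1] for ch in chains])
    fitted = PosteriorFit(
        pop_draws=pop, subject_draws=subj, subject_ids=d.subject_ids,
        converged=True,
        meta={"config": vars(cfg).copy(), "dataset_meta": dict(ds.meta),
              "n_records": d.N, "estimate_sex_effect": estimate_sex},
    )
    diag = diagnostics(fitted)
    fitted.converged = bool(diag["rhat"].lt(1.1).all())
    return fitted


# --------------------------------------------------------------------------- diagnostics

def gelman_rubin(chains: np.ndarray, split: bool = False) -> float:
    """Gelman-Rubin R-hat: sqrt(((n-1)/n * W + B/n) / W) with B the between-
    and W the within-chain variance.

    With ``split=True`` each chain is first split in half (split-R-hat, the
    form used by :func:`diagnostics`, sensitive to within-chain drift).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("gelman_rubin requires >= 2 chains of draws")
    if split:
        half = x.shape[1] // 2
        x = np.concatenate([x[:, :half], x[:, x.shape[1] - half:]], axis=0)
    n = x.shape[1]
    w = float(np.mean(np.var(x, axis=1, ddof=1)))
    b = n * float(np.var(np.mean(x, axis=1), ddof=1))
    if w == 0:
        return 1.0
    return math.sqrt((b / w + n - 1) / n)


def _spectral_density_0(x: np.ndarray) -> float:
    """Spectral density at frequency zero via Bartlett-windowed autocovariance."""
    n = len(x)
    xc = x - x.mean()
    lags = int(math.sqrt(n))
    acov = np.correlate(xc, xc, mode="full")[n - 1: n + lags] / n
    weights = 1.0 - np.arange(1, lags + 1) / (lags + 1.0)
    return float(acov[0] + 2.0 * np.sum(weights * acov[1:]))


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score for one chain.

    Compares the mean of the first ``first`` fraction of draws with the mean
    of the last ``last`` fraction, with variances from spectral density
    estimates at frequency zero.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    a, b = x[: int(first * n)], x[int((1.0 - last) * n):]
    var = _spectral_density_0(a) / len(a) + _spectral_density_0(b) / len(b)
    if var <= 0:
        return 0.0
    return float((a.mean() - b.mean()) / math.sqrt(var))


def diagnostics(fit_: PosteriorFit) -> pd.DataFrame:
    """Gelman-Rubin R-hat and Geweke z per population parameter.

    Geweke is computed per chain; the largest |z| is reported.  Pass flags
    are ``rhat < 1.1`` and ``|z| < 2``.
    """
    if fit_.n_chains < 2:
        raise ValueError("diagnostics require >= 2 chains")
    rows = []
    for name, draws in fit_.pop_draws.items():
        if name == "phase":
            # phase is circular: diagnose on circularly centred draws so
            # equivalent modes 24 h apart do not masquerade as non-convergence
            center = _circular_center(np.mod(draws.reshape(-1), 24.0))
            draws = np.mod(draws - center + 12.0, 24.0) - 12.0
        if np.allclose(draws, draws.reshape(-1)[0]):
            rhat, z = 1.0, 0.0  # constant parameter (e.g. sex effect fixed at 0)
        else:
            rhat = gelman_rubin(draws, split=True)
            z = max((geweke_z(c) for c in draws), key=abs)
        rows.append({"parameter": name, "rhat": rhat, "geweke_z": z,
                     "pass": (rhat < 1.1) and (abs(z) < 2.0)})
    return pd.DataFrame(rows).set_index("parameter")


# --------------------------------------------------------------------------- summaries

def _circular_center(draws: np.ndarray, period: float = 24.0) -> float:
    ang = draws * 2.0 * np.pi / period
    return float(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) * period / (2.0 * np.pi))


def _ci(draws: np.ndarray):
    return (float(np.median(draws)),
            float(np.quantile(draws, 0.025)), float(np.quantile(draws, 0.975)))


def posterior_summary(fit_: PosteriorFit) -> pd.DataFrame:
    """Median and central 95% credible interval per population parameter.

    Conventions mirror the usual reporting table: baseline/amplitude/residual
    in ms, slope in ms/nM, between-subject variability as percent
    (100 x the log-SD for log-normal parameters; 100 x SD / |median| for
    phase and slope, with the phase median wrapped to (0, 24]); the phase
    itself is summarised circularly on [0, 24).
    """
    rows = []
    phase_pool = fit_.pooled("phase")
    center = _circular_center(np.mod(phase_pool, 24.0))
    centered = np.mod(phase_pool - center + 12.0, 24.0) - 12.0
    med_c, lo_c, hi_c = _ci(centered)
    phase_med = (center + med_c) % 24.0
    phase_for_pct = phase_med if phase_med > 0 else 24.0
    slope_med = float(np.median(fit_.pooled("slope")))

    for name in POP_PARAMS:
        draws = fit_.pooled(name)
        if name == "phase":
            med, lo, hi = phase_med, (center + lo_c) % 24.0, (center + hi_c) % 24.0
            unit = "h"
        elif name in ("bsv_qtc0", "bsv_alpha", "bsv_amp"):
            med, lo, hi = (100.0 * v for v in _ci(draws))
            unit = "%"
        elif name == "bsv_phase":
            med, lo, hi = (100.0 * v / phase_for_pct for v in _ci(draws))
            unit = "%"
        elif name == "bsv_slope":
            denom = max(abs(slope_med), 1e-12)
            med, lo, hi = (100.0 * v / denom for v in _ci(draws))
            unit = "%"
        else:
            med, lo, hi = _ci(draws)
            unit = {"slope": "ms/nM"}.get(name, "ms")
            if name == "alpha":
                unit = ""
        rows.append({"parameter": name, "median": med, "ci_low": lo, "ci_high": hi,
                     "unit": unit})
    return pd.DataFrame(rows).set_index("parameter")
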
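# Methods

## Model

The concentration-QT model treats each observed QT interval as the sum of an
individually heart-rate-corrected baseline, a circadian oscillation and a
linear drug effect:

```
QT_ij ~ Normal( (QTc0_i + sex·female_i) · RR_ij^alpha_i
                + A_i · cos(2π/24 · (t_ij − phi_i))
                + slope_i · C_ij ,  sigma )
```

with RR in **seconds**, so `QTc0` is the QT interval at RR = 1 s (60 bpm).
This normalisation is deliberate: baseline estimates of 240–400 ms across
species match QT at 60 bpm, whereas exponentiating RR in milliseconds with
alpha ≈ 0.3–0.5 would produce meaningless magnitudes.  Clock time `t` enters
the circadian term; study time (hours since dosing) is what datasets store,
and the two are related by the dosing clock time recorded in the dataset
metadata (default 08:00).  The model's assumptions: residual error is
additive Gaussian and homoscedastic; the drug effect is linear in
concentration with no delay (no effect compartment, no tolerance); RR is
observed, not modelled; the circadian period is fixed at 24 h.

The linear effect term is a low-dose approximation — it reads the lower
ascending limb of a saturating concentration-effect curve.  At extreme
exposure it can predict QT beyond the physiological ceiling (QT cannot
exceed RR); see the generator notes below.

### Random effects

| parameter | distribution across subjects | rationale |
|---|---|---|
| QTc0, alpha, A | log-normal (median = population value, log-SD = BSV fraction) | strictly positive; A > 0 also removes the (A, phi) → (−A, phi+12) aliasing |
| phi | normal, treated circularly (wrapped mod 24 in the generator; sampled on an unwrapped axis with a mode-merging ±24 h move and summarised circularly) | phase is a circular quantity |
| slope | normal (SD = BSV fraction × |population slope|) | a slope credible interval can span zero, so individual slopes must be allowed to be negative; a log-normal could not represent this |

The additive sex effect on baseline is estimated only when both sexes are
present in the data, otherwise fixed at 0.

### Priors (defaults, all overridable via `ModelConfig.priors`)

* normal priors on the logs of positive population parameters, centred at
  species-plausible values with SD 1 (log QTc0 at log 350 ms, log alpha at
  log 0.35, log A at log 5 ms) — weak on the scale of the likelihood;
* population slope: Normal(0, 0.1) ms/nM — 0.1 ms/nM is ~25× the largest
  slope reported for these compounds, so the prior is uninformative where
  there is concentration signal and keeps placebo-only fits proper;
* phase location: Normal(12 h, 24 h), effectively flat over a cycle;
* half-normal priors on all between-subject SDs (scales 0.5–1 on log
  parameters, 6 h on phase, 0.05 ms/nM on slope) and on the residual SD
  (scale 50 ms).

The original analysis was run in a Gibbs-sampling framework whose priors and
initial values were not reported; these defaults are this package's own
documented choice, and equivalence with any other sampler is at the level of
the posterior, not the algorithm.

### Sampler

A blocked Metropolis-within-Gibbs scheme, chosen because every conditional
this model needs is either conjugate or a cheap low-dimensional update:

* subject-level `log QTc0`, `log alpha`, `log A`, `phi`: vectorised adaptive
  random-walk Metropolis (all subjects updated in parallel — their
  likelihood contributions are independent);
* subject slopes, the sex effect and all five population means: conjugate
  normal Gibbs updates;
* between-subject SDs and the residual SD: adaptive Metropolis on the log
  scale under the half-normal priors;
* three non-trivial mixing moves, each a valid Metropolis proposal:
  1. an interweaving (non-centred) update of each between-subject SD that
     rescales all subject effects around their mean, breaking the
     centred-parameterisation funnel;
  2. a ridge move updating (alpha_i, QTc0_i) jointly along the flat
     direction of `QTc0·RR^alpha` (at species RR far from 1 s the two are
     strongly correlated; dogs and monkeys need this), plus a population-level
     version shifting all subjects coherently;
  3. a likelihood-invariant swap between the sex effect and the female
     baselines, and a ±24 h phase translation that merges the periodic
     copies of the phase mode.

Step sizes adapt toward 0.44 acceptance during warmup only.  Defaults are
2 chains × 1000 warmup + 1000 kept draws — on the shipped study sizes
(240–720 records, 6–24 subjects) a fit takes a few seconds and replicate
recovery experiments are practical.  Initial values are data-driven (median
baseline, least-squares circadian and slope) with per-chain jitter.

### Diagnostics

Split-chain Gelman-Rubin R-hat and Geweke z-scores (first 10% vs last 50%,
spectral variance at frequency zero via Bartlett-windowed autocovariances)
per population parameter; phase is diagnosed on circularly centred draws.
R-hat >= 1.1 on any population parameter flags the fit `converged=False` —
a flag rather than an exception, so pipelines can log and proceed.  Two
further classical diagnostics sometimes quoted alongside these
(Raftery-Lewis, Heidelberger-Welch) are out of scope.

### Summaries

Posterior medians and central 95% intervals use linear-interpolation
quantiles (draws 1..1000 give the interval (25.975, 975.025)).
Between-subject variability is reported as percent: 100 × log-SD for the
log-normal parameters (≈ CV%), and 100 × SD / |median| for phase and slope,
with the phase median wrapped to (0, 24].  Phase itself is summarised with a
circular mean/quantile construction on [0, 24).

## Risk layer

`P(C) = P(slope·C >= threshold)` is the fraction of posterior slope draws at
or above `threshold/C` (threshold default 10 ms, the conventional
regulatory concern level).  Cp50 is located by bracketing the 0.5 crossing
on a log-spaced concentration grid (200 points spanning
`threshold/q99.9(slope)` to `threshold/q0.1(slope)`) and refining by
bisection, so it is exact even for degenerate (point-mass) posteriors.  The
safety margin divides Cp50 by a caller-supplied reference Cmax; the report
layer defaults to the *human* Cmax for every species, because that is the
exposure scale on which preclinical-to-clinical translation is judged (the
published margins are only reproducible under this convention).
`normal_approx_draws` converts a published median and 95% interval into
`Normal(median, width/3.92)` draws so the risk layer can run from summary
tables without refitting; this symmetric approximation is accurate for
near-symmetric intervals and degrades for strongly skewed ones (the dog
slope interval is the canonical example — its exceedance probability at
Cmax comes out ≈0.91 rather than ≈1).

A published closed-form expression for this probability (a step function
with a small-constant gender factor) is not evaluable as a probability as
printed; this package implements the quantity it is described as producing —
the posterior exceedance probability — which self-consistently reproduces
the published Cp50 ≈ 10/slope and probability-at-Cmax values.  Sex-specific
curves are produced by filtering draws, not by the opaque gender factor.

## Synthetic data generator

The generator emulates the published experimental designs:

| study | design | ECG times | PK handling |
|---|---|---|---|
| dog, moxifloxacin | 8 M, 4-way crossover 0/3/10/30 mg/kg | continuous telemetry, emulated as 15-min averages over 24 h, then phase-balanced (5 records per absorption/peak/elimination phase) | closed-form 1-compartment (Ka 1.78 /h, CL 3.39 L/h, Vc 43.23 L) |
| monkey, moxifloxacin | 8 M, crossover 0/90 mg/kg, weights U(2.8, 6.8) kg | as dogs | sparse samples at 1, 2, 4, 8, 24 h, log-linearly interpolated (deconvolution stand-in) |
| human, moxifloxacin | 24 subjects (64% M), 2-way crossover placebo/400 mg | 15-point grid −0.17 to 48 h | 2-compartment, zero-order (D1 0.629 h) + first-order (Ka 2.21 /h) absorption, CL 13.41 L/h, Vc 122 L, Vp 55.4 L, Q 78.4 L/h |
| monkey, NCE05 | 6 (3M/3F), crossover 0/25/40 mg/kg | 16-point grid −1.17 to 24 h | sparse samples at 1.5, 4, 8, 24 h, interpolated |
| human, NCE05 | 24 M, parallel groups of 6 at 1/4/14/30 mg | 15-point grid | 1-compartment; the 1 mg arm falls below the LLOQ and is zeroed, serving as the baseline arm |

QT-model generating parameters are the published species × compound
estimates (baselines 240–399 ms, alpha 0.26–0.55, circadian amplitudes
2.4–14.9 ms, slopes 0.00056–0.022 ms/nM, the published BSV fractions and
residual SDs).  RR series are a circadian cosine around species resting RR
(600 ms dogs, 500 ms monkeys, 900 ms humans; fractional swing 8–10%,
beat-to-beat noise 3–4%, RR trough phase 4 h) — values chosen once as
field-typical, since the analysis conditions on RR rather than modelling it.
Dosing is at 08:00 by convention.

Exposure calibration.  Where published disposition parameters and the
published peak concentration are mutually inconsistent (the dog apparent
parameters under unit bioavailability predict ~7× less than the reported
112,930 nM peak — dog bioavailability was estimated per dose level, i.e.
the parameters are F-confounded), the preset carries an apparent dose-level
bioavailability factor (dog: 7.54) fixed analytically so the simulated
top-dose peak matches the reported Cmax.  Monkey PK parameters and human
NCE05 PK were not published at all; the presets carry synthetic
one-compartment generators (ka 1 /h, ke 0.1 /h) with volumes calibrated the
same way (monkey moxifloxacin 31,400 nM at 90 mg/kg; monkey NCE05 8,660 nM
at 40 mg/kg; human NCE05 101 nM at 30 mg).  NCE05's molecular weight is not
public; the presets use a synthetic 450 g/mol.  These calibrations set the
exposure scale only; the concentration-QT layer never sees them.

The monkey NCE05 preset is an edge case worth knowing about: the published
slope (0.022 ms/nM) times the published peak (8,660 nM) implies ~190 ms of
drug effect, which a linear model adds on top of a ~250 ms baseline —
crossing the physiological QT < RR ceiling.  The generator redraws residuals
that violate the ceiling and truncates any record whose *noiseless*
prediction exceeds it at 0.95·RR (a handful of top-dose peak records).  This
is the point where the linear low-dose approximation visibly breaks.

What the generator does **not** emulate: ECG waveforms and beat annotation
(RR/QT are interval-level), food-effect artefacts on QT, dropout or
withdrawal on ECG stopping criteria, assay error in concentrations, and any
covariate other than sex.  Passing recovery tests therefore demonstrates
that the inference machinery is correct *under the model's own assumptions*
at realistic designs and noise levels — not that the model is robust to the
misspecifications real telemetry data carry.

## Numerical choices

* Two-compartment profiles are computed exactly with matrix exponentials
  (augmented-matrix form during the zero-order infusion); the ODE-solver
  route exists only as an independent oracle in the tests.
* Log-linear interpolation is exact at nodes, linear on rises from zero,
  zero before the first sample, and extrapolates with the terminal log
  slope of the last two positive points.
* Phase-balanced thinning partitions each subject-occasion at 0.8×tmax and
  1.5×tmax (a convention of this package; no boundaries were published) and
  keeps at most n records per phase by evenly spaced index selection —
  deterministic, and applied to placebo occasions by the same time rule.
* BLQ handling replaces concentrations below the LLOQ with zero
  (idempotent).
* All randomness flows from explicit seeds; dataset metadata records the
  seed and full generating parameter set, and refitting with the same seed
  reproduces draws bit for bit.

## Known limitations

* The sampler is single-process; very large datasets (≫10⁴ records) would
  want a compiled or gradient-based sampler.
* Geweke flags are per-parameter at |z| < 2; with a dozen parameters,
  occasional chance exceedances are expected and the R-hat criterion is the
  primary convergence gate.
* With only 6–8 animals, between-subject SDs are weakly identified and
  their posteriors lean on the half-normal priors; population means are
  robust to this, but BSV% summaries from small preclinical fits should be
  read with care.
* The dog study combines a very large BSV on alpha (86%) with RR far from
  1 s; its fits occasionally flag R-hat marginally above 1.1 at the default
  chain lengths.  The slope — the quantity of interest — is stable across
  such replicates; longer chains clear the flag.
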
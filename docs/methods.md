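# Methods

This note documents the models, numerical methods and design choices
behind `maintpkpd`, in the order data flows through the package.

## Structural model

**Methotrexate.**  Amounts (µmol) in gut, central and peripheral plasma
compartments follow a linear oral two-compartment model,

    dX_GI/dt = -ka·X_GI
    dX_C/dt  =  ka·X_GI - ke·X_C - k_cp·X_C + k_pc·X_P
    dX_P/dt  =  k_cp·X_C - k_pc·X_P

whose parameters are fixed population-wide.  The erythrocyte
concentration X_E (µmol/L) is fed from the central or peripheral
concentration `C = X/V` by either a linear law `Kin·C` or a saturable law
`Vmm·C/(Kmm + C)`, and cleared as `Keff·X_E`.  The erythrocyte pool does
not feed back on plasma: its mass flux is negligible on plasma scale, so
the plasma subsystem is strictly autonomous.

**6-mercaptopurine.**  The same structure with a one-compartment plasma
model (gut, central); the erythrocyte pool is the measured thioguanine-
nucleotide concentration E-TGN.  One transcription of the source
equations writes the central-compartment balance with dX_GI/dt on the
left; it is implemented as dX_C/dt, the only reading under which X_C is
defined.

**Myelosuppression.**  Five compartments (proliferating pool, three
transits, circulating pool X_ma = model ANC):

    dX_prol/dt = ktr·X_prol·(1 - E_drug)·fb - ktr·X_prol,
    dX_trk/dt  = ktr·(upstream - X_trk),          k = 1..3
    dX_ma/dt   = ktr·X_tr3 - kcirc·X_ma,          fb = (base/X_ma)^γ

with `kcirc = 2.3765 /day` fixed (ln 2 / 0.29 d half-life of circulating
neutrophils) and the proliferation rate tied to `ktr`.  The drug effect
is `slope_6MP·E-TGN`, optionally plus `slope_MTX·E-MTX`; it is **not**
clipped at 1, so extreme exposure reverses proliferation — the model's
literal behaviour, exercised deliberately in tests.

**Mid-therapy initialisation.**  Records begin months into therapy, so
plasma compartments start at zero, erythrocyte pools at the first
observed concentration (INIMTX / INITGN; alternatively an estimated
patient parameter, or the residual-error-adjusted form
`(INI - σ₂η₂)/(1 + σ₁η₁)`), and the myelosuppression chain at a
treatment steady state scaled by the estimated parameter `inieff`:
X_ma(0) = inieff·base, upstream compartments at inieff·base·kcirc/ktr.
`inieff` is not constrained below 1.

**Variant space.**  `ModelVariant` spans: MTX influx law
(linear/Michaelis–Menten) × source (central/peripheral), 6MP influx law,
effect function (E-TGN only or E-TGN + E-MTX), initialisation mode, and a
fixed-PK comparison configuration (intracellular PK frozen
population-wide, ANC-only likelihood).  The default ("final") variant is
linear peripheral MTX influx, saturable 6MP influx with a no-IIV
Michaelis constant, and an E-TGN-only effect.

## Units, doses, fixed parameters

Metabolite measurements in nmol/mmol Hb convert to µmol/L with the
erythrocyte hemoglobin molarity 330 g/L ÷ 64458 g/mol = 5.1196 mmol/L.
Protocol doses (mg/m²) are scaled by Mosteller body surface area
√(height·weight/3600), multiplied by bioavailability (6MP F = 0.12; MTX
constant F or a pluggable dose-dependent function) and converted to µmol
(MW 152.18 / 454.44 g/mol).

6MP plasma rates ka = 21.07 /day and ke = 15.40 /day are literature
values; the central volume (60 L) and the MTX plasma block (ka 11, ke
6.93, k_cp 1.0, k_pc 3.5, Vc 30 L, Vp 10 L, F 0.7) are
literature-derived placeholders calibrated so that steady-state
erythrocyte exposures under protocol dosing land near the observed
population medians (E-TGN ≈ 0.8 µmol/L, E-MTX ≈ 0.026 µmol/L); all are
config profiles the user can override (`data/profiles.yaml`).

## Integration

Two integration paths exist and are tested against each other:

* **Reference path** (`simulate_patient`): adaptive stiff-capable
  integration (LSODA, rtol 1e-8 / atol 1e-10 by default) of the coupled
  system with dose boluses applied as state jumps and a restart at every
  event.  Used by the closed-form oracles (no-dose exponential decay to
  1e-6 relative; single-oral-dose two-exponential solution to 1e-6).
* **Fast engine** (`CohortEngine`): exploits the linearity and
  population-fixed parameters of plasma.  Plasma states are propagated
  analytically (cached matrix exponentials; exact day integrals via
  ∫X dt = M⁻¹ΔX) once per cohort; per day, the erythrocyte pools are
  stepped exactly against precomputed forcings (saturable influx by
  midpoint quadrature on a sub-day grid refined over the absorption
  peak), and the five myelosuppression states by RK4 with a
  rate-adaptive step (nominally 4/day, shortened when the feedback makes
  the system stiff, with states clipped to a physical band).  Agreement
  with the reference path is ~0.1–0.5% on protocol schedules; population
  estimation, VPC and sensitivity scans run on this engine because a fit
  needs thousands of cohort simulations.

Predictions at non-integer observation times are linearly interpolated
between day-grid points on the fast path (generated cohorts observe on
whole days, where extraction is exact).

**Feedback floor.**  X_ma enters the feedback floored at 0.01 G/L.  An
unbounded feedback reaches ~10⁷ as the count collapses and drives
rebounds of thousands of G/L — far outside any observed count; 0.01 G/L
is a detection-limit-scale floor bounding the feedback at
(base/0.01)^γ ≈ 70.  The same floor is applied to ANC predictions inside
the proportional residual model, whose variance prop_var·f² is otherwise
singular as f → 0.

## Estimation

The population objective is the Laplace approximation of −2 log marginal
likelihood: per patient, the joint −2 log-likelihood at the MAP η̂ plus
ln det(H/2π), with H the Gauss–Newton Hessian (including the
proportional-error interaction term) of half the joint objective — exact
for models linear in η, which anchors the closed-form test.

The optimizer iterates:

1. **MAP update** — vectorised Levenberg–Marquardt across patients with
   forward-difference Jacobians, per-patient damping and acceptance.
   The per-patient posterior is multimodal (rival phase alignments of
   the feedback-driven ANC oscillation), so a staged multi-start runs
   periodically: PK axes first (metabolite channels make them nearly
   unimodal), then the PD axes from fixed phase/potency patterns, a
   per-patient ANC level anchor, patient-keyed random draws screened by
   objective, and a growing-time-window continuation; each patient keeps
   its best mode.  Draw randomness is keyed to patient identity so fits
   are invariant to patient ordering.
2. **Exact recentring** — θ ← θ·exp(mean η̂), η̂ ← η̂ − mean: predictions,
   Jacobians and Hessians are unchanged and the objective provably drops
   by n·Σ mean²/ω²; applied unconditionally.
3. **Fixed-effect step** — profiled Gauss–Newton on log θ: the
   sensitivity J_θ + J_η·dη̂/dθ with dη̂/dθ = −H⁻¹(J_ηᵀWJ_θ) accounts for
   the empirical-Bayes re-adjustment that otherwise makes η-compensated
   directions look spuriously stiff.  This is also the only update for
   parameters without IIV (the Michaelis constants).
4. **Variance updates** — EM-style: ω²_k ← mean(η̂² + [H⁻¹]_kk); residual
   variances from expected squared residuals (with the J·H⁻¹·Jᵀ
   correction), a 1-D/2-D inner optimisation for combined error.  Both
   are capped at 3× per iteration so a transiently poor structural fit
   cannot run the variances away.
5. **Damped acceptance** — the full proposal, then fixed-effects-only,
   then variances-only, each with log-space step halving; a proposal is
   accepted only if the Laplace objective decreases, so the accepted
   trace is monotone.  Mode discoveries made during rejected trials are
   transferred back to the current point.

Convergence: repeated sub-tolerance improvements or repeated failure to
move; an optional wall-clock budget bounds long fits (the acceptance
study allows 420 s for the 100-patient fit).  Standard errors by central
finite differences of the objective in log θ are available on request
(`compute_se`); they re-solve the inner problem per evaluation and are
reported only when the information matrix is positive definite.

**Known limitation.**  Under the study's observation design (monthly
metabolites, biweekly ANC with 50% proportional noise, one year, 100
patients), the effect slope trades off against the maturation rate, the
initialisation parameter and the saturable-influx pair along a nearly
flat ridge of the Laplace objective.  The recovery study typically ends
with a median fixed-effect error of ~6%, eight to nine of ten fixed
effects and all variability components inside their tolerance bands, but
the slope tens of percent high — and driving the optimizer deeper lowers
the objective while moving the slope further away, i.e. the approximate
objective's own optimum sits off-truth on this axis (a linearisation/
shrinkage bias of Laplace-type estimators under weak individual-level
identifiability).  The empirical-Bayes estimates of the slope and
maturation-rate etas correlate only weakly with the generating values
for the same reason.  This mirrors the instability of exactly these
parameters under data reduction in the motivating analysis.

## Virtual cohorts

The generator draws demographics (ages uniform on 2.4–16.9 y; height and
weight follow simple growth trends with noise, clipped to the observed
81.5–180 cm and 10.3–105.5 kg), individual parameters log-normally
around the population values, and simulates the full model under
protocol dosing: 6MP 75 mg/m²/day and MTX 20 mg/m²/week, titrated by a
count-guided controller (±25% steps against the 0.5–2.0 G/L target,
suspension below 0.3 G/L with resumption at half dose, weekly reviews
acting on noisy interim counts that are *not* retained in the emitted
dataset — clinical monitoring uses more counts than a research extract
keeps).  Because real patients enter such datasets mid-maintenance,
each patient's starting dose is pre-titrated (protocol notches down from
75/20 until the steady-state drug effect leaves a viable count), and the
erythrocyte pools start at their periodic steady state under that dose.
Without pre-titration the feedback model produces rebound counts of
10³–10⁴ G/L for drug-sensitive patients — a regime the source data never
enters and the transit-feedback model does not describe credibly.

Observations: joint E-MTX/E-TGN measurements every ~28 days and ANC
every ~14 days, jittered by a rounded N(0, 2 d), always including day 0
(the initialisation anchor); residual error per channel, clipped at zero
(measured concentrations and counts are non-negative).  A ground-truth
sidecar stores per-patient η, individual parameters and noise-free
predictions; re-simulating from it reproduces the predictions to
numerical identity, and generated cohorts pass the exclusion filter
untouched.

What the generator does *not* emulate: real dose-adjustment magnitudes
and cadences (unpublished), the metabolite-product dosing arm, visit
non-compliance, assay artefacts, covariate effects on PK, or
between-occasion variability.  Passing recovery tests therefore show the
estimator recovers the model's own data-generating process at realistic
design density — not that the model is correct for real patients.

## Diagnostics and downstream analyses

* CV% = 100·√(exp(ω²)−1); η-shrinkage = 100·(1 − SD(η̂)/ω) (n−1
  denominator); η p-values from one-sample t-tests of the EBE means.
* RMSE/MAE per patient and channel, summarised by median/mean/SD, for
  individual (EBE) and population (η = 0) predictions.
* Cross-validation: per patient, the cutoff is the time of the
  (⌊n/2⌋+1)-th ANC observation and observations strictly before it are
  retained (so at most half the ANC observations survive for even n),
  followed by re-filtering.
* VPC: the observed design is fixed; replicates redraw η and ε; 2.5/50/
  97.5 percentiles per equal-count time bin (default 10) with Monte-
  Carlo 95% bands; seeds fan out per replicate via `SeedSequence` spawn
  keys.
* Sensitivity: one fixed parameter at a time (6MP ka, ke, Vc, F; the MTX
  plasma block; kcirc) over an interval (95% CI, or 50–150% for F, or
  ln 2 / CI(t½) for kcirc), 100 equally spaced simulations of a
  median-demographics reference patient (114 cm, 21.5 kg) on the
  protocol starting schedule over 364 days, daily grid; the reported
  statistic is max |ANC − reference| per grid point.  The reference
  schedule behind the published scan maxima is not public, so these
  scans are checked by their structural properties (zero width ⇒ zero,
  inert parameter ⇒ zero, determinism, nested intervals) rather than by
  value.

## Problem sizes used by the shipped studies

Parameter recovery: 100 patients × 364 days (13 metabolite pairs, ~26
ANC per patient), fit budget 420 s.  Cross-validation: 40 patients, two
120 s fits.  VPC: 200 replicates.  Unit and oracle checks run on single
reference patients in milliseconds to seconds.
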
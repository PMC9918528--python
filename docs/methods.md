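# Methods

## Model overview

The package simulates paired [¹¹C]raclopride PET scans (placebo vs
methylphenidate challenge) and estimates the dynamics of the induced
dopamine increase from the difference of their SUVr time courses. Time is
in minutes, rate constants in 1/min; t = 0 is the tracer bolus, the scan
window is 0–90 min, the IV challenge occurs at +30 min and the oral
challenge at −30 min.

**Tracer input.** The arterial tracer concentration is a linear rise to
`A1+A2+A3` at `t_peak` followed by three decaying exponentials with
half-lives `T1..T3` referenced to `t_peak`:

```
C_p(t) = (A1+A2+A3)/t_peak · t                          t < t_peak
       = Σ_i A_i · exp(−ln2/T_i · (t − t_peak))          t ≥ t_peak
```

Defaults: amplitudes (288.6, 1.1, 409.7) Bq/ml, half-lives (4.28, 735.5,
183.5) **minutes**, `t_peak` = 110 s. The half-lives must be read on the
minute scale: on a seconds scale the plasma tail would be gone within ~1 h,
the simulated cerebellum activity would fall to ~0.01 Bq/ml by 60 min, and
the SUVr ratio would diverge to several hundred — a reference-tissue
framework is only meaningful when the reference region retains measurable
activity for the whole scan. With the minute-scale reading the late-scan
SUVr settles near the distribution volume ratio (≈ 6.9), as it must.

**Reference region.** One-tissue cerebellum model,
`dC_r/dt = K1r·C_p − k2r·C_r`, with K1r = 0.092 mL/min/g and
k2r = 0.45 min⁻¹.

**Target region (LSSRM).** The striatal TAC follows the linear simplified
reference region model with a time-varying efflux term for
dopamine–raclopride binding competition:

```
C_T(t) = R1·C_r + k2∫C_r − k2a∫C_T − γ∫h(u)·C_T(u) du
```

solved in differential form with the substitution `z = C_T − R1·C_r`,
which removes the reference-derivative term; the integral and differential
forms agree to better than 1e-6 relative (enforced by a test). Defaults:
R1 = 1.154, k2 = 0.45 min⁻¹, k2a = 0.065 min⁻¹ (baseline
BP_nd = k2/k2a − 1 = 5.92). The displacement amplitude defaults to
γ = 0.18 min⁻¹ (0.003 s⁻¹). This value is set by two consistency
requirements: (i) the challenge-induced ΔSUVr must stand well above the 3%
SUVr measurement noise for the time-to-peak estimator to behave as the
framework's robustness results require (at γ = 0.003 min⁻¹ the signal
amplitude, ≈ 0.26 SUVr units, would be *below* one noise SD per sample and
every downstream statistic would be noise-dominated); (ii) published LSSRM
displacement amplitudes for pharmacological-scale challenges lie in the
0.05–0.4 min⁻¹ range. γ is a config parameter; nothing in the code assumes
the default.

**DAT occupancy.** Free and bound MP in the striatum follow a two-tissue
model expressed in concentrations relative to the total transporter pool
DAT₀ (`R = C_free/DAT₀`, `f_occ = C_bound/DAT₀`):

```
dR/dt     = K1·Rp − k2·R − k3·(1−f_occ)·R + k4·f_occ
df_occ/dt = k3·(1−f_occ)·R − k4·f_occ
```

with K1 = 0.6, k2 = 0.06, k3 = 0.5, k4 = 0.2 min⁻¹. The relative plasma MP
input is `Rp(t) = A·exp(−λt)` after the IV bolus (A = 0.25,
λ = 0.05 min⁻¹, i.e. a 13.8-min blood half-time); the default amplitude
produces ≈ 64% peak DAT blockade, consistent with the ~70% expected at
this dose. The oral input is a peak-normalized unit-scale gamma density
with mode 90 min after ingestion; its amplitude (0.161) is calibrated so
the oral peak occupancy matches the IV condition, mirroring the dose
equivalence of the two administration routes. Occupancy ≥ 1 is rejected as
unphysical.

**Dopamine response.** Extracellular dopamine rises with transporter
blockade and clears through the remaining free transporters. After scaling
out the release rate, the single-parameter form is

```
dD/dt = β·[ f_occ − (1−f_occ)·D ],      β = 0.02 min⁻¹.
```

Clamping `f_occ = c` gives the closed-form equilibrium `D → c/(1−c)`
(property-tested to 0.1%).

**Displacement profile h(t).** `make_h` builds h from `f_occ` (occupancy
hypothesis), from `D` (dopamine hypothesis) or from a heuristic
gamma-variate, normalized to a peak of 1 and zero before the challenge;
the normalization is computed over the scan window only, and an all-zero
profile is an error. The Monte-Carlo experiments instead scale
`h = D/D_ref`, where D_ref is the canonical-condition dopamine peak: at
the nominal dose this is identical to peak normalization, but dose and
parameter draws then modulate the displacement amplitude mechanistically —
per-replicate renormalization would erase the dose response entirely.

**SUVr and noise.** SUVr is the instantaneous ratio C_T/C_r on 1-min frame
midpoints (0.5 … 89.5 min); frame averaging onto the 48-frame acquisition
scheme (30×1, 12×2.5, 6×5 min) is available but opt-in. Measurement noise
is multiplicative Gaussian, `value·(1 + N(0, cv))` with cv = 0.03 by
default (SUVr is a ratio metric with approximately proportional error); an
additive variant is a config toggle. ΔSUVr = SUVr_PL − SUVr_MP pointwise.

## Estimation

**Gamma-CDF time-to-peak.** `F(t′) = A·P(s, t′)` (regularized lower
incomplete gamma, unit scale in minutes, `t′ = t − onset`) is fitted to the
post-onset ΔSUVr samples by bounded least squares (trust-region reflective;
two free parameters). TTP = s − 1 is the mode of the corresponding density.
Initialization: s₀ = max(2, half-rise time + 1), A₀ = late-curve mean;
bounds s ∈ (1, 200], A ∈ (0, 10] — s ≤ 1 is a non-identifiable plateau.
Non-convergence and degenerate inputs set a flag rather than raising, so
Monte-Carlo batches always complete; fits at the s bound are treated as
non-converged.

**Logan reference analysis.** OLS on the reference-tissue Logan transform
for t ≥ t\* (default 20 min), trapezoidal running integrals, slope = DVR,
BP_nd = DVR − 1. The reference-efflux term `C_r/(k2′·C_T)` uses
k2′ = 0.45 min⁻¹ by default and can be omitted. On noiseless placebo
simulations the estimate reproduces k2/k2a − 1 within 2% for
t\* ∈ {15, 20, 25} min.

**Delay metric.** The lag between two monotone-rise curves is the
difference of their half-maximum crossing times (primary) or the
correlation-maximizing shift (secondary); the two agree within a few
minutes on smooth curves.

**Outliers.** Fitted TTP values more than 2 sample SDs from the mean are
flagged (single pass, candidate included) and excluded from summaries;
exclusion counts are always reported.

## Monte-Carlo experiments

Default n = 1000 replicates (the in-suite checks use n = 200 and compare
through 3-standard-error brackets; the replicate count is a config value).
Parameter draws are multiplicative Gaussian CVs truncated at ±4 SD to keep
rates positive. All draws and noise derive from one master seed
(bit-reproducible).

- *Specificity*: noiseless ΔSUVr under h ∝ f_occ vs h ∝ D with identical
  kinetics; reports both delay metrics and the shape correlation of each h
  with its own ΔSUVr. The dopamine-driven curve lags the occupancy-driven
  one by ~16 min (half-max), and only the dopamine profile matches its
  ΔSUVr shape (r ≈ 0.99 vs 0.93).
- *Dose sensitivity*: peak ΔSUVr across dose scales; amplitude increases
  monotonically and sublinearly (receptor-competition saturation).
- *Injection jitter*: N(0, 120 s) shifts of the tracer bolus (challenge
  scan) or the MP bolus; fitted-TTP SD ≈ 0.43 min and ≈ 1.6 min
  respectively at 3% noise.
- *Within-pair variability*: independent 4%-CV draws of the input and
  kinetic parameters per scan; fitted-TTP SD ≈ 1.6 min.
- *Target-model-only variability*: 10%-CV draws of R1, k2, k2a, γ move the
  fitted TTP by < 1 min on average — TTP is insensitive to the tracer
  kinetics per se.
- *Between-subject associations*: 10%-CV draws of dose, plasma timing and
  all kinetic parameters; univariate R² of fitted TTP on each drawn
  parameter. Dose dominates for IV; the absorption peak time dominates for
  oral.
- *TTP recovery*: plasma decay fixed, 4%-CV draws of everything else plus
  noise; Pearson correlation between fitted TTP and the true rate TTP
  (argmax of dD/dt, central differences on the solver grid) and the
  mean |fitted − true|.

## Numerics

Single trajectories: LSODA (automatic stiffness switching), rtol 1e-8,
atol 1e-10; integration starts at the administration time for the
occupancy system, since the state is identically zero before and the bolus
is a step discontinuity. Batches: classical RK4 on a fixed 0.02-min grid
(occupancy at 0.01 min so RK4 midpoints land on stored samples), with the
step discontinuity of the IV bolus handled by averaging the one-sided
limits at the landing node; agreement with the adaptive solver is
1e-4 relative or better on the quantities that propagate (f_occ, D, TACs).
A full 1000-replicate experiment takes a few seconds on one CPU; the
complete headline-statistics script runs in about a minute.

## What the generator does and does not emulate

The synthetic scans include the acquisition timing, kinetic heterogeneity,
dose variation, injection-time error and multiplicative measurement noise.
They do **not** include scanner resolution effects, motion,
attenuation/scatter residuals, radioactive-decay counting statistics
(noise is stationary in CV, not frame-duration weighted), head-to-head
anatomical variability, or placebo-condition dopamine fluctuations.
Passing tests therefore demonstrate the internal consistency of the
estimation chain under the stated noise model, not performance on real
scans.

## Known limitations

- The time-to-peak of the fitted gamma CDF systematically exceeds the true
  dopamine-rate TTP by ~1–10 min depending on γ: ΔSUVr is a
  `k2a`-low-passed functional of D(t), so the proxy lags the underlying
  rate; the lag shrinks as the displacement term grows.
- Fitted TTP moves almost 1:1 with the MP bolus time, so MP-timing errors
  propagate with sensitivity near unity when the analysis assumes the
  nominal onset.
- Within-pair kinetic differences (R1, k2, k2a) shift the SUVr level
  between scans; the resulting ΔSUVr baseline distortion biases the
  two-parameter fit, which has no offset term. Baseline-correcting over
  the pre-challenge window does not help — the pre-challenge SUVr is still
  equilibrating and its mean is itself biased.
- The oral route's fitted TTP is almost fully determined by the absorption
  peak time (R² ≈ 0.98 under 10% CV), a consequence of the
  single-gamma-density absorption model.
- The occupancy model omits peripheral MP metabolism beyond the
  mono-exponential plasma decay, and the dopamine model is a single
  clearance compartment: β sets the only intrinsic dopamine timescale.
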
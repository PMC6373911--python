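# Methods

`cpetcf` re-implements, as a tested pipeline, an analysis chain for
cardiopulmonary exercise tests (CPET) in children and adolescents with cystic
fibrosis (CF): extraction of ventilatory and metabolic predictors from
breath-by-breath ramp-test traces, automated gas-exchange-threshold (GET)
detection, a Gaussian-process (GP) emulator predicting the GET from seven
patient-level inputs with leave-one-out validation, PCA-based performance
characterisation, and a mechanistic dead-space / alveolar-ventilation model.
Because no patient-level dataset is available, all statistical structure is
exercised on a synthetic cohort with known ground truth; this note records
what each stage assumes, the defaults chosen where the design was open, and
what passing tests do and do not establish.

## The ramp protocol and the trace model

A test consists of a 3-minute warm-up at a low fixed power (10–20 W), a ramp
at a per-patient rate of 10–25 W·min⁻¹ chosen to elicit volitional exhaustion
in roughly ten minutes, and 5 minutes of active recovery at 20 W.  Traces
carry time (s), work rate (W), oxygen uptake V̇O2, CO2 output V̇CO2 and
minute ventilation V̇E (all L·min⁻¹), breathing frequency BF (min⁻¹) and
tidal volume V_T (L), with the identity V̇E = BF·V_T enforced up to a
configurable relative tolerance (default 5%, accommodating real-cart noise;
the synthetic generator satisfies it exactly).  One canonical unit set is
used throughout — reference values quoted in L·s⁻¹ are converted on input
(0.822 L·s⁻¹ ≡ 49.32 L·min⁻¹) — and the CSV reader supports declared unit
dialects (mL·min⁻¹, L·s⁻¹).  Resampling onto a uniform grid is plain linear
interpolation; any smoothing is left to the stage that needs it.

## Synthetic cohort

The generator emulates the statistical structure the downstream analysis
assumes, with every "true" quantity recorded per patient:

* V̇O2 = resting V̇O2 + efficiency × work, through an optional first-order
  lag (τ = 30 s default; the lag filter is seeded at the warm-up steady state
  so warm-up baselines are exact).  Peak V̇O2 is sampled per patient and the
  ramp rate derived so the ramp lasts ≈ 600 s, then clipped to the protocol's
  10–25 W·min⁻¹ band.
* V̇CO2 = RQ·V̇O2 below the true threshold, plus an excess-CO2 slope above it
  (the V-slope breakpoint; RQ ≈ 0.85, excess slope ≈ 0.45 by default).
* ln V̇E = α + β·V̇O2, with β ≈ 1.0 per L·min⁻¹; α is derived from the
  sampled baseline BF and V_T so that V̇E = BF·V_T holds exactly at warm-up.
  A linear hyperventilation surge (up to +30%) is applied over the final 60 s
  before exhaustion, emulating the respiratory-compensation point that the
  fitting windows must exclude.
* V_T saturates from its baseline towards a per-patient maximum (≈ 45% of
  FVC, the tidal-volume ceiling characteristic of CF); BF = V̇E / V_T, so the
  ventilation identity is exact by construction.
* Noise: additive Gaussian on V̇O2/V̇CO2 (SD 0.035/0.040 L·min⁻¹),
  multiplicative log-normal on V̇E (σ = 4%), additive on V_T (SD 0.02 L).
  Breaths are approximated by a uniform 1-s grid rather than simulated
  individually — the analysis operates on resampled grids anyway.

Cohort-level distributions (age 13 ± 2.5 y, FVC 3.0 ± 0.7 L, FEV1/FVC
0.78 ± 0.08, V̇O2max 1.9 ± 0.35 L·min⁻¹, GET at 55 ± 6% of V̇O2max) are
physiologically plausible for a paediatric CF group and are config-exposed;
they are not claimed to match any particular study cohort.  Generation is
deterministic given (seed, patient index).

What the generator does **not** emulate: breath-by-breath timing
irregularity, cart-specific filtering, V̇O2 slow-component kinetics,
plateau/verification-bout behaviour, or any dependence of the threshold
fraction on the seven features beyond what the shared physiology induces.
Passing tests therefore establish the *algorithms'* correctness and the
pipeline's statistical behaviour under known structure — not clinical
validity on real carts.

## Feature extraction

Performance is the total mechanical energy transferred: the trapezoidal
integral of work rate from warm-up start to exhaustion, in kJ.  All
ramp-phase fits share one exclusion window — the first 180 s (work rate not
yet increasing) and the final 60 s before exhaustion (post
respiratory-compensation hyperventilation) are dropped.  The ventilatory
curve is fitted as an ordinary least-squares regression of ln V̇E on V̇O2
(natural logarithm; the base only rescales intercept and slope jointly).
The seven emulator inputs are: baseline BF and V_T (warm-up means), the V̇O2
at which the fitted curve reaches a reference ventilation of 49.32 L·min⁻¹,
FVC, FEV1, and the OLS slopes of BF and V_T over the same window.  Slopes
are regressed against V̇O2, mirroring the ventilatory-fit convention; a
`--vs-time` alternative exists because either reading of "rate of change" is
defensible.

## Threshold detection (V-slope)

Below the anaerobic threshold V̇CO2 tracks V̇O2 via the respiratory
quotient; above it, bicarbonate buffering of lactate adds excess CO2.  The
detector fits a continuous two-segment piecewise-linear model of V̇CO2 on
V̇O2 (basis [1, x, (x−c)₊]) over the shared ramp window, searching candidate
knots on a grid with step 1% of the V̇O2 range over the central 10–90% of
that range, and keeps the global RSS minimiser — a formulation chosen for
transparency and exhaustive-search checkability over opaque heuristics.  An
F-test (2 extra effective parameters, default α = 0.05) against a single
line rejects spurious breakpoints on linear data, as does a negative
excess-slope estimate.  The threshold crossing time is the first ramp-phase
time at which a 15-s moving-average V̇O2 reaches the detected threshold
(smoothing prevents noise-triggered early crossings).  The detector is
scale-equivariant: rescaling both gas channels rescales the threshold and
leaves slopes unchanged.

## Gaussian-process emulator

The emulator is GP regression from first principles with the anisotropic
squared-exponential covariance K(x,x′) = σ²·∏ᵢ exp(−|xᵢ−xᵢ′|²/(2Φᵢ²)) and a
first-order polynomial mean μ(x) = β₀ + βᵀx.  The posterior at a query z is

    m(z)   = μ(z) + K(z,X)ᵀ K(X,X)⁻¹ (y − μ(X))
    s²(z)  = K(z,z) − K(z,X)ᵀ K(X,X)⁻¹ K(z,X)

with a nugget on the diagonal of K(X,X).  Numerical choices:

* Inputs are standardised to zero mean / unit SD (the seven inputs have
  incommensurate units; lengthscales then compare meaningfully), outputs
  centred.
* Hyperparameters are estimated by multi-start L-BFGS in log space with
  analytic gradients; the mean coefficients are profiled out by generalised
  least squares at each step.  The first start is at (log sd(y), Φ = 1); the
  rest are seeded draws.  Deterministic given `random_state`.
* Lengthscales are bounded in [0.01, 100] (standardised units).  The upper
  bound matters: σ and Φ are unidentifiable along the joint ridge
  σ, Φ → ∞, which otherwise yields absurd fits (σ of ~10²·sd(y)) that
  extrapolate confidently and wrongly.  Bounding Φ at a large multiple of
  the input range is standard kriging practice.
* The nugget defaults to 10⁻⁸·var(y), escalated tenfold on factorisation
  failure up to 10⁻²·var(y).  With `estimate_nugget=True` the noise variance
  becomes an additional ML parameter — appropriate when the outputs are
  *detected* thresholds carrying measurement error, and used by the pipeline.
* `objective="reml"` maximises the restricted likelihood instead of the
  profiled marginal likelihood.  With n = 15 and a d+1 = 8-term mean, plain
  ML underestimates σ² by roughly the factor (n−8)/n; REML removes this
  bias.  The pipeline uses REML; the class default remains plain ML.

Two variance conventions coexist deliberately.  `predict()` returns the
conditional-GP variance above, which treats the mean as known: it vanishes
at training inputs and reverts to σ² far from data.  For held-out
prediction the mean coefficients are themselves estimates, so LOO fold
variances add the universal-kriging correction
uᵀ(HᵀK⁻¹H)⁻¹u, u = h(z) − HᵀK⁻¹K(X,z), available via
`predict(..., include_mean_uncertainty=True)`.  The correction is zero at
training inputs and grows where the estimated trend is extrapolated.

Leave-one-out cross-validation reports MSE_LOO = (1/n)∑(m₋ᵢ(xⁱ) − yᵢ)²,
its value relative to mean(y), per-fold means/variances and the count of
95% intervals (m ± 1.96 s) containing the left-out value.  The default
`refit` mode re-estimates hyperparameters on every fold (the literal
definition of m₋ᵢ), with per-fold optimizer seeds derived deterministically
from the base seed; `fixed` mode holds hyperparameters from the full fit
and re-solves only the mean and posterior per fold.

A known limitation, measured rather than hidden: with hyperparameters
*estimated* per fold at n = 15, d = 7 (16 free parameters on 14 points),
pooled interval coverage falls well short of nominal regardless of ML/REML
or bounds — emulation at this sample size is under-determined, consistent
with the usual ~10·d-points design guideline.  With the covariance known
(the well-specified case), pooled LOO coverage is nominal; that is the
calibration property the acceptance suite asserts, while the
estimated-hyperparameter coverage is reported as an output.

## PCA of the breathing/uptake space

Baseline BF, baseline V_T and the V̇O2 at the reference ventilation strongly
co-vary; cohorts lie close to a plane in this 3-space.  Variables are
standardised (units are incommensurate) and the correlation matrix
eigendecomposed; loadings are sign-fixed to a non-negative BF component.
Two summaries are attached: θ = arccos |⟨PC1, ê_BF⟩|, the polar angle of the
leading loading relative to the breathing-frequency axis, and the fraction
of total-energy variance explained by a univariate OLS regression of energy
on the PC1 score.  The latter is this package's operationalisation of "the
share of performance variation captured by the first component" — the
most literal defensible reading of an ambiguous quantity, and labelled as
such.

## Dead-space model and ODE core

Dead-space ventilation is modelled as V̇D(t) = V̇DB + a·W(t) with
V̇DB = BF(rest)·V_D(rest) and a = BF(exercise)·V_D(exercise)/W(exercise),
built from rest and *peak*-exercise measurements (which exercise time point
defines the scaling is not uniquely determined; peak is the default and is
config-exposed).  Alveolar ventilation follows as V̇A = V̇E − V̇D, an exact
identity wherever all three are defined; negative V̇A is counted and
reported, never clipped, since it flags a mis-parameterised patient.  Per-
patient dead volumes V_D are treated as measured inputs; the synthetic
cohort supplies them as fixed fractions of tidal volume (35% of baseline
V_T at rest, 30% of the V_T ceiling at exercise — elevated dead-space
fractions consistent with CF).

The ODE core is a compartmental cardiopulmonary model in the classical
lumped tradition: alveolar partial pressures of O2 and CO2 and mixed-venous
concentrations evolve by lung/tissue mass balance (863 mmHg converts STPD
flows to partial-pressure units); arterial contents follow an exponential-
saturation O2 dissociation curve and a linearised CO2 curve; cardiac output
rises linearly with O2 uptake (5 L·min⁻¹ per L·min⁻¹); metabolic rate
follows the work profile through a 30-s first-order response with RQ 0.85;
and alveolar ventilation is set by a central CO2 controller
(1.8 L·min⁻¹·mmHg⁻¹ above a 35-mmHg threshold) plus an exercise feedforward
drive proportional to excess metabolic CO2 (20 L·min⁻¹ per L·min⁻¹), which
keeps the simulated response near-isocapnic, as observed below the
respiratory compensation point.  All parameter values are documented
physiological defaults of standard textbook magnitude; the module's tested
surface is the dead-space algebra, steady-state/Fick consistency, O2 mass
conservation and solver convergence, not patient-specific parameter
fidelity.  Integration uses LSODA with rtol 10⁻⁸ and scaled atol; the
zero-dead-space mode (V̇E = V̇A) is bitwise independent of the dead-space
parameters.  The resting steady state (PaO2 ≈ 105 mmHg, PaCO2 ≈ 38 mmHg,
V̇A ≈ 5.8 L·min⁻¹ at V̇O2 = 0.30 L·min⁻¹) is obtained by root-finding and
used as the initial condition.

## Pipeline and reproducibility

`run_all` chains cohort generation (or reading traces from disk), feature
extraction, threshold detection, emulator fitting with LOO, PCA, and the
ventilatory-split summaries, writing one machine-readable table per stage
plus a manifest (seed, config hash, package versions, stage timings).  A
stage failure aborts with the stage name while preserving partial outputs.
Runs are bit-reproducible given the config and seed.  Problem sizes used by
the test and acceptance runs — 15-patient cohorts (the study's size), 100
threshold-recovery replicates, 50 calibration cohorts — were chosen as the
smallest sizes at which the assessed statistics are stable.

## Known limitations

* The cohort distributions are plausible defaults, not fitted to any real
  group; absolute pipeline outputs (MSE_LOO, PCA shares) describe the
  synthetic conditions only.
* The emulator's estimated-hyperparameter intervals undercover at n = 15,
  d = 7 (see above); more patients, not more tuning, is the fix.
* The ODE core's parameters are population defaults; no per-patient fitting
  is attempted beyond the closed-form dead-space construction.
* The V-slope formulation (continuous segments, grid search, F-test guard)
  is one transparent member of the V-slope family, not a re-implementation
  of any specific published procedure's internals.
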
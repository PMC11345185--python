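# Methods

This note records the models, parameter choices, and numerical decisions
behind `pfr`, and what the synthetic-data tests do and do not establish
about real recordings.

## The compartmental pressure-flow model

Intracranial hemodynamics are reduced to a zero-dimensional compartment in
which cerebral blood flow `Q` responds to the perfusion-pressure gradient
`∇p = ABP − ICP`:

```
Q(t) = α₁ ∇p(t) + α₂ d∇p/dt,      α = (α₁, α₂) ≥ 0.
```

`α₁` (mL·s⁻¹·mmHg⁻¹) is a vessel-bed conductance — its reciprocal is the
familiar cerebrovascular resistance `CVR = ∇p/Q` once the storage term is
averaged away — and `α₂` (mL·mmHg⁻¹) a compliance-like coefficient.
Cerebrospinal-fluid, venous-sinus, and volumetric compartments are
deliberately out of scope: they render the model unidentifiable without
data that bedside monitoring does not provide. The non-negativity of `α`
encodes the positive pressure-flow hypothesis; it is what forces
negatively coordinated data to reveal themselves downstream.

### Inversion

CA is treated as stationary at 1-min timescales: each 1-min block of the
(block-averaged) CPP series carries its own constant `α`. The trajectory
minimizes

```
Σ_k |q_k − α_k·X_k|²  +  μ Σ_k |α_k − α_prior|²  +  λ Σ_k |α_{k+1} − α_k|²,
α ≥ 0,   X_k = (∇p_k, d∇p_k/dt),
```

solved as a single bound-constrained least-squares problem (dense BVLS; the
stacked system has 2 unknowns per window). The derivative is a central
difference on the 1-min means, one-sided at the ends; NaN input propagates
to the affected samples and their stencil neighbors.

Defaults: `α_prior = (1, 0)` model units, anchor weight `μ = 10⁻³`,
roughness `λ = 1`, minimum 10 valid windows. The anchor exists because the
absolute flow scale is unidentifiable from pressure alone; every downstream
use of the estimate goes through a variance-standardized slope, which is
scale-free, so the anchor value is immaterial to classification.

The flow-consistency term is active only when a model-space flow
observation is supplied (as in the forward–inverse oracle tests). On the
clinical path the estimator sees CPP alone — perfusion enters only at the
posterior correction — and the returned flow is the prior-anchored model
response of the observed CPP.

### Sign guarantee

On the clinical path the estimate is non-negatively oriented with CPP by
construction (`corr(Q̂, CPP) ≥ 0`; with a nonzero compliance prior a
fallback to the pure conductance response enforces it). When fitting to a
flow observation, per-window non-negativity still holds, but the *global*
correlation of a piecewise-scaled flow with CPP can legitimately be
negative when parameter shifts dominate the flow variance; such fits are
flagged (`negative_orientation`) rather than overridden, since overriding
them would destroy exact recoveries of valid model flows.

## Posterior correction and regime classification

Model flow (global, model units) and thermodiffusion perfusion (local,
mL/hg/min) differ by patient- and probe-specific scale and offset. Both
signals are standardized to zero mean and unit variance; the slope `m` of
the least-squares fit of standardized flow to standardized perfusion is
then their Pearson correlation, comparable across probe placements. The
offset is reported back in perfusion units. NaN pairs are dropped listwise
and at least 30 joint samples are required.

Labels: `pPFR` if `m > 0.2`, `nPFR` if `m < −0.2`, `zPFR` if `|m| ≤ 0.2`
(boundary inclusive). The printed form of the negative branch in the source
material reads as a threshold at +0.2, which would not be exclusive of the
zero band; it is implemented as `m < −0.2`. The 0.2 half-width is
configurable.

## Autoregulation indices

Mx and PRx share one computational core: block-average two channels at
width `w`, slide a window of `n` consecutive blocks by a step (default
60 s), and emit the Pearson correlation per window, stamped at the window
end. Windows missing any valid pair, or with zero variance, are NaN.

* Mx: flow vs CPP, `w = 12 s`, `n = 30` (6-min windows).
* PRx: ABP vs ICP, `w = 10 s`, `n = 30` (5-min windows) — the literature
  convention; there is no consensus parameterization, and bedside-computed
  PRx values from commercial monitors may use other windows, so all
  parameters are configurable.

Epoch-level summaries are means over valid windows. The neutral-Mx
comparison splits epochs at `|Mx| < 0.15` and applies a one-sided
two-sample t-test (alternative: neutral-group PRx smaller); a pooled-
variance test by default, Welch optional.

## Quality control and interval extraction

The unit of analysis is a 100–140 min window with ABP, ICP, and perfusion
jointly present. Maximal joint-coverage runs (perfusion gaps up to 10 min
tolerated; any ABP/ICP gap longer than a second breaks a run) are tiled
greedily left-to-right into non-overlapping max-length chunks, keeping a
final chunk if it still reaches the minimum; overlap policy is a package
choice, as is left-aligned half-open block averaging with timestamps at
block starts.

QC rules, evaluated in physical units and all configurable:

1. ABP negative anywhere; or ABP above a factor (default 1.1) times the
   epoch-level 99.8th percentile. The outlier clause is ambiguous in its
   source: a literal "any sample above the epoch's own 99.8th percentile"
   fails every non-degenerate interval by construction (0.2% of any epoch's
   mass lies above its 99.8th percentile), so a multiplicative margin is
   applied and exposed in `QCConfig`.
2. Perfusion negative anywhere; any sample above 130 mL/hg/min; any 5-min
   rolling mean (full windows only) above 95 mL/hg/min.
3. ICP negative anywhere; or above 100 mmHg continuously for more than
   5 min, evaluated on 1-s averaged ICP, a run being broken by any sample
   at or below 100.

QC never raises on data content; every violated rule is reported with its
offending time ranges. A `probe_quality` field is carried through for
cohorts with probe diagnostics but no semantics are imposed on it.

## Synthetic data: what it emulates, what it does not

The generator exists because the motivating clinical dataset is
access-restricted; it makes every downstream stage testable with known
ground truth.

* **ABP** (125 Hz): mean level (default 90 mmHg) + slow fluctuations +
  cardiac pulse train (half-sinusoid systolic upstroke over 30% of the
  beat, exponential diastolic decay with time constant 0.2 beats;
  peak-to-trough amplitude = pulse pressure, default 40 mmHg) + Gaussian
  noise (sd 1 mmHg).
* **Slow variability**: three sinusoids with periods drawn one per
  disjoint band (60–120, 150–300, 380–600 s) carrying 90% of the variance,
  plus an AR(1) drift (φ = 0.98 at 1 Hz) carrying 10%; total sd is the
  `slow_fluctuation_scale` (default 5 mmHg). The band separation prevents
  beat envelopes slower than the coupling schedule, which would unbalance
  the zero-net construction. This spectral content roughly occupies the
  slow-wave band the index windows average over.
* **ICP** (125 Hz): mean level (default 12 mmHg) + 0.2 × the ABP slow
  component (so PRx is exercised over its range) + independent slow
  variability + noise (sd 0.5 mmHg).
* **Perfusion** (1 Hz): `baseline + gain(t)·(CPP − mean CPP) + noise`,
  baseline 30 mL/hg/min with seeded per-epoch baseline/scale jitter
  emulating probe-placement heterogeneity, noise sd 2 mL/hg/min. The gain
  schedule encodes the regime: constant +1 (pPFR), constant −1 (nPFR), or
  ±1 alternating in equal 15-min blocks (zPFR). With the default
  fluctuation scale the coupling signal is roughly twice the perfusion
  noise sd at 1 Hz. No quantitative coupling magnitudes or noise levels
  are available for the motivating cohort; these defaults are
  calibration-free choices.

Not emulated: mechanistic CA control laws, respiration- and
ventilation-coupled waveforms, sensor drift, intervention responses, and
the nonlinear, probe-location-dependent relation between local perfusion
and global flow. Passing the recovery tests therefore shows that the
pipeline identifies the coordination structure it is pointed at under
realistic noise and gap patterns — not that real cohort percentages would
be reproduced, which restricted data access precludes checking at desk
scale.

## Regime-level statistics

* **2-D two-sample KS**: the quadrant statistic — the maximum over the four
  open quadrant orientations anchored at every point of both samples of the
  absolute difference in empirical quadrant probabilities. The citation
  trail for the test does not pin a construction, so this standard
  assumption-light form was chosen; p-values come from seeded label
  permutations (default 999; at least 100 enforced), with the 1-D
  asymptotic approximation at the effective sample size available as an
  option. The observed statistic is computed in float64; the permutation
  distribution in float32 (error ~10⁻⁷, immaterial to a permutation rank).
* **Impairment boundary** `Mx = c·(1 − PRx)`: grid search `c ∈ [0, 1]` in
  steps of 0.01 maximizing balanced accuracy of `pPFR ⇔ Mx > c·(1 − PRx)`,
  ties toward smaller `c`; a density-difference variant is available. The
  default `c = 0.43` generalizes the independent single-index thresholds
  (≈0.3) for impaired autoregulation; such coefficients depend on the
  index windowing and should be refit per window scheme.
* **Group comparisons**: per variable and group pair, 1-D two-sample KS
  (flagged at p < 0.005) and Welch t-test (flagged at p < 0.05), with
  medians and quartiles; thresholds are used uncorrected by default, with
  a Bonferroni option.
* **Predictor ranking**: ARD via Gaussian-process regression with an
  anisotropic squared-exponential kernel plus white noise; one length scale
  per predictor is learned by marginal-likelihood optimization and
  importance is the reciprocal scale (fits are subsampled to 400 points for
  cubic-cost control). Lasso/Ridge at cross-validated penalties rank by
  absolute standardized coefficient and serve as robustness checks.
  Constant predictors receive zero importance with a warning.

## Numerical and design notes

* Block averaging: non-overlapping `[k·w, (k+1)·w)` bins on the absolute
  time axis, block value = mean of non-NaN samples, all-NaN blocks stay
  NaN; idempotent at the native block width.
* Degenerate inputs: constant CPP leaves `α₂` unidentifiable — it is
  returned at its prior with a flag; zero-variance signals are a hard
  error for standardization and yield NaN index windows.
* Problem sizes in the test suite and acceptance script (2-h epochs;
  50–100 seeds per recovery property; 100–500 KS replicates at n = 200
  with 999 permutations; 15–50 ranking seeds at n = 300) were chosen to
  keep the full run at desk scale while leaving the binomial error of
  every estimated rate well inside its asserted margin.
* Determinism: every stochastic component takes an explicit seed; the
  generator derives independent streams per channel from the spec seed, and
  the pipeline derives per-stage seeds from a master seed by fixed offsets.
  The run manifest records the config hash and output digests so re-runs
  can be compared byte for byte.

## Known limitations

* The inversion's regularization scheme is a declared concrete choice
  satisfying the stated constraints (1-min stationarity, non-negativity,
  smoothness); other estimators satisfying the same contract would differ
  in their `α` trajectories while leaving the scale-free classification
  slope essentially unchanged.
* Linear flow-to-perfusion calibration is by design; the true relation is
  nonlinear and probe-dependent, and nonlinear calibration is out of scope.
* The zPFR construction equates "no net coordination" with a balanced
  alternating schedule; real decoupling by functional autoregulation need
  not look like that.
* Cohort headline numbers from the motivating study (regime percentages,
  index-cloud separation, group means) are not reproduction targets: they
  derive from restricted patient data.
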
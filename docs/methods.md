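# Methods

## Scope and workflow

`ceftripk` reanalyzes a pediatric ceftriaxone pharmacokinetic study design:
24 hospitalized children (1 month to <18 years) receiving IV bolus
ceftriaxone 50–100 mg/kg every 12–24 h, with exactly three trough plasma
samples per patient drawn from different dosing intervals, each assayed for
total and free (unbound) drug by HPLC with an LLOQ of 2.5 µg/mL.  The
pipeline mirrors that study's workflow:

1. load (or simulate) the cohort tables;
2. replace below-LLOQ observations with LLOQ/2 (Beal M5);
3. fit one- and two-compartment IV bolus models by maximum likelihood with
   multiplicative error and compare them by AIC/BIC;
4. simulate each patient's noise-free concentration–time profile from the
   fitted parameters and run noncompartmental analysis (NCA) on that
   profile — not on the three raw troughs;
5. compute renal-function and protein-binding metrics and their
   regressions;
6. compute %fT>MIC target attainment and cohort summaries.

Units throughout: hours, µg/mL (≡ mg/L), mL, mL/h, mg doses,
mL/min/1.73 m² for eGFR.

## Structural and error models

One-compartment IV bolus with first-order elimination, by superposition
over the dose history:

    C(t) = Σ_{t_i ≤ t} (D_i·1000/V) · e^{−k (t−t_i)},   k = CL/V.

The two-compartment alternative uses the standard macro-constant
biexponential (central volume V1, peripheral V2, inter-compartmental flow
Q; α > β > 0).

Observation error is multiplicative: C_obs = C_pred·exp(ε), ε ~ N(0, σ²) —
equivalent to additive Gaussian error on log concentration.  For fixed
structural parameters the MLE of σ² is RSS/n on the log scale, so point
estimation is nonlinear least squares on log C, performed in log-parameter
space (trust-region reflective, wide bounds 10⁻³–10¹², tolerances 10⁻¹⁵
for per-subject fits and 10⁻¹⁰ for pooled fits) from a moment-based
initial plus four log-normally jittered restarts under a seeded generator.
The profiled deviance is −2LL = n·(log 2πσ̂² + 1).  When a fit is exact
(σ̂ → 0) the variance is floored at 10⁻²⁰ to keep the criteria finite; the
fit is flagged.

### Parameter accounting for AIC/BIC

AIC = −2LL + 2k and BIC = −2LL + k·ln n hold as invariants on every fit.
For per-subject fits k = (#structural) + 1 residual term.  "Population"
estimation is implemented as naive-pooled ML (one parameter vector, each
patient keeping their own dose history) plus per-subject fits; for pooled
fits k counts structural parameters, one between-subject variance term per
structural parameter, and one residual term — 1-compartment k = 2+2+1 = 5,
2-compartment k = 4+4+1 = 9, with n the pooled observation count (72 for
24 patients × 3 troughs).  This accounting reproduces the reference
study's printed AIC exactly and BIC to within 10⁻³ from its printed
deviances.  Full nonlinear mixed-effects estimation (FOCE, η/ε-shrinkage)
is deliberately out of scope.

### Identifiability of trough-only designs

Three troughs taken at the same time-after-dose at steady state are a
single degree of freedom: V and CL enter only through the common trough
level, and the per-subject likelihood is flat along a (V, CL) ridge.  The
synthetic generator therefore places troughs in dosing intervals 1, 2 and
one random later interval — sampling during accumulation restores
identifiability, and with no noise the per-subject fits recover (V, CL) to
optimizer precision (<10⁻⁶ relative, measured ~10⁻¹⁴).  At 10% assay noise
the 3-point design remains fragile: a few subjects per cohort land on a
degenerate flat-curve optimum (k → 0, CL at its bound), the classic
pathology that population pooling exists to fix.  This behaviour is left
visible in the analysis scripts; the quantitative recovery claims (median
|bias| of CL and V < 5%) are made, and verified, under rich sampling
(six early post-dose samples plus the troughs), where they hold with
margin.

## Noncompartmental analysis

Terminal slope λz: log-linear regression over candidate tails (the last
3..m positive points, never including the Cmax point), keeping the subset
with the highest adjusted r² and breaking ties within 10⁻⁴ toward more
points.  Integration is linear-up/log-down by default (log trapezoids are
exact on exponential decay; plain linear is available and over-estimates
on convex decays).  AUC∞ = AUC_last + C_last/λz;
MRT = (AUMC_last + C_last·t_last/λz + C_last/λz²)/AUC∞;
CL = 1000·dose/AUC∞; Vss = CL·MRT; t½ = ln 2/λz.  C0 is the exponential
back-extrapolation through the first two positive samples and is flagged
if it falls below Cmax.  On mono-exponential profiles Vss equals V and
t½ equals ln 2·V/CL to well under 0.5%; the reference study's printed
per-patient t½ values do not satisfy that identity against its printed
Vss/CL and are therefore carried as data, never used as oracles.

## Renal function, binding, PK/PD

* eGFR: bedside Schwartz, 0.413·height(cm)/Scr(mg/dL); full precision kept
  internally, one decimal for table parity.
* Average unbound fraction per patient: 100·CL_total/CL_free (free drug is
  the only fraction cleared); per-sample observed fu: 100·C_free/C_total,
  reported as a per-patient range.  Values above 100% are flagged, not
  rejected.
* Regressions (CL vs eGFR, covariate analysis) are ordinary least squares
  with exact t-based two-sided p-values; log-log transform available for
  allometric body-weight effects.  Zero-variance responses return slope 0,
  r² 0, p 1 by convention.
* %fT>MIC over one steady-state interval τ, for MIC 0.5/1/2 mg/L and
  thresholds 60%/70%.  One-compartment closed form:
  Css,max = (D·1000/V)/(1−e^{−kτ}), %fT>MIC = 100·min(τ, ln(fu·Css,max/MIC)/k)/τ
  (100% if even the trough exceeds MIC, 0% if the peak does not reach it);
  two-compartment models accumulate numerically with a 20-terminal-half-life
  burn-in and integrate on a dense grid.  The closed form agrees with grid
  counting to <0.001 percentage points.

## Assay validation arithmetic

Calibration is OLS of mean peak area on nominal concentration
(2.5–100 µg/mL in the reference assay); σ is the standard error of the
intercept, LOD = 3.3σ/S and LOQ = 10σ/S.  With only two calibration points
the line is exact but σ is undefined (zero residual df); the fit carries a
flag instead of fabricating a value.  Intra-day CV% is the mean of
within-day CVs; inter-day CV% pools all replicates across days
(sd/grand mean); recovery% = 100·grand mean/nominal — the reference text
names these metrics without formulas, so the conventional definitions are
used and stated here.  System suitability follows USP conventions:
N = 16(tR/W)², HETP = L/N, tailing = W₀.₀₅ₕ/(2f), Rs = 2(tR₂−tR₁)/(W₁+W₂).
BLOQ handling is Beal M5 — every censored sample becomes LLOQ/2, per
sample, idempotently; samples exactly at the LLOQ are not censored
(strict <).  The LLOQ defaults to the lowest calibration level.

## Synthetic cohort generator

The generator emulates the study conditions and returns ground truth for
recovery testing.  Defaults (chosen once, from the study's stated design
and the field's typical values for this drug and population):

| parameter | default | rationale |
|---|---|---|
| n_patients | 24 | study size |
| age | U(2.5, 144) months | study range |
| weight, height | crude growth curves of age × log-normal jitter, clipped to 1.7–37 kg | study range |
| dose | U(50, 100) mg/kg | study regimen |
| interval | 12 or 24 h | study regimen |
| duration | U{5..21} days | study range |
| troughs | 3 per patient at (next dose − 0.25 h) | study design; offset is a stated convention |
| CL_total | 35 mL/h/kg × e^N(0, 0.40) | ≈ study median CL / median weight |
| V_total | 500 mL/kg × e^N(0, 0.35) | ≈ study median Vss / median weight |
| assay noise | multiplicative, CV 10% | matches the fitted multiplicative error model |
| LLOQ | 2.5 µg/mL | lowest calibration level |
| albumin | U(1.8, 4.6) | study laboratory range |
| binding | fu = 1/(1+κᵢ·albumin), κᵢ = 0.8·e^N(0, 0.7) | see below |

Binding: the study reports fu varying with albumin *and* illness but no
functional form.  A saturable-binding-like form fu = 1/(1+κ·albumin) with
a log-normal between-subject factor on κ is a modelling choice of this
package, calibrated once so the defaults span the observed 9.6–67% fu
band; a single κ cannot span that band over a realistic albumin range,
consistent with the clinical claim that critical illness raises fu beyond
what albumin explains.  Free concentrations are fu × the true total
concentration with independent multiplicative noise, so observed
free/total ratios scatter around fu with ≈ CV·√2 spread.

Per-patient RNG substreams are keyed by (seed, patient index): patient i
is bit-reproducible regardless of cohort size.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: no renal–clearance coupling (creatinine and
CL are drawn independently, so the in-vivo CL_free–eGFR correlation is not
reproduced), no maturation/allometric exponents beyond weight
proportionality, no within-patient parameter drift over the treatment
course, no correlated assay errors between analytes, and no dosing-history
irregularities (missed/late doses).

## Numerical conventions and edge cases

* Median of an even-sized column is the midpoint of the two central values.
* Results CSVs are written at 6 significant digits; write→read is the
  identity at that precision; median/min/max summary rows are appended.
* Prediction at times before the first dose is 0 (defined, not an error).
* λz estimation requires ≥3 positive post-peak points and a negative slope
  on at least one candidate subset.
* Compound indications ("Meningitis, Gastroenteritis") are their own
  category in breakdowns.
* Albumin is stored as printed in the source table (header g/L, reference
  range in g/dL convention); the hypoalbuminemia threshold is configurable.
* The three paired liver-panel tests report raw p-values (as the reference
  study did); Holm adjustment is available behind a flag, default off.

## Problem sizes

Default qualification studies: 20 seeds × 24 patients for noisy recovery
(rich sampling), 20 seeds for each model-selection rate, 145-point dense
grids for the NCA oracle, 25 random regimens × 200k-point grids for the
%fT>MIC check.  These sizes give Monte-Carlo error comfortably below the
asserted margins while keeping the full suite in the low minutes on one
core.

## Known limitations

* Naive-pooled "population" fitting is not FOCE; between-subject
  variability inflates σ̂ instead of being partitioned, and shrinkage
  diagnostics are not produced.  The k-accounting above restores
  information-criteria comparability, not the mixed-effects estimates.
* Per-subject fits of 3-trough data under noise can be weakly identified
  (see above).
* The reference study's printed CL/eGFR column and its CL_free–eGFR
  regression coefficients are dimensionally ambiguous in the source and
  are carried as data with a caveat, not reproduced.
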
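# Methods

## Kinetic model and estimands

After an IV pulse of dose *D* (μmol) of a stable tracer, the plasma
tracer-to-tracee ratio decays as a sum of two or three exponentials.
Amplitudes are in TTR units and rate constants per hour; sampling times
enter in minutes (the protocol unit) and are converted at the API
boundary, so AUCs come out in TTR·h and WBP in μmol/h.

* **WBP** = D / AUC, with AUC the *analytic* integral of the fitted model
  over the fixed 10–120 min window — not a trapezoid over the raw points.
  The non-compartmental interpretation is the rate of appearance of the
  amino acid into plasma.
* **Clearance** = WBP / plasma concentration. We apply this formula
  verbatim. Note that for typical WBP (~3500 μmol/h) and concentration
  (~50 μmol/L) it yields clearances of order 70 L/h; published cohort
  tables sometimes print values of order 1–2 L/h for the same quantity,
  which would imply an additional normalization (e.g. per kg fat-free
  mass) that is not part of the stated formula. The package computes the
  stated formula and leaves any normalization to the caller.
* **Conversion flux** (substrate → product) = WBP_product ×
  AUC(product tracer after the substrate pulse) / AUC(substrate tracer).
  A two-pool mass-balance oracle (forward ODE simulation in the test
  suite) confirms this estimator returns f × WBP_substrate when a
  fraction f of substrate disposal is routed to the product, which is the
  identity the design relies on. The formula is isolated in
  `compute_conversion` so an alternative algebra can be swapped in.

## Decay fitting

Bounded least squares (`scipy.optimize.least_squares`, trf) on the
untransformed residuals, all parameters bounded below by ~0 so
non-negativity is structural rather than clipped. Initialization is by
curve peeling — log-linear fit of the tail gives the slowest phase,
which is subtracted before the next phase is estimated — with rates
clamped to the window the sampling design can identify (≈5/t_first).
Because peeling can still start the optimizer near a poor local minimum
on steep curves, a small deterministic set of fallback starts is also
tried: fixed rate patterns scaled to the sampling span, with amplitudes
from non-negative linear least squares (the model is linear in the
amplitudes given rates). The best SSE wins; iteration stops early when
the residual reaches the machine floor. Fits report `converged=False`
with best-effort parameters rather than raising.

Model order: order 2 is always fitted; order 3 additionally when the
series has ≥ 6 points (6 parameters need at least that many
observations). Selection is by AICc, with fallback to order 2 when the
order-3 fit fails to converge or violates the parameter invariants
(positive amplitudes, strictly ordered positive rates). For AICc on
noiseless data the SSE is floored at n·(10⁻¹²·max|y|)² so the comparison
is deterministic rather than driven by which fit's rounding error is
smaller. Weighted (1/y) least squares is available but off by default;
the unweighted objective matches the additive-residual convention of
standard non-compartmental practice.

## Synthetic cohort

The generator emulates a two-group COPD study: group sizes default to
51 CN / 27 CD, ages uniform on 46–76 y, BMI normal per group (means
29.1 / 31.7 kg/m², SDs back-calculated from typical cohort CIs), HADS-D
scores drawn consistently with the ≥ 8 stratification rule, and a
nine-tracer pulse panel (Phe, Tyr, Trp, Leu, Ile, Val, Arg, Cit, Orn)
sampled at 10/20/30/60/120 min.

Per subject and tracer, true concentration and WBP are drawn lognormally
around typical CN means (between-subject CV 0.20), covariate effects are
added linearly on the endpoint scale, and CD values are then scaled by
the configured group-effect multipliers (defaults follow the direction
reported for depressed COPD: lower BCAA/aromatic concentrations, mildly
higher production; magnitudes are configuration). The decay shape is
drawn (k1 ∈ [3, 9] h⁻¹, k2 ∈ [0.3, 1.2] h⁻¹, amplitude ratio ∈ [2, 6])
and the amplitudes are rescaled jointly so that dose / analytic window
AUC equals the drawn WBP exactly — the truth is consistent with the
estimand to < 10⁻⁹ relative by construction. Doses default to ≈ 5% of
hourly turnover, placing TTRs in the 0.01–0.1 range typical of pulse
designs.

Secondary (conversion) enrichment series are generated as positive
2-exponential decays with slower rates, rescaled so their window AUC is
exactly consistent with the configured transfer fraction through the
estimator identity. This sidesteps the rising-then-falling shape a true
two-pool secondary curve has before its peak; over the 10–120 min
analysis window the decaying tail is the identifiable part, and the
simplification keeps every generated series inside the
positive-amplitude model family the fitter estimates. The two-pool
physics itself is verified independently by the ODE oracle test.

Measurement noise is multiplicative Gaussian on TTR (error scales with
enrichment), CV 3% by default — a placeholder for an unreported assay
CV, exposed in `CohortConfig.noise_cv`. Values are clipped to stay
positive. What the generator does **not** emulate: assay drift or
correlated residuals within a curve, isotopomer-correction artifacts,
non-steady-state tracee pools, missing samples, and any real covariance
between clinical covariates and kinetics beyond the configured linear
slopes. Passing tests therefore demonstrate correctness of the
estimators and calibration of the statistics under the stated model, not
robustness to those real-data features.

## Statistical pipeline

Order of operations per endpoint: D'Agostino–Pearson normality test
(scipy's `normaltest`; samples < 8 are "untestable" and proceed
untransformed) → natural-log transform when normality fails and all
values are positive (retested; still-non-normal endpoints proceed on the
ln scale with a warning status; non-positive endpoints proceed
untransformed with a warning) → ROUT outlier removal per group, applied
only when normality was confirmed on the analysis scale → ANCOVA →
BH-FDR. The ordering for transformed endpoints (ROUT on the confirmed
scale) is a design choice; the steps themselves are standard.

**ROUT** (constant model): robust location by IRLS with Lorentzian
weights; robust residual SD from the 68.27th percentile of absolute
residuals with the n/(n−K) small-sample correction (K = 1); per-point
two-tailed p from the t distribution (df = n−1); detection by
Benjamini–Hochberg at rate Q (default 5%). Measured behaviour: a 10-SD
contaminant in n = 21 is caught essentially always; clean Gaussian
datasets receive at least one false flag in ≈ 5–6% of cases, i.e. the
procedure is approximately calibrated at Q with a slight liberal bias
from the noisy scale estimate. Samples below n = 10 are never trimmed.

**ANCOVA**: OLS of the (possibly ln) endpoint on an intercept, a CD
indicator and the covariates (default age, BMI); the group coefficient,
its 95% CI and p-value are reported. Listwise deletion for missing
covariates; singular designs raise an explicit model error. The
"estimated difference" column follows the unadjusted unpaired-t-test
convention on the raw scale (matching how such tables are usually
printed), while the covariate-adjusted difference is emitted alongside;
for transformed endpoints the p-value comes from the transformed model.

**FDR families**: endpoints sharing a prefix (concentrations, WBP,
clearances, conversions) form one BH family each, configurable via
`StatsConfig.families`. The categorical comparison is Fisher's exact
test (two-sided) by default — the convention that produces the "> 0.999"
p-values seen in balanced yes/no tables — with chi-squared as an option.

## Derived phenotype quantities

sumBCAA = Leu + Ile + Val; sumLNAA = sumBCAA + Tyr + Phe + Trp. The
LNAA "correction" of tryptophan or tyrosine is implemented both as a
competitor ratio (amino acid ÷ (sumLNAA − itself), the blood–brain
barrier competition reading; an inclusive-denominator variant is an
option) and as an ANCOVA with sumLNAA added as a covariate — the default
analysis path uses the covariate form. HOMA-IR uses the standard
glucose[mmol/L] × insulin[μIU/mL] / 22.5; note that a cohort's mean HOMA
is the mean of per-subject indices, not the formula applied to group
means. GOLD stages use the universal FEV1 %predicted cut-offs
(≥80 / 50–79 / 30–49 / <30). Leg-endurance decline is
(mean of first 3 − mean of last 3) / mean of first 3 over a 30-repetition
series, negative when force rises.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng(seed)`; identical
configuration and seed give byte-identical CSV output (numbers
serialized with `%.10g`). Problem sizes in the validation harness — 200
curves for recovery, 2000 ANCOVA replicates, 6 simulate→fit→analyze
replicates of 15+15 subjects over a five-tracer panel for the
global-null FDR check, 500 ROUT replicates — were chosen to keep
Monte-Carlo error a small fraction of the quantities being checked while
the whole harness runs in about a minute on one core.

## Known limitations

* The fitted model assumes the tracee pool is at steady state over the
  2-h window; no compartmental or plateau-infusion math is provided.
* Clearance is not normalized to body composition (see above).
* The exact algebra behind the conversion-flux AUC ratio is the one
  identity the two-pool oracle validates; alternative conventions
  (e.g. substrate-dose scaling) would need a one-line change in
  `compute_conversion`.
* ROUT is implemented for the constant (single-sample) model only, which
  is what per-endpoint group screening needs; it is not a general
  robust-regression outlier tool.
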
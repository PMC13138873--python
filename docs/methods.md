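# Methods

## Structural and statistical model

Isavuconazole concentrations are described by a one-compartment model with
first-order absorption (ka fixed at 2.5 h⁻¹, giving a time-to-peak of
~2.6 h at base-model parameters CL 2.2 L/h, V 550 L) and linear
elimination; oral bioavailability is fixed at 1 (IV and oral data showed no
difference).  Interindividual variability (IIV) is log-normal on CL and V;
BMI enters V linearly on the normalized scale, V_i = TVV·(BMI_i/25)·e^{η_V}.
Residual unexplained variability is mixed:
y = f·(1+ε_p) + ε_a with Var(y|η) = f²σ_p² + σ_a².

Default parameter values (the "final model" used throughout the analyses
and simulations): TVCL 2.3 L/h, ω_CL 0.37, TVV 523 L, ω_V 0.34, σ_p 0.19,
σ_a 0.73 mg/L.  An ω printed as "CV%" is interpreted as 100·ω on the
log-SD scale (37% ⇒ ω = 0.37); the alternative √(e^{ω²}−1) convention
differs by <2% at these magnitudes and can be adopted by passing the
converted value.

Closed forms: superposition over the dosing history for oral doses, IV
boluses and zero-order infusions; steady-state trough
C_min,ss = F·D·ka/(V(ka−ke))·[e^{−keτ}/(1−e^{−keτ}) − e^{−kaτ}/(1−e^{−kaτ})];
AUC_τ = F·D/CL; t_max = ln(ka/ke)/(ka−ke); t½ = ln2·V/CL.  Long once-daily
histories are evaluated by geometric-series sums over uniform dosing blocks,
which is algebraically identical to per-dose superposition (property-tested)
but costs O(observations) instead of O(observations × doses).

## Estimation

The population objective is OFV = −2·Σ_i log ∫ p(y_i|η) p(η) dη.  The inner
integral is approximated by Laplace at the per-subject posterior mode:
OFV_i = G(η̂) + ln|Ω| + ln det(H_G(η̂)/2), where G is the joint −2 log
density and H_G its Hessian.  The mode search is a damped Newton iteration
run for all subjects simultaneously (finite-difference stencils evaluated
in one broadcast pass), seeded from a coarse η grid because sparse-data
posteriors can be multimodal; subjects whose iteration stalls are polished
with a simplex search, and the log-determinant uses eigenvalue flooring at
10⁻³ of the prior curvature so saddle-point evaluations at poor trial
parameters stay finite.  Setting `agq_nodes > 1` replaces the Laplace
integral with adaptive Gauss–Hermite quadrature centred at the same mode
(nodes = 1 reproduces Laplace exactly); with 7–9 nodes per dimension the
marginal likelihood agrees with 2-D adaptive quadrature to <0.01% on sparse
test subjects, versus ~0.8% for plain Laplace.  Fits use the fast Laplace
path; the quadrature refinement exists for verification and for users who
want tighter integrals.

Outer optimization runs Nelder–Mead on log-transformed parameters
(covariate-effect exponents stay on the raw scale) with an explicit initial
simplex (step 0.25) — the scipy default step for a coordinate at exactly 0,
as a fresh covariate effect is, is ~2.5·10⁻⁴ and cannot escape the
no-effect region — followed by a fresh-simplex restart to guard against
premature collapse, and optional multi-start (3 jittered starts by
default; the heavy simulation-study tests use a single start from a
deliberately misplaced starting model).  Standard errors come from the
finite-difference Hessian of the OFV (Cov = 2H⁻¹); for log-scale parameters
the SE of log θ is reported directly as RSE%.

Model selection: likelihood-ratio thresholds use χ² quantiles rounded to
the conventionally printed two decimals (3.84 at df 1 forward, 6.63
backward) so the inclusive boundary ΔOFV ≤ −3.84 behaves as printed.
Non-nested models are compared by an AIC decrease of ≥2.  CWRES are
computed by first-order conditional linearization around the empirical
Bayes estimates, whitened with the symmetric inverse square root of the
marginal covariance; |CWRES| > 3 flags outliers.  η-shrinkage is
100·(1 − SD(EBE)/ω) with the population (ddof = 0) SD.  The nonparametric
bootstrap resamples subjects with replacement and reports per-parameter
medians with percentile CI95 (default 2000 replicates; tests use far
fewer).

The stepwise covariate engine tests power-on-normalized,
linear-centered and categorical (exp(θ·x)) forms, centring continuous
covariates on the cohort median; forward inclusion takes the best ΔOFV
first at p = 0.05, backward deletion removes relations whose deletion
costs ≤6.63 points, and the variance reduction of each retained relation's
IIV term is reported.

## MAP-Bayes exposure

Individual η's are posterior modes given all of a subject's observations;
with none, the prior mode (typical values) is returned.  Exposure on an
evaluation day uses the dosing history in force: C_min is the model
concentration at the next scheduled dose time, AUC is the daily dose
divided by individual CL.  Subjects without a measurement within 50 days
of the evaluation date (inclusive, date arithmetic in hours) are excluded.
For the virtual TDM study a vectorized variant solves all 10,000
single-trough MAP problems at once, seeded by a 1-D scan over η_CL (the
steady-state trough is monotone in CL).

## Virtual TDM study

10,000 virtual patients at steady state on 200 mg once daily: BMI uniform
on (12, 40) kg/m², η's from their log-normal distributions, and (CL, V)
pairs rejected and redrawn when the implied half-life leaves the
plausibility window — default (40, 400) h around the typical 158 h; the
window is configurable because the observed range behind it is not
published, and the acceptance property checks that attainment moves ≤2
points when the window is widened to (30, 500) h.  Each patient gets one
noisy trough C_min,RUV = C_min·(1+ε_p)+ε_a (non-positive draws redrawn).

Dose adjustment follows routine TDM practice: the dose changes **only when
the monitored estimate falls outside the therapeutic range** (trough
2.5–5.0 mg/L, AUC 60–233 mg·h/L).  When it does, the proportional rule
targets the geometric mean of the range (√(2.5·5.0) = 3.54 mg/L,
√(60·233) = 118.2 mg·h/L) and rounds to the nearest allowed dose among
{100, 200, 300, 400} mg, exact midpoints breaking to the lower dose
(safety).  The conditional trigger is a deliberate design choice: an
unconditional proportional rule over-treats patients already in range and
produces materially different attainment (e.g. ~99% instead of ~89% AUC
attainment after AUC-guided MIPD, and a 7-point rather than 2-point gap
between proportional and MIPD trough strategies); the conditional policy
reproduces the published simulation behaviour and is what a TDM service
actually does.  It is switchable via
`TdmStrategy(adjust_only_outside_range=False)`.

Strategies: `proportional_cmin` applies the rule to the noisy trough
itself; `mipd_cmin`/`mipd_auc` first compute the MAP-Bayes individual
estimate from that single trough and apply the rule to the Bayes-predicted
trough or AUC.  One measurement, one adjustment cycle.  After re-dosing,
true exposures rescale linearly with dose (the model is dose-linear) and
attainment is summarized with inclusive bounds.

## Synthetic cohort generator

The generator emulates the study conditions: 41 subjects by default;
samples per subject from a fixed pmf on 1–11 with median 4; daily doses
drawn from {100, 200, 300, 400} mg weighted toward 200; treatment courses
of 28–55 days starting with an IV (1-h infusion) lead-in covering ~20% of
treatment days so ~80% of samples fall under oral dosing; sampling days
uniform over the course with 80% troughs (23.75 h post-dose) and the rest
1–8 h post-dose.  Covariates are drawn once per subject to match the
published cohort's medians and ranges (BMI log-normal around 24 kg/m²
clipped to 12–40; age, height, sex, creatinine, bilirubin, albumin, liver
enzymes similarly); eGFR uses the 2009 CKD-EPI equation in its published
table form (creatinine/88.4 to mg/dL; sex-specific κ, α; no race term).
Only BMI carries a true effect — the other covariates exercise the
stepwise engine's type-I behaviour.  Outcome labels: treatment success
~ Bernoulli(logistic(−2.14 + 1.5·ln C_min,true)), calibrated to ≈43%
success at the cohort's exposure distribution; hepatotoxicity is
exposure-independent at 28% with discontinuation in 24% of toxic subjects
(a null toxicity model, matching the absence of an exposure–toxicity
association).

What the generator does **not** emulate: time-varying covariates within a
course, dose changes during the course, centre-3-style time-imputation
error (represented only by an `imputed` flag), drug–drug interactions, and
saturable protein binding.  Passing tests therefore demonstrate that the
machinery is correct under the stated generative model, not that the fitted
numbers would reproduce on the original hospital data.

## Validation metrics

MPE(%) = 100·(exp(mean(ln DV − ln IPRED)) − 1) and
RMSE(%) = 100·√(exp(mean((ln DV − ln IPRED)²)) − 1), with the MPE CI95
from a Student-t interval on the log differences, back-transformed the
same way.  Note that RMSE ≥ |MPE| holds on the log scale but not after
back-transformation (all pairs at ratio 1.5 give MPE 50%, RMSE 42%).  The
pcVPC multiplies each observed and simulated value by (bin-median
population prediction / own population prediction), bins by time after
dose with ~equal counts (default 10 bins; empty bins are dropped with a
warning), and overlays observed 5/50/95th percentiles on simulation CIs.

## Problem sizes and numerical choices

Simulation studies in the test suite use 10,000 virtual patients (the
study's own size; Monte-Carlo SE on a percentage ≈0.5 points), 200-subject
cohorts × 20 replicates for parameter recovery, and 150-subject cohorts ×
10 replicates for covariate-selection consistency — sizes chosen so each
property is decided by its statistical tolerance rather than by run-to-run
noise.  Inner Newton tolerance 10⁻⁷ on the gradient, step cap 2.0,
η capped at ±12; outer Nelder–Mead xatol/fatol 10⁻³ on the log scale.
Exposure-response regressions use statsmodels' Logit MLE with
likelihood-ratio p-values (robust at small n; Wald would be the
alternative); complete separation is reported as such with no p-value.

## Known limitations

The estimator is a Laplace-family approximation, not a full FOCE-I
re-implementation; numeric equality with other software's estimates is not
claimed.  At very sparse, trough-heavy designs with wide IIV the
approximated marginal likelihood retains some mode-search roughness, and
Hessian-based RSEs can be optimistic there; the bootstrap CI95 is the
reliability measure of record for such fits.  ω_V is weakly identified under trough-heavy sparse designs (the
fitted cohort shows ~50–60% η_V shrinkage), and its estimate carries a
downward finite-sample bias of order 15% at 200 rich-sampled subjects.
Inter-occasion variability, multi-cycle adaptive TDM, loading-dose
modelling and protein-binding corrections are out of scope.
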
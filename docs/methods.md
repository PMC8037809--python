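# Methods

## Scope and model

The package estimates blood–brain-barrier permeation, expressed as
logBB = log10(C_brain/C_blood), by two complementary routes and reconciles
them per compound:

1. **QSAR route.** An affine model over three molecular descriptors,
   `logBB = b0 + b1·ΔlogP + b2·lipophilicity + b3·E`, shipped with the
   literature coefficients (−0.114, −0.098, 0.278, 0.218). ΔlogP
   (= logPow − logPcw) captures hydrogen-bonding capacity, the lipophilicity
   slot takes logPow or a chromatographic surrogate, and E is the Abraham
   excess molar refraction. Prediction is a pure affine map; no descriptor
   computation happens inside the package — descriptor tables are inputs.
2. **Biomimetic route.** Isocratic retention in three membrane-mimicking
   HPLC systems (IAM, CHOL, BMC) is converted to retention factors
   k = (t_R − t_0)/t_0, log10 k is regressed on the eluent composition, and
   the intercept is logkw — retention extrapolated to a pure-water eluent, a
   lipophilicity index substitutable for logPow in the QSAR equation
   (yielding labeled logBB-IAM / logBB-CHOL / logBB-BMC variants). For the
   micellar system the Foley linearization `1/k = (K_MA/(P_SW·Φ))·C_M +
   1/(P_SW·Φ)` additionally gives the analyte–micelle association constant
   K_MA = slope/intercept (Φ-free) and P_SW = 1/(intercept·Φ); log10 K_MA is
   treated as a logBB-like descriptor and enters the cross-method
   comparison as a correspondence, never through a calibrated conversion.

Assumptions: retention is log-linear over the studied composition ranges
(no quadratic term is offered); solutes are neutral at the working pH;
micellar retention follows the two-site Foley partitioning model; the QSAR
response is linear with homoscedastic Gaussian error.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| acetonitrile levels (IAM/CHOL) | 0.3, 0.4, 0.5, 0.6 | v/v fraction | the study's isocratic design |
| surfactant levels (BMC) | 0.075, 0.1, 0.125, 0.15 | mol/dm³ total | the study's micellar design |
| Brij35 CMC | 9.0×10⁻⁵ | mol/dm³ | documented literature default at 25 °C; override per run |
| phase ratio Φ | none | — | column-specific; deliberately no default, must be chosen explicitly |
| replicates per level | 3 | — | retention values are averages of ≥3 independent measurements |
| backward-elimination α | 0.10 | — | conventional removal threshold of the stepwise tooling used in this field |
| LTO fold size | 10 | rows | leave-ten-out; 30 training rows give three folds |
| AD threshold | h* = 3(p+1)/n | — | Williams leverage cut-off |
| permeability thresholds | ≥ 0 permeant, ≤ −1 non-permeant | logBB | brackets the reference compounds' values; configurable module constants |
| QSAR noise scale | 0.436 | logBB | the published model's residual standard error, used by the generator |

## Numerical choices

* **Replicate aggregation.** Replicates are averaged on the k scale before
  the log transform (how chromatographers average retention), with
  log-scale averaging available (`aggregate="log"`). k-scale averaging of
  log-normally distributed replicates biases log10 k upward by
  ≈ σ² ln10 (1 − 1/m)/2 — about 0.002 at σ = 0.05, m = 3 — negligible
  against fitting error but visible in large Monte-Carlo averages.
* **Line fits** (logk–composition, Foley 1/k–C_M) are unweighted OLS via the
  closed-form normal equations; the Foley fit deliberately stays on the
  reciprocal scale the linearization implies. A weighted variant is a known
  refinement (reciprocal transforms distort the error structure) and is not
  applied by default.
* **Non-physical Foley fits.** A fitted 1/k intercept ≤ 0 admits no
  P_SW > 0 and raises instead of returning a value; a negative slope yields
  a negative K_MA that is reported with an anti-binding warning, not
  clipped, so diagnostics stay honest.
* **Degenerate inputs.** <3 distinct levels → insufficient-data error; zero
  level variance → singular-design error; k ≤ 0 levels are excluded with a
  warning before the log transform; a constant response gives R² = 100%
  by the 0/0 → perfect-fit convention.
* **R²_pred** is computed on the held-out test split with the total sum of
  squares centred on the **training** mean (the external-validation Q²_F1
  convention); the centring is stated because conventions differ.
* **Rounding** of reported descriptor means is half-away-from-zero
  (−5.0333… → −5.03), matching how such averages are conventionally printed;
  rounding affects display only.
* **Bound-flagged logBB** (a value reported as "<−2") participates in
  classification at its bound but is excluded from numeric means: a bound is
  not a point estimate.
* **Ties** in extreme-value selection break by first occurrence.

## Backward elimination and its power

Elimination iteratively removes the predictor with the largest coefficient
p-value while that p-value exceeds α, refitting after each removal; if
everything is removed an intercept-only model is returned with a warning.
Because a true-null predictor's p-value is uniform on (0,1), the
probability that elimination removes it is exactly 1 − α whenever the
remaining predictors are clearly significant. The package's removal-rate
experiment therefore runs at a stringent α = 0.01 so that it measures what
can fail — whether the procedure removes the *null* descriptor rather than
a signal one — with the Type-I floor (the α-rate of keeping the null) held
at 1%. An exhaustive all-subsets oracle is shipped for cross-checking the
greedy path at p = 3.

## Synthetic-data generators

The generators emulate the statistical structure the estimators assume, at
the study's designs: four-level isocratic series with additive Gaussian
noise on log10 k (the scale on which the model is linear), four-level
micellar series with multiplicative noise on k, and 40-compound training
tables (30 train / 10 test) with descriptors drawn uniformly over the span
of the reference compounds (ΔlogP 1.17–21.0, logPow −3.7–5.2; the E range
1–8 is an order-of-magnitude choice, as no reference E values exist) and
logBB from the published coefficients plus noise at sd 0.436. Defaults for
the micellar truth (K_MA = 120 dm³/mol, P_SW = 40, Φ = 0.1) are a moderate
association regime typical of Brij35 systems.

What the generators do **not** emulate: correlated descriptors, replicate
drift, level-dependent retention noise, peak-integration error, column
ageing, or any structure–descriptor relationship (compounds are descriptor
vectors). Passing recovery tests therefore demonstrates estimator
correctness under the assumed error model, not robustness to real-data
pathologies.

## Recovery experiments (self-validation harness)

`bbbperm.recovery` packages the Monte-Carlo experiments used in the test
suite: logkw intercept recovery (2×1000 IAM/CHOL series at noise sd 0.05),
Foley K_MA recovery (1000 four-level series at 2% multiplicative noise;
the headline number is the relative error of the *median* estimate, since
with only four points the per-fit dispersion of the ratio slope/intercept
is large — ≥ ~15% relative sd even in favourable regimes — while the
median is nearly unbiased), MLR coefficient bias at the published noise
(1000 tables; |bias| under 2 Monte-Carlo standard errors), the
null-descriptor removal rate (500 seeds), and RMSECV versus the generating
noise (one table, 200 fold partitions). Problem sizes are chosen so the
whole harness runs in seconds while keeping Monte-Carlo error well inside
the asserted tolerances.

## Known limitations

* The logK_MA ↔ logBB correspondence is a reported empirical parallel; the
  package compares the two and never converts between them.
* No chromatogram processing: inputs begin at retention and dead times.
* The published model's own training data are not redistributed; its
  reported cross-validation statistics (R²_CV 78.25%, R²_pred 74.02%) are
  carried as metadata of `published_model()` and are not recomputed.
* Permeability calls are rule-based screening labels, not predictions of
  CNS activity; evidence items (TPSA, MW, logPow) never override the logBB
  rule.
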
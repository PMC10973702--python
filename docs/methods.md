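# Methods

This note records the models behind `sulcalml`, the assumptions they make,
the parameters that matter, and the choices taken where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The problem setting

The package targets case–control classification of whole-cortex sulcal
morphometry in the small-sample regime: two diagnostic groups of roughly 56–58
subjects, ~123 candidate cortical regions each contributing three measures
(length, mean depth, maximum depth), heavy attrition from automated sulcus
misdetection, and more features (147 after cleaning) than subjects (114).
Every design decision below follows from that regime.

## Synthetic cohort generator

Real sulcal tables from clinical cohorts are not publicly depositable, so the
generator is first-class, tested code, and its defaults are the study
conditions everything downstream is exercised under: 57 subjects per group,
49 usable regions × 3 measures = 147 features, ~15% long-tailed columns, and
within-region depth correlation 0.7.

The generative model per region:

- every column is marginally standard normal before contamination;
- the two depth measures share a latent factor: `meandepth = √ρ·g + √(1−ρ)·ε₁`,
  `maxdepth = √ρ·g + √(1−ρ)·ε₂`, giving correlation exactly ρ (default 0.7 —
  deep sulci are deep on both summaries); length is independent, as no
  length–depth coupling is assumed;
- a seeded subset of columns (fraction `heavy_tail_fraction`) receives an
  additive one-sided lognormal contaminant (scale 0.8, σ = 0.9, demeaned),
  strong enough that a Shapiro–Wilk test at n ≈ 114 rejects essentially
  always — these model the right-skewed features observed in real tables;
- group effects are planted as mean shifts of δ standard deviations of the
  contaminated column, so δ is always on the standardized scale;
- misdetections are region-level Bernoulli events: all three measures of a
  region go missing together, as when the labelling pipeline misses a sulcus;
- gross outliers are injected at ±(6–10) column SDs so the downstream
  exclusion rule has positive cases.

One master seed drives four fixed-offset substreams (base draws, heavy-column
choice, misdetection, outliers), so tables are bit-identical across runs and
changing one contamination channel does not reshuffle the others.

What the generator does **not** emulate: anatomical geometry or atlas
identity, spatial correlation between neighbouring regions beyond the depth
pair, site/scanner effects, or any relation between demographics and the
imaging features. Passing tests therefore certify the statistical machinery,
not anatomical validity on real cohorts.

The demographics generator rescales within-group draws affinely to the exact
target mean and SD, which makes summary-moment worked examples (e.g. a pooled
t of 1.93 on years-of-education moments) reproducible to rounding.

The true effect sizes of discriminative sulci in real data are unknown;
planted defaults (δ ≈ 1 at a handful of features) are calibration knobs
chosen to give the selection paths realistic, not saturated, power at
n ≈ 50–100 per group.

## Preprocessing cascade

Order is fixed and canonical:

1. drop subjects with **more than** 18 misdetected regions (strictly greater;
   the ~15%-of-regions gloss is commentary, the integer is the rule);
2. drop named regions (default: left/right insula, unreliable to detect);
3. drop any region with a residual misdetection among remaining subjects
   (misdetection = any NA among the region's three measures);
4. z-score each surviving column; sample (n−1) SD by default, configurable;
5. drop subjects with any |z| > 6, **without** re-standardizing.

Step 5 deliberately reuses the step-4 statistics: the ">6 SD" rule has a
single meaning, computed once on the post-exclusion cohort. Swapping steps 4
and 5 changes the outcome (the outlier inflates the SD it is judged against)
and the suite pins the chosen order with a fixture where the two orders
disagree. Whether normalization should precede or follow the named-region
exclusion is not determined by practice; the cascade above is declared
canonical and tested as such. No imputation is offered — misdetected sulci
are excluded, not filled in.

## Parametric selection path

Shapiro–Wilk at routing level α = 0.05 sends each feature to a pooled
two-sample t-test (Welch available) or a Mann–Whitney U (exact null
enumeration for tie-free groups under 20, normal approximation with tie
correction otherwise). Statistics are oriented control − case. Ranking is by
raw p-value with deterministic name tie-breaks; no multiple-testing
correction is applied by default, matching the raw-p ranking practice this
pipeline reflects (a Benjamini–Hochberg helper would sit naturally upstream
of `rank_features` but is intentionally not the default). The 2×2 Pearson
chi-square uses no continuity correction — with Yates' correction the
standard sex-by-diagnosis worked example (counts 35/23 vs 29/27 → χ² = 0.85)
is not reproducible.

## Classifier-based (proportion-test) path

Each feature alone is scored by a class-weight-balanced linear SVM under
resubstitution, corrected by the d = 1 concentration bound, averaged over
`n_permutations` balanced subsamples (equal class counts, size 2·min(n₀,n₁),
drawn without replacement). Pure order-shuffling would leave resubstitution
unchanged, so "permutation" here must mean re-drawing the balanced subsample.
π₀ is the mean of the bound-corrected accuracies; whether the reference
proportion should average corrected or uncorrected accuracies is ambiguous in
principle, so both modes exist (`apply_bound`), corrected being the default.
The p-value is the one-sided upper tail — relevance means sitting above the
average — and per-feature sub-seeds are fixed offsets of the master seed so
results do not depend on column order.

## PLS extraction

PLS1 via NIPALS with the binary label as the single response: unit-norm
weight vectors from the residual covariance `Xᵀy`, score deflation of both
blocks, and the sign convention that each weight vector's largest-magnitude
entry is positive (required for cross-run determinism; the decomposition is
otherwise sign-ambiguous). The training identity X_c = X_s·X_lᵀ + E holds to
machine precision by construction, and the test suite cross-checks scores
against an independent NIPALS implementation (scikit-learn's PLSRegression)
to 1e−6 up to per-component sign.

Inside cross-validation the PLS step is refit per fold on training data only;
`transform` takes no labels, so leakage is excluded by interface. A
`leaky_pls` mode fits once on all data before CV — the classic mistake that
produces near-perfect training accuracy and chance-level test accuracy on
null data — and is kept as a demonstrable cautionary baseline, off by
default.

## Classifiers

The linear SVM uses a soft margin fixed at C = 1.0 (exposed in config) with
balanced class weights; decision values are wᵀx − b. The MLP is a
four-layer feedforward network — input, two ReLU hidden layers, 2-unit
softmax output — trained for exactly 18 epochs at batch size 1 with Adam at
learning rate 0.001 under inverse-class-frequency-weighted cross-entropy; the
loss is a training objective, not a stopping rule, so there is no early
stopping. Hidden widths default to 32 and 16; these are declared defaults,
not values derived from any reference architecture. Sample order is a seeded
shuffle per epoch, and zero-epoch training returns the seeded initialization,
which makes the optimizer path testable. Both models expose ‖Θ‖² — the sum
of squared weights and biases — as the complexity input to the PAC-Bayes
bound, and both serialize to JSON for exact reload.

## Validation

**Stratified K-fold CV** (default K = 10, seeded shuffle) reports fold-wise
train and test metric means ± SD. **RUB** fits on all n samples, measures
resubstitution metrics, and subtracts a bound μ:

- *Concentration bound*: μ(n, d, η) = √( ln(2·Σₖ₌₀^{d−1} C(n−1,k) / η) / 2n ).
  The binomial sum is evaluated as a log-sum-exp of log-binomials (C(111, 8)
  ≈ 4.4×10¹¹ overflows nothing in log-space) with an exact-integer path used
  as an equality oracle in tests. Strictly increasing in d; decreasing in n
  in the regimes used. At d = 1 it reduces to the Hoeffding bound, which the
  suite asserts as a closed-form limit.
- *PAC-Bayes dropout bound*: minimized over k = 20 evenly spaced λ on
  (1/2, 10]; η = 0.05; L_max = 1. The dropout attenuation is implemented as
  ((1−α)/2)·‖Θ‖², with the exponent on (1−α) configurable because the
  alternative reading ((1−α)²/2)·‖Θ‖² cannot be excluded on algebraic
  grounds; no printed numeric value distinguishes them, so the linear form —
  the canonical dropout-penalty form in the PAC-Bayes literature — is the
  default.

Corrected metrics are **not floored** at 0 or 0.5: when the bound exceeds the
empirical headroom the corrected value goes sub-chance and is reported as-is,
which is informative (it says the sample cannot support that feature
dimension). Sensitivity, specificity and AUC are corrected by subtracting the
same μ as accuracy; this is a documented heuristic — the bound is derived for
classification error, and the per-class error decomposition is not available
without further assumptions.

The balanced-permutation harness re-draws balanced subsamples (e.g. 112 of
114 subjects) and re-runs an arbitrary evaluation closure, reporting mean ±
SD across iterations; with one iteration the SD is reported as 0 by
convention.

## Explanation operators

Backgrounds for coalition evaluation default to mean substitution (features
outside the coalition are set to the training mean), the cheapest faithful
choice at this scale; a background-sample marginal expectation would also be
valid. Exact Shapley enumeration is guarded at 12 features (4096 coalitions).
Kernel-SHAP solves the constrained weighted least squares by eliminating one
coefficient against the additivity constraint; under full enumeration it
equals exact enumeration to 1e−6, which the suite asserts at M = 5. In
sampled mode coalitions are drawn with probability proportional to the
Shapley kernel and regressed with uniform weights. The local surrogate uses
Gaussian perturbations around x in standardized units (σ = 1), an RBF
proximity kernel (width 2.0), and a ridge-penalized linear fit; tabular
continuous features need no binarization. Kernel width, perturbation count
and penalty are declared defaults — no reference values exist for this
setting.

## Numerical and degenerate-input policy

- Zero-variance columns abort normalization with the column named; the check
  tolerates O(machine-ε) spread from the mean's rounding.
- The proportion test is degenerate when no accuracy exceeds the mean
  (σ₀ undefined) and errors accordingly.
- PLS stops with an informative error if the residual label covariance
  vanishes before the requested component count.
- Constant decision values yield AUC 0.5 by convention.
- All Monte-Carlo tolerances in the suite are 3-standard-error binomial bands
  at the simulated sizes, not tuned constants.

## Problem sizes in the test suite

The suite runs the full stack at reduced sizes chosen to keep statistical
power while staying fast: permutation counts of 10–100 (the harness's
estimate concentrates as 1/√B, so B = 25–100 suffices for the assertions
made), cohorts of 40–100 per group for power checks, and 500 per group for
moment-recovery checks. Sweeps use 3 seeds per cell. These are the package's
own verification sizes; production analyses would use the defaults
(1000 permutations).

## Known limitations

- The concentration bound applies to linear classifiers; pairing RUB with
  the MLP uses the PAC-Bayes route, and the ‖Θ‖² of an untrained-scale MLP
  can make that bound vacuous (> 1) at small n — truthfully reported rather
  than clipped.
- The generator's null is exactly Gaussian-plus-lognormal; real sulcal
  distributions include discreteness and detection-length floors it does not
  model.
- Sensitivity/specificity correction under RUB shares accuracy's μ (see
  above).
- Exact Shapley values are exponential in features; beyond 12 features only
  the kernel estimator is available.
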
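# Methods

This note documents the models and procedures implemented in `metabomod`,
the conventions and tunable parameters that matter, what the synthetic-data
generator does and does not emulate, and the design choices made where the
design was genuinely open.

## Statistical conventions

* **t-tests** are Welch (unequal-variance) throughout, with the
  Welch–Satterthwaite df and two-sided p. The package reproduces the
  reference cohort's combined age comparison (p = 0.028) from printed group
  summaries only under Welch.
* **2×2 chi-squared** tests use the Yates continuity correction (the
  correction term clipped at zero). All three reference race p-values
  (0.353, 0.609, 0.680) reproduce exactly at three decimals only with the
  correction; the uncorrected statistic does not reproduce them.
* **FDR** is Benjamini–Hochberg. q-values are computed over the full
  feature set of the analysis context, never over a filtered subset.
* **ROC** ties receive half credit (equivalent to the Mann–Whitney
  statistic); thresholds are the distinct observed scores plus a sentinel
  above the maximum, and a positive call is score ≥ threshold. The Youden
  point maximizes J = sens + spec − 1, breaking ties toward the lowest
  cutoff so the operating point is deterministic.
* All p-values are two-sided. Standardization uses the sample SD (n − 1),
  making the toy column [1, 2, 3] map to [−1, 0, 1].

## Differential model

Each feature (standardized within the analysis context) is regressed on a
case indicator plus standardized age, a caucasian indicator, and
standardized BMI. Because all features share one design matrix the fit is
vectorized — one least-squares solve yields every coefficient — and the
test suite asserts exact agreement with the single-feature OLS primitive.
A covariate that is constant in the current samples (e.g., race in a small
subsample) carries no adjustment information and is dropped with a warning;
genuine collinearity among non-constant columns is an error.

Decision rules: discovery hit at q < 0.1; replicated when the replication
subsample gives p < 0.05 *and* the same coefficient sign (sign consistency
is also flagged separately, since a consistent direction without nominal
significance is a meaningful intermediate outcome). The combined analysis
is pool → batch adjustment (subsample as batch) → standardize → fit.

## Batch adjustment

The batch model is the parametric empirical-Bayes location/scale family:
per feature, `y = alpha + X beta + gamma_batch + delta_batch * eps`. After
removing the covariate fit and standardizing by the pooled residual SD,
per-batch locations get a normal prior and per-batch variances an
inverse-gamma prior, hyperparameters by method of moments, posteriors by
fixed-point iteration; the adjusted data are returned on the original scale
with covariate effects restored. A unit test cross-checks the
implementation against Bioconductor `sva::ComBat` (parametric) to 1e-3 on
a small noisy two-batch matrix.

The group label is **excluded** from the covariates during batch
estimation. With groups approximately balanced across batches (as in the
discovery/replication design) the exclusion cannot absorb group signal into
the batch estimate, and it is the conservative choice when the protection
status of the label is unknown. Passing the label explicitly via
`covariates` is supported.

## Composite score

Candidates are the top-K features by training-set Welch p (ties broken by
feature id). The elastic-net logistic model is tuned over mixing
α ∈ {0.1, …, 1.0} and a 50-point log-spaced λ path from the all-zero
solution downward (glmnet convention), by stratified fivefold
cross-validated AUC; CV folds and solver shuffling are fully seeded. Ties
in CV AUC prefer the sparser model (larger λ, then larger α). Ranking,
standardization and tuning see training samples only — the suite verifies
that perturbing test data cannot change the fitted model.

Model selection across the (K, panel) grid maximizes **test** AUC,
replicating the reference design; the grid report carries the caveat that
the selected cell's AUC is optimistically biased (a max over noisy cells).
The default K grid is 2–10, 20–100 by 10, 200–500 by 100, plus "all"
(22 finite values); panel filtering happens before ranking, which for a
single panel is equivalent to ranking first.

## Consensus ICA

Orientation: the decomposition treats **features as observations**. Each
component is a source-signal vector over features — the quantity
thresholded at 2 SD for membership — and the per-sample mixing weights are
the module-activity scores regressed on group. This resolves the dual use
of "source signal" for both member selection and trait regression: one
vector cannot be both over features and over samples, so the feature-side
vector defines membership and the sample-side projection defines activity.

The ICA input is the batch-adjusted matrix, **centered per feature but not
scaled to unit variance**. With per-feature unit variance, every noise
feature contributes the same variance as a module feature and the
80%-of-variance rule can never select a small component count on data where
module members are a minority; on the centered scale, co-varying modules
dominate the spectrum and the variance rule behaves as intended (a spectrum
with shares [0.5, 0.3, 0.15, 0.05] gives q = 2). Mean abundance itself
would otherwise appear as a spurious constant-across-samples direction, so
centering is applied inside the single-run wrapper as well.

Single runs use fixed-point ICA (scikit-learn FastICA: symmetric
decorrelation, logcosh contrast with a = 1, tolerance 1e-4, at most 200
iterations, PCA whitening to q dimensions); non-convergence is flagged and
non-converged runs are excluded from the consensus. Components of the first
converged (reference) run are matched one-to-one to each other run by
maximal |Pearson r| under Hungarian assignment; a component is retained
when matched at |r| ≥ 0.90 in ≥ 80% of converged runs. Both thresholds are
configurable; they are conventions, chosen conservative, not empirical
constants. Because ICA leaves each component's sign arbitrary, retained
components are re-oriented to positive source-signal skewness (ties:
positive largest-|loading| feature), which makes repeated runs byte-identical
but means the *sign* of a module–trait coefficient is convention-dependent;
only |coefficient| and p should be interpreted.

## Enrichment and integration

Over-representation uses the hypergeometric upper tail P(X ≥ x) with the
universe equal to all annotated features of the analyzed panel (the
standard convention; restricting the universe to module members would be
circular). The pathway vocabulary defaults to the fine-grained
`sub_pathway` level. Raw p-values at 0.05 are the default for both
enrichment and cross-omics correlation, matching the reference design; a
BH-adjusted column is available but off by default. Cross-omics integration
computes the Pearson correlation of every metabolite/protein module-activity
pair over the shared samples (≥ 3 required).

## Synthetic-data generator

The generator emulates: log-scale abundances with per-feature baselines;
latent co-abundance modules (disjoint memberships, sparse loadings of
magnitude U(0.5, 1) with random sign); group effects as latent shifts
(modules) or standardized mean shifts (singletons); age confounding (cases
~3 years older); a location/scale batch distortion applied to the
replication subsample only; two panels of 738 and 890 features (reducible);
and a protein panel whose designated latents track metabolite latents at a
chosen correlation ρ on a 96-sample overlap (30 cases / 66 controls).

Singleton effects are planted so the **standardized coefficient** equals
the requested value: the raw shift is `e·sd/√(1 − e²pq)` because the shift
itself inflates the marginal SD. Latent scores are Laplace by default:
purely Gaussian latents make the ICA rotation unidentifiable, so a
heavy-tailed draw is required wherever ICA recovery is tested; in the
feature-observation orientation the sparsity of the loading vectors
provides additional identifiability. Symptom-score totals are drawn
directly inside the case (> 44) and control (< 22) ranges.

What the generator does **not** emulate: missingness beyond MCAR,
instrument drift, correlated (overlapping) modules, non-linear covariate
effects, heavy-tailed measurement noise, or annotation errors. Passing
recovery tests therefore demonstrates internal correctness of the
pipeline's inference under its own assumptions, not performance on real
plasma data.

Defaults mirror the study conditions and were fixed before any experiment
was run: cohort 39/49 + 17/19; 10 modules of 10–40 features; three modules
carrying a +0.5 SD latent group shift (mirroring three trait-associated
modules); one complex-lipid singleton at +0.74 SD (a hexosylceramide-scale
effect); noise SD 0.5; batch location shift 0.5, log-scale 0.1; 87%
caucasian; pathway fidelity 0.9.

## Validation experiments (`metabomod.validation`)

The experiment sizes are desk-scale choices, stated here as the package's
own design:

* **Differential recovery** — 50 seeds of an 800-feature panel carrying 20
  true 0.7-SD effects plus the 0.74-SD singleton, full 124-sample cohort,
  no batch/module structure (those have their own experiments). The 20
  background signals set the realized BH threshold near p ≈ 2e-3, giving
  the singleton (t ≈ 4.4) analytic detection power ≈ 0.9; the same runs
  yield the empirical FDR (truth known) and the coefficient recovery error.
* **Composite** — 20 seeds, 5 planted 0.6-SD features among 800, 88/36
  split; the grid K ∈ {2, 5, 10, 20, 50} × {HD4, CLP, combined} with
  α ∈ {0.1, 0.5, 1.0} and 20 λ points is scanned and the best test-AUC cell
  reported, mirroring the selection rule under evaluation; the null arm
  fits a single K = 10 model on effect-free data.
* **ICA modules** — 20 seeds, 300 features, three modules of 25–35 features
  (noise SD 0.15 so the 80%-variance rule lands at q = 3), one module with
  a 1-SD latent group shift; batch distortion on and adjusted, 50 restarts.
* **Batch adjustment** — a noiseless two-batch +2 location shift (every
  feature sharing one sample pattern, so removal must be exact to machine
  precision); the F-statistic collapse and coefficient-preservation checks
  run on the 800-feature signal panel with batch shift 2, comparing the
  adjusted fit against a batch-free counterfactual generated from the same
  seed.
* **Integration** — 20 seeds of the module configuration plus a 150-protein
  panel (5 modules, 3 tracking metabolite latents at ρ = 0.8, 96 shared
  samples), and a ρ = 0 null arm for the significant-pair fraction.

## Known limitations

* The EB batch adjustment assumes roughly balanced groups across batches;
  under strong imbalance, excluding the group label can remove group signal.
* Consensus retention depends on the convergence flag of the underlying
  fixed-point iterations; data with many near-Gaussian directions can
  retain spurious stable components (the reference-run convention also
  means consensus components inherit the reference run's estimation noise).
* The test-AUC model-selection rule is reported faithfully but is an
  optimistic estimator; an outer validation set would be needed for an
  unbiased performance claim.
* Minimum imputation is a detection-limit convention; it biases low-abundance
  features downward and is not appropriate for values missing at random.
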
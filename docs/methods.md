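# Methods

## Model

The package treats a reaction trial as a perturbation of a known baseline.
The baseline (reference function) is the mean observed yield of the trial's
conditioning cohort; the conditioner defaults to the catalyst reuse cycle
n, so the reference of a trial at n = 4 is the average yield of all trials
at their fourth reuse.  Deviations from that baseline are explained by
perturbation-theory operators: each molecular descriptor D_k and
quantitative condition variable V_k enters as its raw value minus the
moving average of the population of trials sharing the values of a block of
qualitative condition variables,

    ΔX_k(i, c_j) = X_k(i) − ⟨X_k⟩_{c_j(i)} .

The linear model is then an ordinary least-squares regression of yield on
the reference plus the Δ terms.  The key assumptions are (a) that trials
within a condition-partition group are exchangeable, so the group mean is a
meaningful expectation, and (b) that yield responds linearly to deviations
from that expectation over the observed range.

### Condition partitions

Nine qualitative condition variables are declared: catalyst nature, support
type, support form, metal, preparation process, support treatment, assembly
generation, reaction type, and detection method; the grouping machinery
additionally accepts the derived variables reuse cycle and nucleophile
addition step.  The exact numbering of these variables in the original
supporting tables is not reproduced in print, so the package freezes named
variables and the following scheme definitions (overridable via JSON):

* **PTML1** — c_I = {catalyst nature, support type, support form, metal};
  c_II = {preparation process, support treatment, assembly generation};
  c_III = {reuse cycle, reaction type, detection method}.
* **PTML2** — PTML1 with reuse cycle replaced in c_III by the nucleophile
  addition step (the output variable already conditions on reuse).
* **PTML3** — two blocks: everything catalyst-related (c_I ∪ c_II of
  PTML1) vs. reaction-related {nucleophile step, reaction type, detection
  method}.
* **PTML4** — one all-inclusive block over the nine qualitative variables.

Group labels are compared as trimmed, case-preserved strings.

### Combination terms and the published recipes

Terms such as Δ(D₂·V₂) or Δ[V₂₉·(V₂₂+V₂₆)] combine raw values first and
center the combined quantity ("combine-then-center"); this is the natural
reading of the printed Δ(·) notation and is the default, with a
recipe-level flag for the alternative center-then-combine reading.  The
two built-in published PTML 3 equations share eight perturbation terms
plus the reference — matching the nine-input architecture codes of the
neural models.  The full-dataset equation is typeset with E₆ in the sixth
term where the reduced equation uses D₆; both built-ins use D₆.  The
printed equations do not say which molecule's descriptor each D_k is or in
which block each term is centered, so the package freezes a documented
reading: D₂ → catalyst, D₆ → nucleophile, D₁₅ → base; Δ(D₂·V₂) is centered
in the catalyst block of PTML 3, all other terms in the reaction block.
Published coefficients are stored at printed precision and never
re-derived.

### Centering population

Moving averages (and reference cohort means) are computed over the full
dataset by default, which mirrors how the published equations appear to
have been built; a training-only mode (`fit_population`) avoids information
leakage at the cost of diverging from whole-dataset centering.  A record
whose group was absent from the fit population is centered on the term's
global mean, with a warning.  Singleton groups always yield Δ = 0 — a
deliberate property of the operator, not an error.

## Fitting and validation

* **OLS** via statsmodels, with Pearson R between observed and fitted,
  MAE, RMSE and per-coefficient p-values; a rank-deficient design raises an
  error naming the collinear columns (pivoted-QR diagnostic).
* **Forward stepwise**: partial F-to-enter with default entry p < 0.05 and
  a 10-step cap; ties broken by recipe order, making selection
  deterministic.  The entry criterion itself is a package choice in line
  with classical stepwise practice; the reference column is never subject
  to selection.
* **Expert-guided selection** unions the stepwise result with forced
  terms, preserving order and dropping duplicates.
* **Leave-one-out CV** reports per-row relative errors
  |obs − pred| / max(obs, 1); the 1% floor prevents blow-up at near-zero
  yields.  **Leave-group-out CV** refits with one reaction family (e.g.
  double carbonylation) removed from training and evaluation.
* Linear predictions are not clipped to [0, 100] by default; a clip flag
  exists for reporting.

## Splitting, binarization, classification

The train/validation split sorts by (reaction type, yield descending,
original index) and sends positions ≡ 0 (mod 4) of the 1-based sorted
order to validation — the "every fourth reaction" rule with the phase fixed
at the fourth position, which the source procedure leaves open.  This
yields floor(N/4) validation records and preserves each family's share
within one record.

Binarization labels a reaction desired (1) iff yield > threshold; the
threshold defaults to the mean of the supplied yields because the published
79% cutoff is that dataset's mean; passing 79 reproduces the published rule
exactly.  The classifier's reference input is the per-reuse-cycle
prevalence of class 1 computed on the training population.

Classification metrics include the confusion matrix at a 0.5 cutoff,
precision/recall/F1/accuracy, TPR/TNR percentages, and AUC via the
Mann–Whitney rank statistic with tied scores averaged (cross-checked in
tests against exhaustive pairwise comparison); ROC points use trapezoidal
conventions over unique thresholds.  Feature importance is permutation
importance (accuracy for classifiers, Pearson R for regressors) — the
source names no method, so a model-agnostic standard was chosen.

## Neural models

Architecture codes follow A:B-C(-D)-E:F (inputs : input layer - hidden
widths - output layer : outputs).  The original training software's exact
schedules are not reproducible, so the package matches architectures and
bounds (≤ 20 units per MLP layer, ≤ 300 RBF centers) and treats published
network performance numbers as context, not targets.  MLPs train with Adam
to a loss-improvement tolerance of 1e-6 (≤ 3000 epochs, learning rate
0.01) on standardized inputs; RBF networks use the classical three-stage
assembly — k-means center assignment, widths from the mean distance to the
two nearest other centers, output weights by pseudo-inverse; GRNN is
Nadaraya–Watson regression with one Gaussian bandwidth chosen on a 20%
shard of the training rows from a grid around the median pairwise
distance; LNN is an affine least-squares map.  All training is a pure
function of (features, targets, spec, seed).

## Synthetic data

The generator emulates the compiled dataset's shape: ~1100 trials over
seven reaction families (double carbonylation ≈ 10%), Pd-dominated metal
mix, gold/glass support forms, reuse cycles 0–10 with geometrically
decaying counts (ratio 0.8, so most trials are early reuses), ~63% of
yields above the 79% threshold, and 10% missing catalyst amounts.  Yields
come from the forward linear model: a planted per-cycle baseline
(95 − 5.5·n %), a reference slope of 0.5, and eight perturbation
coefficients applied to the package's own Δ features of the published
recipe, plus Gaussian noise (default sd 3%).  Condition variables carry
per-group offsets so moving averages are informative; planted coefficient
magnitudes are sized so each term contributes roughly 9 yield-% of spread,
keeping every coefficient well identified (relative standard error ≈ 1%)
at n = 1000 — identifiability is prioritized over a narrow yield
distribution, so with defaults roughly a quarter of pre-noise yields
exceed 100 and are clipped.  Ground truth retains pre-clip yields, the
planted reference, masked amounts and the exact feature table, so recovery
tests regress pre-clip yields on ground-truth features and avoid
truncation and imputation biases.  An intercept shift calibrated by
bisection (under the normal-noise model) sets the expected fraction of
yields above the threshold to the configured imbalance target; the shifted
intercept is what ground truth reports.  The double-carbonylation family
optionally receives extra disturbance (default sd 20%), reproducing
qualitatively the one systematically mispredicted reaction class and the
leave-group-out improvement.

What the generator does **not** emulate: chemically meaningful descriptor
values, correlations between condition variables and reagent identity,
literature-style reporting noise, or heteroscedasticity across families
(beyond the double-carbonylation disturbance).  Passing tests therefore
demonstrate the correctness of the pipeline's mechanics and estimators
under the assumed generative model, not predictive accuracy on real
reaction data.

A hand-computed 8-record fixture (two families, four trials each) ships
with its expected moving averages, Δ features, reference yields, split
labels and class labels, and anchors the unit tests.

## Numerical choices and degenerate inputs

* Rank tolerance for singularity detection: 1e-8 relative to the design's
  largest entry; stepwise F = ∞ when a candidate drives the residual sum
  of squares to numerical zero.
* Group-mean imputation ladder: exact key (metal, support type,
  preparation process, reuse cycle), then dropping reuse cycle, then
  preparation process, then support type, then the global mean — most
  specific component first.  The exact-match rule is the documented
  procedure; the ladder is this package's fallback and each fill is logged
  with its level.
* Pearson R is reported as missing (with a warning) when either vector has
  zero variance; AUC is undefined for single-class labels.
* Mean-centering test tolerance scales with the column magnitude (product
  terms reach ~1e5 in raw units, so absolute 1e-9 is meaningful only after
  scaling).
* Problem sizes in the test suite (150–1200 synthetic trials, 3 replicate
  seeds per sample size in the convergence check) were chosen as the
  smallest sizes at which the statistical assertions have comfortable
  margins.

## Known limitations

* The published dataset itself (supporting spreadsheet plus externally
  computed DRAGON descriptors) is not redistributable here, so dataset
  metrics of the original models (R ≈ 0.86, classification accuracy 0.93)
  are context, not reproduction targets; `dataset_summary` reproduces the
  published training-set sizes (851 / 789) and mean yield when that
  spreadsheet is supplied.
* Descriptor computation, SMILES handling and unit conversion are out of
  scope; descriptors and units are consumed as given.
* Stepwise inference p-values are nominal, not selection-adjusted.
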
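# Methods

## Scope and data model

The pipeline starts at per-cytosine methylation calls (Bismark-dialect
CpG reports: chromosome, 1-based position, strand, methylated count,
unmethylated count, context, trinucleotide) and ends at interpreted
neural models of sample traits. Read trimming, alignment and
bisulphite-conversion estimation are upstream of the package; non-CpG
contexts (CHG/CHH) are parsed but dropped at the strand-merging step.

A methylome is represented as one row of a sample × CpG matrix of
intensities in [0, 100]. Sites are addressed by the plus-strand
cytosine of the palindromic CpG dyad (`Chrom.pos`, e.g.
`Chr05.8103103`); counts from the minus-strand cytosine at `pos + 1`
are summed into the dyad before intensities are computed, so both
strands contribute to one estimate per site.

Two filters define missingness: within a sample, a site covered by
fewer than 10 reads is excluded (the boundary case, exactly 10 reads,
is kept); across samples, the matrix covers the union of observed
positions, so a site absent from one report is simply missing there.
Missing entries are imputed as the column mean over observed samples —
computed separately inside the training and the test subsets, so no
test-set statistic reaches a training-time computation.

## Differential methylation

Per-CpG two-group comparisons use Welch's unequal-variance *t*
(delegated to `scipy.stats.ttest_ind(equal_var=False)`, vectorized
across columns) with two-sided p-values and Benjamini–Hochberg step-up
FDR adjustment (`statsmodels`) over the tested family. Sites with zero
variance in both groups have an undefined statistic; they are skipped
and excluded from the FDR family, and the reported family size shrinks
accordingly.

Selection strategies:

* **By thresholds** — keep `p ≤ α` (default α = 0.01) and `q ≤` an FDR
  cutoff, ordered by ascending q, then p, then position id (the tie
  rule makes selections deterministic).
* **To a count** — search the achievable q-cutoffs for one yielding a
  target ± tolerance number of sites (ties in q are kept or dropped
  together). If even the full `p ≤ α` set falls short of the target by
  more than the tolerance, the selection fails with the nearest
  achievable counts; if it falls short within tolerance, the full set
  is returned.
* **Pooled** — union of the top-q blocks of several tests (first
  occurrence kept), for multiclass problems built from one-vs-rest and
  pairwise group definitions.
* **Random** — uniform without replacement, the negative control.

Quantitative traits are converted to two groups by splitting at the
training-set mean: "high" is strictly above the mean, values exactly
at the mean fall to the complement.

## Network model

Exactly two fully connected hidden layers; tanh, rectifier or maxout
(per-unit maximum over 2 linear channels; channel count configurable)
activations; softmax output for classification, a single linear neuron
for regression. The training loss is mean cross-entropy (probabilities
floored at 1e-15 before the log) or mean squared error, plus
`l1·Σ|W| + l2·Σ W²` over weight matrices (not biases).

Inputs are standardized per feature (mean/sd fitted on the training
portion, stored with the model); raw intensities span [0, 100], so
training on unstandardized inputs would couple the learning rate to
the intensity scale. Weights initialize uniformly in
±√(6/(fan_in+fan_out)); biases start at zero.

Optimization is single-threaded minibatch SGD (default batch 16) with
Nesterov momentum (default 0.9) and polynomial rate annealing
`lr_t = lr₀ / (1 + t·a)` over update counter `t`. Dropout is
"inverted" (retained activations rescaled at train time), applied to
the input layer and both hidden layers, with masks resampled per
batch. All randomness (init, shuffling, dropout) derives from the spec
seed, so a fitted model is bit-reproducible on one thread. A
non-finite epoch loss raises an error advising a lower learning rate —
there is no silent recovery.

Recommended hyperparameter search ranges, matching the study protocol
this pipeline follows: hidden sizes 4–400, L1 in [5e-6, 5e-4] or 0, L2
in [5e-7, 5e-5] or 0, dropout 0–50%, epochs 200–600. Validation
enforces structure (exactly two hidden layers, sizes in [1, 400],
dropout ≤ 0.5) but not the search ranges, since interpretable
hand-built examples (e.g. a 2×2 hidden toy for the importance formula)
legitimately fall outside them.

Model selection is an exhaustive grid search scored by k-fold
cross-validation (default k = 7, i.e. ~86% train / 14% holdout per
fold; folds stratified by class when every class has ≥ k members).
Each fold refits standardization and weights from scratch; pooled
holdout predictions yield the CV metrics (log loss and
misclassification for classification; MSE, r² and adjusted r² for
regression). Adjusted r² uses one predictor —
`1 − (1 − r²)(n − 1)/(n − 2)` — i.e. it adjusts the prediction-vs-
observation regression, not the network's input count. Grid ties break
toward the smaller total hidden size, then lexicographically, so
leaderboards are reproducible. The winner is refit on the full
training set.

## Interpretation

**Variable importance.** With `P1[i,j] = |W1[i,j]| / Σᵢ′ |W1[i′,j]|`
and `P2[j,k]` defined likewise, the raw importance of input `i` is
`Σₖ Σⱼ P1[i,j]·P2[j,k]`, normalized to sum to one. Hidden units with
all-zero incoming weights are excluded from the normalization and
contribute nothing. For maxout, `|W|` is the channel-wise maximum
absolute weight. The chain deliberately stops at the second hidden
layer; `gedeon_importance_through_output` extends it through the
output weights as a sensitivity check. Scores are invariant to
positive rescaling of any layer.

**Backward elimination** refits the grid search at every step of a
strictly decreasing input-count schedule (explicit lists such as
8400 → 4000 → … → 12, or a fractional rule, e.g. remove 5% per step:
600 → 570 → …), then keeps the top-m inputs of the current best
model's importance ranking. Retraining the search at each step, rather
than freezing the first winner, lets the preferred architecture shrink
with the input set.

**Response curves** (Profile sensitivity method): for each input, its
value is set to each of the 99 empirical percentiles (0.01–0.99,
linear interpolation, computed on raw training intensities) while all
remaining inputs are set jointly to their own qb-th percentile for
qb = 0.01–0.99. The 99 × 99 = 9801 vectors per input are standardized
inside `predict` and the output activations recorded. Backgrounds
co-move at a single shared quantile level because independent
permutation of p−1 inputs would explode combinatorially
(99^(p−1) settings); co-movement keeps the probe affordable and
matches the per-cytosine 9801-row arithmetic. Constant training
columns collapse to a single focal value; their curves are produced
and flagged.

**Diagrams.** The exported node/edge specification carries signed
weight magnitudes (positive = stimulatory, negative = inhibitory),
bias nodes per layer, and inputs ordered by descending importance —
sufficient for a neural interpretation diagram in any plotting layer;
rendering itself is out of scope.

## Study orchestration

The canonical split holds out one randomly chosen genotype per
provenance, with *all* methylomes of that genotype (both sites, both
tissues, technical replicates and mature-leaf samples) moving to the
test set together; provenances with a single genotype contribute no
test genotype and stay in training. Alternate splits come from
alternate seeds. A "full-data CV" rule (training on every methylome,
no held-out genotypes) is supported for protocol fidelity but its
in-sample nature is flagged in every report.

Per task, the pipeline imputes train/test separately, selects features
on training data only, grid-searches with sevenfold CV, refits on the
full training set and evaluates on the held-out genotypes. The
misclassification probability of a test sample is 1 minus the softmax
probability of its true class. Mixed-tissue regression never passes
the tissue label to the model. Every training-time statistic is
appended to an audit log with the exact sample ids that fed it;
`AuditLog.assert_no_leakage` fails if any test id appears.

## Synthetic data-generating process

The generator emulates a two-common-garden tree study: a balanced
design of provenances × genotypes × sites × tissues with sample names
in the field convention (e.g. `POR12IHX`). Per CpG `j` and sample `s`:

* baseline `base_j` ~ a two-component beta mixture (defaults: modes
  near 8% and 85% methylation, concentration 12, low-mode weight
  0.45) — the classic bimodal CpG landscape;
* deterministic percentage-point shifts add the planted effects on the
  probability scale, clipped to [0.001, 0.999]: tissue-associated CpG
  separate the two tissues by `tissue_effect` (default 25 points);
  provenance-associated CpG place the provenance classes at levels
  ordered along one fixed class sequence, adjacent classes
  `provenance_effect_step` (default 7 points) apart — the generator's
  analogue of an optimal class ordering with respect to methylation,
  which is what response-curve interpretation can recover;
* trait-associated CpG carry a per-tree factor loading (logit sd 0.8,
  shared by both tissues of a tree, or restricted to one tissue via
  `trait_tissue` for tissue-specificity probes), and per-methylome
  biological noise (logit sd 0.35) is added before the sigmoid;
* observed data: coverage ~ Poisson(30), methylated reads ~
  Binomial(coverage, latent), intensity = 100·meth/coverage; entries
  with coverage < 10 or hit by the uniform 3.1% missingness mask are
  absent. The quantitative trait is an affine function of the mean
  causal latent methylation per tree (intercept 11.4, slope 0.25 trait
  units per percentage point) plus Gaussian noise (sd 0.5), giving a
  signal-to-noise regime in which the causal regression has r² ≳ 0.8.

Applying the planted percentage-point effects on the probability scale
(with clipping) and the continuous noise terms on the logit scale
keeps every latent proportion inside the unit interval while making
effect sizes directly interpretable in intensity points.

Defaults are scaled-down study conditions: 20,000 CpG with 200 planted
CpG per effect class, versus 12.4 million CpG with thousands of
selected sites in a real methylome. Two consequences of the reduced
scale are worth keeping in mind when reading test results. First, 1%
of synthetic sites are causal, so a 14-CpG random control has a ~13%
chance of catching a planted site and occasionally classifies above
chance on a single seed — controls are therefore judged by their
median over ten seeds. Second, the generator omits several properties
of real methylomes: spatial autocorrelation along chromosomes,
genotype relatedness and population structure beyond the planted
provenance means, non-CpG contexts, bisulphite conversion failure and
batch effects. Passing recovery tests therefore demonstrates the
correctness of the pipeline's machinery under its stated statistical
assumptions, not field performance on real trees.

Cytosine reports written by the generator split each dyad's counts
between the two strands so the reader's merge step is exercised;
reading the files back reproduces the simulated matrix exactly.

## Numerical choices and degenerate inputs

* Cross-entropy probabilities floored at 1e-15; softmax computed with
  the max-subtraction trick.
* Welch statistic undefined (both variances zero) → site skipped,
  family size reduced, warning emitted.
* Empirical quantiles use linear interpolation (recorded in the
  response-curve metadata via the method's documented convention).
* Selection ties broken by ascending q, then p, then position id;
  grid ties by total hidden size then spec repr; importance ties by
  input index.
* All-missing columns are an imputation error naming the position;
  constant features standardize with sd 1 to avoid division by zero.
* Seeds: simulation, splitting, fold assignment, init, shuffling,
  dropout and random selections all derive from explicit integer
  seeds; fixed seeds give bit-identical studies, fits and suites on a
  single thread.

## Problem sizes used in the shipped experiments

The recovery experiment runs 9 provenances × 3 genotypes × 2 sites ×
2 tissues (108 methylomes; 72 in training after the split — the same
training-set size as the study design the package follows), 20,000
CpG, 200 planted CpG per class, a compact two-point hyperparameter
grid per task, and ten replicate seeds for median-based assertions.
These sizes were chosen as the smallest at which the planted effects
are comfortably identifiable while the whole suite stays quick to run;
larger grids and schedules (e.g. 8400-CpG selections, the full
11-step elimination ladder) are supported by the same code paths.

## Known limitations

* The SGD implementation is deliberately single-threaded and
  deterministic; it does not reproduce the asynchronous parallel
  variant used by large-scale frameworks, and no GPU path exists.
* No early stopping; epoch counts are hyperparameters.
* Region-level (DMR) calling, beta-binomial differential methylation
  and covariate adjustment are out of scope.
* The importance measure is magnitude-based; it does not account for
  input correlation and is not a causal attribution.
* `import_reports` holds all intensity maps in memory; genome-scale
  matrices (10⁷ CpG × 10² samples) need the TSV/columnar path and
  chunking, which this desk-scale implementation does not provide.
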
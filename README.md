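# methylearn

Estimation of plant traits from whole-genome bisulphite CpG methylomes,
built around small, interpretable feed-forward neural networks.

The package is aimed at researchers who have per-cytosine methylation
calls (Bismark-style CpG reports) for a population study — e.g. tree
genotypes replicated across common-garden sites and sampled in several
tissues — and want to ask: *how much of a phenotype (tissue identity,
population of origin, biomass, wood chemistry) can be recovered from
CpG methylation intensities, and which cytosines carry the signal?*

## Method

1. **Matrix construction** — per-sample cytosine reports are parsed,
   the two cytosines of each strand-symmetric CpG dyad are merged,
   sites with coverage < 10 reads are treated as missing, and
   intensities (0–100%) are assembled into a sample × CpG matrix over
   the union of positions. Missing entries are mean-imputed per column,
   with training and test subsets imputed independently.
2. **Feature selection** — each CpG is tested between two groups of
   methylomes with Welch's unequal-variance *t*-test,

   *t* = (x̄₁ − x̄₂) / √(s₁²/n₁ + s₂²/n₂),

   with Welch–Satterthwaite degrees of freedom and Benjamini–Hochberg
   FDR control across the tested family. Selections can target a count
   (e.g. 8000 ± 100 CpG by searching the FDR cutoff), pool the top of
   several tests, or be drawn uniformly at random as a negative
   control. Quantitative traits are dichotomized at the training mean
   before testing.
3. **Modelling** — networks with exactly two fully connected hidden
   layers (tanh, rectifier or maxout), a softmax output for
   classification or a linear neuron for regression, L1/L2 penalties
   and inverted dropout, trained by minibatch SGD with Nesterov
   momentum. Hyperparameters are chosen by exhaustive grid search
   scored by sevenfold cross-validation (log loss / MSE); every
   data-driven statistic is computed on training samples only and an
   audit log proves it.
4. **Interpretation** — Gedeon-style variable importance
   (column-normalized absolute-weight flow through both hidden
   layers), backward elimination along a declining input-count
   schedule, and Profile-method methylation-response curves: each
   input swept over its 99 training percentiles while the remaining
   inputs co-move over their own 99 percentiles (99 × 99 = 9801
   network evaluations per cytosine).
5. **Synthetic studies** — a generator plants tissue-, provenance- and
   trait-associated CpG into a bimodal beta-mixture methylation
   landscape with Poisson coverage, binomial read sampling, a
   ≥ 10-read filter and ~3% missingness, so the whole pipeline is
   testable against known ground truth.

## Worked example

```python
import methylearn as ml
from methylearn.pipeline import TaskConfig, make_split

cfg = ml.SyntheticConfig(genotypes_per_provenance=3, seed=1)
study = ml.simulate_study(cfg)            # 108 methylomes x 20,000 CpG
design = make_split(study.metadata, seed=1)  # hold out 1 genotype/provenance

report = ml.run_classification(
    study.matrix, study.metadata, design,
    TaskConfig(task="tissue", feature_source="differential",
               target_count=200, target_tolerance=100, seed=1),
)
print(len(report.selection), report.cv_metrics, report.test_metrics)
```

Output:

```
200 {'misclassification': 0.0, 'log_loss': 1.068e-06} {'misclassification': 0.0, 'log_loss': 1.210e-07}
```

meaning: 200 differentially methylated CpG were selected on the 72
training methylomes, the sevenfold cross-validated model classified
72/72 training methylomes correctly (log loss 1.1e-6), and all 36
methylomes of the held-out genotypes were also classified correctly.
A random-CpG control on the same data stays at chance, and the same
protocol with `ml.run_regression` recovers a planted quantitative
trait (CV r² ≈ 0.87 at the default effect sizes).

A command-line interface mirrors the library:

```bash
methylearn simulate --seed 1 --out study --reports
methylearn import study/reports --out matrix.tsv
methylearn run --config suite.yaml --out results/
```

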
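# taloco

Comparative biomechanics and morphometrics of the primate talus, with
machine-learning inference of locomotor behaviour for fossils.

The talus (ankle bone) transmits body-weight forces from leg to foot
and is one of the most commonly preserved postcranial elements in the
platyrrhine (New World monkey) fossil record. Extant platyrrhines
fall into three broad locomotor categories — arboreal quadruped,
leaper, clamber/suspensory — and both the *strength* of the talus
under a standardized load (finite-element stress) and its *shape*
(3-D landmarks) track those categories. `taloco` implements the full
inference chain that exploits this: from per-element von Mises stress
fields and landmark configurations, through bespoke summary
statistics and phylogenetically informed tests, to cross-validated
classifiers that assign fossil tali posterior probabilities over the
three locomotor classes.

## What is inside

| Module | Contents |
| --- | --- |
| `taloco.fea` | mesh-weighted stress statistics: MWAM = Σσᵢvᵢ/Σvᵢ, volume-weighted percentiles M25–M95 (MWM = M50), quasi-ideal-mesh errors PEofAM/PEofM, body-weight-force 0.3·m·g |
| `taloco.intervals` | Intervals' method: % of model volume in N stress bins below FT_upper, convergence ladder, Box-Cox + centre/scale with stored transforms for fossils |
| `taloco.shape` | generalized Procrustes analysis, shape PCA, broken-stick retention |
| `taloco.phylo` | Brownian covariance C, multivariate phylogenetic signal Kmult, PGLS with residual randomization, two-block and phylogenetic PLS, phylomorphospace ancestral projection |
| `taloco.grouptests` | PERMANOVA (pseudo-F on Euclidean distances), Holm-corrected pairwise tests, Mardia's normality screen |
| `taloco.classify` | six-family classifier bench (LDA, CART, KNN, NB, linear SVM, RF) with 200× leave-group-out CV, accuracy + Cohen's Kappa, tuning grids, fossil posteriors |
| `taloco.synthetic` | seeded generator of complete study-scale datasets (tree, shapes, stress fields, metadata, unlabeled fossils) |
| `taloco.io` / `taloco.pipeline` | plain-text readers/writers (CSV, Newick, TPS) and the two-route orchestration |

The numbered scripts under `analysis/` run the study as a sequence:
simulate → stress summaries → interval features → PERMANOVA →
GPA/PCA → comparative statistics → classifier bench → fossil
inference, each writing its tables under `results/`.

## Worked example

```sh
python analysis/01_simulate_dataset.py
python analysis/04_stress_group_tests.py
python analysis/06_comparative_stats.py
```

prints (seed 0, 40 extant species, 9999 permutations):

```
PERMANOVA: F=20.240  R2=0.522  p=0.0001
  arboreal_quadruped vs clamber_suspensory: F=6.21 R2=0.21 p_holm=0.0207
  arboreal_quadruped vs leaper: F=23.03 R2=0.43 p_holm=0.0006
  clamber_suspensory vs leaper: F=43.50 R2=0.70 p_holm=0.0006
...
Kmult shape : 0.4685 (p=0.0001)
Kmult stress: 0.1616 (p=0.0165)
PGLS stress~volume: R2=0.072 p=0.0927
PGLS shape~size   : R2=0.073 p=0.0002
r-PLS=0.781 (p=0.0011); phylogenetic r-PLS=0.773 (p=0.0129)
```

Reading this: locomotor groups differ strongly in their stress
percentiles (PERMANOVA explains 52% of the distance variance, and
every pairwise contrast survives the Holm correction); both shape and
stress carry significant phylogenetic signal, though less than a pure
Brownian process would produce (K < 1); neither talar volume nor
centroid size explains the patterns away; and shape covaries tightly
with biomechanical performance (r-PLS ≈ 0.78), with or without the
phylogenetic correction. The classifier bench
(`analysis/07_classifier_bench.py`) then shows shape features
outclassing interval stress features:

```
biomech route (200x leave-group-out CV):
  LDA        acc=0.698 [0.40,0.90] kappa=0.500
  ...
  best: LDA
shape route (200x leave-group-out CV):
  LDA        acc=1.000 [1.00,1.00] kappa=1.000
  RF         acc=0.996 [0.90,1.00] kappa=0.993
  ...
  best: LDA
```

and `analysis/08_fossil_inference.py` emits per-fossil posterior
probabilities over the three classes and scores them against the
generator's held-back truth (8/10 recovered via the shape route, 6/10
via the interval route at seed 0).

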
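# Methods note

This note records the models, conventions and design choices behind
`prognet`, in the spirit of a package reference manual: what is assumed,
what is configurable, and what the synthetic experiments do and do not
demonstrate.

## Step-function dichotomization

`stepminer.fit_step` fits a single rising step to the sorted expression
vector by exhaustive least squares over all n−1 split positions
(computed in O(n) with prefix sums). Conventions, fixed for
reproducibility:

- ties in SSE resolve to the **smallest split index** (more biomarker+
  patients); tie detection uses a relative tolerance of 1e-9·range²
  because the prefix-sum formula can split exact ties at the 1e-16
  level;
- the threshold is the midpoint of the two plateau means; a patient is
  biomarker+ iff expression is **strictly greater** than the threshold;
- a constant vector is degenerate: no split is returned and callers are
  instructed to drop the biomarker.

Only the two-way (low/high) variant is implemented; no intermediate
margin band, since the selector needs a strict bipartition of patients.
The fit is equivariant under translation and positive scaling of the
input, and both subgroups are nonempty by construction.

## Subgroup networks and PRV

Networks are built per biomarker subgroup by thresholding |Pearson r|
(default 0.6) over the pairs of a reference interactome; any edge list
can be supplied, and zero-variance genes contribute no edges. The
prognosis relevance value is operationalized as the **weighted
symmetric-difference degree**: PRV(g) = Σ |w⁺ − w⁻| over interactome
pairs incident to g, absent edges counting 0. This is the minimal
statistic consistent with "how much a gene's interactions differ
between subgroups": it is non-negative, zero exactly when g's incident
weighted edges coincide, and symmetric under swapping the subgroups.
Other operationalizations (e.g. unweighted degree difference) are
plausible; this one is flagged as the package's interpretation.

Candidate selection takes the top-k (default 30) per anchor with two
deliberate exclusions: the anchor gene itself (no self-selection), and
genes with PRV exactly 0. The latter matters: zero-PRV genes carry no
evidence of network difference, and ranking them by the lexicographic
tie rule would manufacture identical "top" lists across anchors from
pure noise, defeating the overlap step's robustness rationale. With the
exclusion, a cohort with no planted network effect yields an empty
novel list essentially always. Remaining ties break lexicographically
by symbol everywhere.

The survival filter dichotomizes each overlap gene at its own step
threshold and applies a log-rank test at raw p < 0.01 (no multiplicity
correction — a deliberate, documented choice; a univariate-Cox variant
is available via `test="cox"`).

## Survival analysis

Five-year labels: alive iff follow-up exceeds 60 months (even if death
occurred later), dead iff a death was observed at ≤ 60 months; patients
censored earlier are **unlabeled for classification but retained** in
Kaplan–Meier/log-rank/Cox analyses — the consistent completion of the
"alive if > 5 years" rule.

KM estimation and the log-rank test are delegated to lifelines; curves
are truncated at 60 months and at tied times events precede censorings.
The univariate Cox model for the binary high/low-risk indicator is a
Newton solver on the **Breslow** partial likelihood written in the
package (lifelines implements Efron ties only; with continuous
simulated times the two coincide and lifelines serves as an independent
cross-check in the tests). Confidence intervals and p-values are Wald.
When all events fall in one group the likelihood is monotone; the
result is flagged rather than reported as a finite estimate.

## Neural models

The networks are plain numpy: ReLU chains with Glorot-uniform seeded
initialization, binary cross-entropy plus an L2 penalty on all weight
matrices (default 1e-4; no published value exists, so it is
configurable), minibatch Nadam (lr 0.006, β₁ 0.9, β₂ 0.999), batch 20,
at most 100 epochs, early stopping once validation loss has stagnated
for more than 30 epochs, and restoration of the best-epoch weights.
Training is single-threaded and bit-deterministic for a fixed seed.

Branch widths: expression 4 × 40, clinical 4 × 18, merged layer
40 + 18 = 58, post-merge 2 × 32, logistic output (9,707 parameters for
the 15-gene panel). The clinical branch uses 18 units in **all four**
layers: only the last-layer width is pinned down by the merged width,
and a uniform stack keeps the branch symmetric with the expression
side. Pre-training contract: at bimodal initialization the branch
activations equal the unimodal models' exactly; zero fine-tuning epochs
leave branch weights untouched.

Class imbalance is not re-weighted during training; it is handled post
hoc by Youden reclassification. The Youden cut-off is computed on the
**validation split** and frozen before being applied to test data (the
derivation split is otherwise unconstrained; validation avoids test
leakage). Ties in J resolve to the smaller cut-off (the more sensitive
operating point), and classification uses score ≥ cutoff ⇒ death.

Benchmarks use scikit-learn with 10-fold stratified CV selecting by
mean AUC: KNN (Euclidean, k = 1..30), RBF-SVM (C ∈ {0.1, 1, 10, 100},
γ ∈ {scale, 0.001, 0.01, 0.1, 1}), random forest (max depth
⌈d/3⌉ for input dimension d, trees ∈ {50, 100, 200, 400}). The exact
SVM/RF grids are package defaults within those stated constraints.

## Feature encoding

Age and panel-gene expression are z-scored with **training-split
statistics only** (population SD, divisor n, fixed for
reproducibility); sex is a 0/1 indicator (male = 1) and stage a one-hot
over {IA, IB, IIA, IIB, III/IV} (III and IV collapsed), giving 7
clinical columns. Constant training columns are flagged and given scale
1. Samples with incomplete clinical data are dropped at alignment with
a logged count; invalid categories are hard errors naming the row.

## The synthetic generator

Defaults (chosen once; they are the package's study conditions):
512 samples split 256/85/171 by shuffling and cutting at fractions
(0.5, 0.166, 0.334) with any rounding remainder assigned to training;
120 genes of which 7 anchors and 8 planted prognostic genes.

- **Anchors**: two-component mixture, modes 6 and 6 + gap (default gap
  4, within-mode SD 1), all driven by a single latent "aggressive
  subtype" (P = 0.5). One shared subtype is what makes the planted
  module recoverable through *every* anchor's subgroup pair, which the
  intersection step requires.
- **Planted module**: inside the aggressive subtype the 8 planted genes
  load on one shared factor with pairwise correlation 0.9
  (`network_effect`); outside it they are independent. All other gene
  pairs have expectation-zero correlation.
- **Survival**: exponential proportional hazards,
  log h = log(0.004/month) + Σ 0.25·z_gene + 0.35·(stage rank − mean) +
  0.015·(age − mean). Per-gene log-HR 0.25 is deliberately moderate —
  the module correlation makes each gene's *marginal* association much
  stronger — and the stage/age terms give the clinical modality its own
  signal. The baseline hazard was calibrated once so that ≈ 69% of
  labelable patients survive five years, matching the survivor-heavy
  imbalance the classifier must face. Censoring is an independent
  exponential whose rate is solved (Brent) so the expected censored
  fraction equals `censor_rate` (default 0.3). The censoring model is a
  stand-in; the real cohort's censoring distribution is unknown.
- **Clinical**: age uniform on [32, 86], sex Bernoulli(0.5), stage
  frequencies (0.49, 0.34, 0.025, 0.095, 0.05).

What the generator does **not** emulate: probe-level structure, batch
effects across merged series, non-proportional hazards, correlations
between clinical covariates and expression, or realistic background
co-expression. Passing tests therefore demonstrate that the
implementation recovers the signal it is designed to detect under the
model's own assumptions — not performance on real microarray cohorts.

## Problem sizes and determinism

Tests and the acceptance script use desk-scale sizes chosen as adequate
for their statistical claims: 1000-vector step-fit oracle sweeps,
200-set ROC/Youden oracle sweeps, 500 null replicates for log-rank
type-I calibration (±2% band), n = 2000 for Cox parameter recovery,
n = 1000 cohorts for feature-selection recovery (50 null replicates),
and 10 training seeds for the bimodal-integration comparison, which is
made on seed-averaged AUCs. Every stochastic component draws from an
explicit seed; the pipeline fans its global seed out to per-stage seeds
via `numpy.random.SeedSequence`, and rerunning a configuration
reproduces `metrics.json` byte for byte.

## Known limitations

- The PRV definition is this package's operationalization; real-data
  panels depend on it and on the interactome supplied.
- The Cox solver handles a single binary covariate only (by design);
  multivariate adjustment is out of scope.
- SVM probability outputs rely on scikit-learn's internal calibration.
- The bimodal benefit on synthetic data is modest when one modality
  dominates; the integration property is a no-harm guarantee plus a
  gain when both modalities carry independent signal.
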
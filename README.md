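# prognet

Prognostic stratification of non-small cell lung cancer (NSCLC) patients
from gene expression and clinical data: a systems-level biomarker
selector feeding a bimodal neural classifier of five-year overall
survival, validated with Kaplan–Meier, log-rank and Cox
proportional-hazards analysis. The package is aimed at computational
biologists who want to experiment with the method end to end; a bundled
synthetic cohort generator with planted, recoverable signal makes every
stage runnable and testable without any external download.

## The method

**Feature selection.** For each of seven literature NSCLC biomarkers
(*EPCAM, HIF1A, PKM, PTK7, ALCAM, CADM1, SLC2A1*), patients are split
into biomarker− / biomarker+ subgroups by a StepMiner-style one-step
fit: on the sorted expression vector the split position *k* minimizing

    SSE(k) = Σ_{i≤k} (v_i − μ_low)² + Σ_{i>k} (v_i − μ_high)²

is found and the threshold is (μ_low + μ_high)/2. Within each subgroup a
co-expression network is built over a reference interactome (edge iff
|Pearson r| ≥ 0.6, weight |r|). A gene's **prognosis relevance value**
(PRV) is the weighted symmetric-difference degree between the two
networks,

    PRV(g) = Σ_{(g,·) ∈ interactome} | w⁺(g,·) − w⁻(g,·) |,

so genes whose interaction neighbourhood changes with biomarker status
rank high. Top-30 candidate lists from all seven anchors are
intersected, and overlap genes whose own StepMiner split separates
overall survival (log-rank p < 0.01) become novel biomarkers; with the
seven anchors they form a 15-gene panel.

**Classification.** Two feed-forward branches — panel expression
(4 × 40 ReLU) and clinical covariates age/sex/stage (4 × 18 ReLU) — are
pre-trained as unimodal classifiers of five-year survival (dead = death
observed at ≤ 60 months; patients censored earlier are unlabeled), then
merged at their last hidden layers (58 units), stacked with two 32-unit
layers and a logistic output, and fine-tuned jointly (Nadam, learning
rate 0.006, batch 20, ≤ 100 epochs, early stopping with patience 30,
L2 penalty). KNN / random-forest / SVM benchmarks are tuned by 10-fold
cross-validated AUC.

**Evaluation.** ROC/AUC, then reclassification: the cut-off maximizing
the Youden index J = sensitivity + specificity − 1 on the validation
split replaces 0.5, trading precision for recall on the survivor-heavy
cohort. Predicted high/low-risk groups are compared with Kaplan–Meier
curves, the log-rank test and a univariate Cox model (hazard ratio with
Wald 95% CI).

## Worked example

`examples/` contains one short script per capability. Running
`python examples/05_reclassification_survival.py` (full pipeline on a
simulated 1000-patient cohort, seed 11) prints:

```
bimodal test AUC: 0.8343
Youden cut-off (validation): 0.4035
  cutoff 0.5    accuracy 0.7812 precision 0.7010 recall 0.6239 F1 0.6602
  cutoff youden accuracy 0.7656 precision 0.6518 recall 0.6697 F1 0.6606
risk groups at 0.5: HR 4.09 [3.13, 5.35], log-rank p = 2.51e-28
```

Reading: the bimodal classifier separates five-year survivors from
deaths with AUC 0.83 on held-out patients; the Youden cut-off falls
below 0.5 because survivors dominate, so reclassification raises recall
(0.62 → 0.67) at some cost in precision; and the predicted high-risk
group dies about four times faster than the low-risk group, with the
log-rank test rejecting equality decisively. The summary table that
follows in the script output compares the microarray-only, clinical-only
and benchmark models at both cut-offs.

A thin CLI mirrors the main stages:

```sh
prognet simulate --out cohort/           # write a synthetic cohort
prognet validate --dir cohort/
prognet stepminer --gene EPCAM --expr cohort/expression.tsv
prognet run --config cfg.yaml --out run/ # full pipeline
prognet report --dir run/
```

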
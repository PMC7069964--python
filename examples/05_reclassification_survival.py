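"""Full pipeline run: Youden reclassification and risk-group survival.

Runs every stage on a simulated 1000-patient cohort and shows how moving
the classification cut-off from 0.5 to the Youden-index point (chosen on
the validation split) trades precision for recall on the imbalanced
five-year outcome, and how the predicted risk groups separate in
Kaplan-Meier / Cox analysis.
"""
from prognet import synthetic as syn
from prognet.pipeline import PipelineConfig, report_summary, run_pipeline

cfg = PipelineConfig(simulate=syn.SimConfig(n_samples=1000),
                     benchmarks=("rf",), seed=11)
report = run_pipeline(cfg, "scratch/example_run")

bim = report["models"]["bimodal"]
print(f"bimodal test AUC: {bim['test_auc']:.4f}")
print(f"Youden cut-off (validation): {bim['youden_cutoff']:.4f}")
for rule in ("0.5", "youden"):
    m = bim["cutoffs"][rule]
    print(f"  cutoff {rule:<6} accuracy {m['accuracy']:.4f} "
          f"precision {m['precision']:.4f} recall {m['recall']:.4f} "
          f"F1 {m['f1']:.4f}")
s = report["survival"]["bimodal"]["0.5"]
print(f"risk groups at 0.5: HR {s['hr']:.2f} "
      f"[{s['ci_low']:.2f}, {s['ci_high']:.2f}], "
      f"log-rank p = {s['logrank_p']:.2e}")

text, _ = report_summary("scratch/example_run")
print("\n" + text)
# The Youden cut-off falls below 0.5 on this survivor-heavy cohort, so
# reclassification raises recall (and F1) at some cost in precision,
# while the high/low risk groups remain strongly separated in survival.
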
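"""Run the complete analysis in one call and read the comparison report.

The pipeline simulates a cohort, TIC-normalizes, splits 4:1, trains the
clinical-only network, the fingerprint network (SN), four classical
baselines (LASSO, random forest, SVM, OPLS-DA) and the multi-modal CSN,
evaluates everything with discovery-fixed Youden thresholds and DeLong CIs,
selects the top-20 saliency panel and refits on it.  Rerunning with the same
master seed reproduces every artifact byte-for-byte.
"""

import tempfile

import fingerdx as fx

config = fx.PipelineConfig(master_seed=42)
with tempfile.TemporaryDirectory() as out:
    result = fx.run_pipeline(config, out)

print(f"{'input':18s} {'model':14s} {'val AUC':>8s} {'sens%':>6s} {'spec%':>6s}")
for row in result["rows"]:
    if row["cohort"] == "validation":
        print(f"{row['input_data']:18s} {row['algorithm']:14s} "
              f"{row['auc']:8.3f} {100*row['sensitivity']:6.1f} "
              f"{100*row['specificity']:6.1f}")
rec = fx.panel_recovery(result["panel"], fx.ground_truth(result["cohort"]))
print(f"\nsaliency panel recovered {100*rec:.0f}% of the planted bins")
print("(every number recomputes identically under the same master seed)")
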
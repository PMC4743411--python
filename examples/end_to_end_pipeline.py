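"""One-command pipeline: simulate -> collate -> train -> evaluate.

Runs the whole stack from a single seeded RunConfig and writes the sparse
and dense matrices, the evaluation report and a reproducibility manifest
(config, derived stage seeds, checksums) to an output directory.
"""

from selprof import RunConfig, run_pipeline

config = RunConfig(n_compounds=1000, annotation_overlap=0.5, label_noise=0.1,
                   strategy="binary_relevance", base_learner="rf",
                   folds=10, seed=1, outdir="scratch/example_run")
result = run_pipeline(config)
report = result["report"]

print(f"sparse dataset: {result['n_sparse']} compounds; "
      f"dense subset: {result['n_dense']}")
print(f"collation reproduced the generator's truth: "
      f"{result['collation_matches_expectation']}")
print(f"binary relevance random forest, 10-fold CV:")
print(f"  macro-accuracy {report.macro_accuracy:.3f}")
print(f"  macro-MCC      {report.macro_mcc:.3f}")
print(f"  macro-AUC      {report.macro_auc:.3f}")
print("\nArtifacts and manifest written to scratch/example_run/.")
print("Re-running with the same config reproduces identical checksums.")
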
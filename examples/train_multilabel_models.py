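"""Compare label-powerset, binary relevance and classifiers chain.

Generates a synthetic two-transporter dataset (1000 compounds, half of them
annotated for both targets, 10 % label noise), then cross-validates the
three multi-label strategies.  The powerset model needs the dense subset;
binary relevance and the chain exploit every annotated cell of the sparse
matrix.
"""

import numpy as np

from selprof import (GeneratorSpec, apply_label_noise, cross_validate,
                     cross_validate_powerset, generate_descriptors,
                     generate_labels, powerset_encode, sparsify)

spec = GeneratorSpec(n_compounds=1000)
truth, classes = generate_labels(spec, seed=0)
observed = sparsify(apply_label_noise(truth, 0.1, seed=1), 0.5, seed=2)
X = generate_descriptors(classes, seed=3)

# label-powerset on the dense subset (all labels present)
dense_rows = observed.labels.notna().all(axis=1)
dense_classes, _ = powerset_encode(observed.labels.loc[dense_rows])
lp = cross_validate_powerset(X.loc[dense_rows.index[dense_rows]],
                             dense_classes, "rf", folds=10, seed=0)
print(f"label-powerset (dense, n={dense_classes.size}): "
      f"exact-match accuracy {lp['accuracy']:.3f}, kappa {lp['kappa']:.3f}, "
      f"ovr AUC {lp['auc']:.3f}")

# binary relevance and classifiers chain on the sparse matrix
for strategy in ("binary_relevance", "classifiers_chain"):
    report = cross_validate(X, observed, strategy, "rf", folds=10, seed=0)
    print(f"{strategy:19s} (sparse, n={len(observed.inchikeys)}): "
          f"macro-accuracy {report.macro_accuracy:.3f}, "
          f"macro-MCC {report.macro_mcc:.3f}, "
          f"macro-AUC {report.macro_auc:.3f}")

print()
print("Exact-match accuracy is stricter than macro-accuracy: the powerset")
print("model must get both labels right at once.  With only two labels and")
print("descriptors that carry each label's signal directly, the chain and")
print("binary relevance perform nearly identically.")
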
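"""When does the classifiers chain beat binary relevance?

Constructs the label-dependence scenario: label A is learnable from the
features and annotated everywhere; label B is a noisy copy of A annotated
for only ~12 % of compounds.  Binary relevance must relearn the signal for B
from those few rows; the chain appends A's predicted score — a learned
one-dimensional summary — and B's model rides on it.
"""

from selprof import cross_validate, generate_label_dependence_scenario

wins = 0
for seed in range(10):
    X, Y = generate_label_dependence_scenario(seed=seed)
    br = cross_validate(X, Y, "binary_relevance", "logreg", folds=10,
                        seed=seed)
    cc = cross_validate(X, Y, "classifiers_chain", "logreg", folds=10,
                        seed=seed, chain_order=("A", "B"))
    b_br, b_cc = br.per_label["B"]["auc"], cc.per_label["B"]["auc"]
    wins += b_cc > b_br
    print(f"seed {seed}: B-label AUC  binary relevance {b_br:.3f}  "
          f"classifiers chain {b_cc:.3f}")

print(f"\nchain wins on the dependent label in {wins}/10 replicates.")
print("The chain's edge is exactly the planted label dependence; on data")
print("whose labels are conditionally independent given the features, the")
print("two strategies coincide.")
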
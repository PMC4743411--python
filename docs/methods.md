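# Methods

## Problem and scope

`selprof` models inhibition of two co-expressed ABC efflux transporters,
BCRP and P-gp, as a **multi-label classification** problem over compounds
assembled from heterogeneous sources.  The package covers the whole path
from raw activity records to interpreted models: structure washing and
InChIKey merge keys, binarization and consensus labeling, sparse/dense
dataset construction, three problem transformations (label-powerset, binary
relevance, classifiers chain), a macro-averaging cross-validation harness
tolerant of missing annotations, and interpretation tools (feature
importance, threshold scans, a fixed selectivity rule, scaffold profiles).
Live database querying is out of scope; collation operates on local tabular
and SDF inputs.

## Collation rules

- Endpoints IC50/EC50/Ki in nanomolar only; other units are rejected rows.
- Sanity cap: values **strictly greater** than 10⁸ nM are dropped before the
  log transform (the cap lives on the raw nanomolar scale).
- pActivity = −log₁₀(value · 10⁻⁹); active ⇔ pActivity > 5 (strict), i.e.
  more potent than 10 µM.
- Relation signs: `<`/`≤` on a concentration makes the computed pActivity a
  lower bound — the record can only assert activity, and does (label 1) when
  the bound already reaches 5, otherwise it is *ambiguous* and removed.
  `>`/`≥` is the mirror case asserting inactivity.  This guarantees a
  censored value weaker than 10 µM never becomes an active.
- Pivot on the full 27-character standard InChIKey (not the connectivity
  block): full keys avoid stereochemistry collisions, and nothing in the
  merge semantics requires tautomer-level collapsing.
- Consensus per cell: any pre-curated label wins outright (conflicting
  pre-curated labels drop the cell — no principled precedence exists);
  otherwise the median of the open labels decides, and an exact 0.5 median
  (even split) drops the cell.  The 0.5-median removal is applied **per
  cell**, not per compound: a conflict on one target says nothing about the
  other target's measurements.
- Consensus is applied to binarized labels, not to pooled pActivity values:
  assays of different setups are comparable at the active/inactive level,
  much less so on the continuous scale.

Washing keeps the largest organic fragment (a tie between the two largest
fragments is an unresolvable mixture → rejection), neutralizes simple
protonation states (RDKit Uncharger), and rejects organometallics
(metal–carbon bond) and elements outside {H, B, C, N, O, F, Si, P, S, Cl,
Br, I}.  Pre-curated entries whose structures fail InChI generation are
rejected and logged rather than merged on a weaker key.

## Descriptors

The panel re-implements, openly, the interpretable descriptors usually
consumed under their MOE names; numeric values are **not** MOE-exact and are
defined as follows:

| name | definition | units |
|---|---|---|
| a_aro | atoms flagged aromatic by RDKit perception | count |
| a_hyd | carbons with no N/O/S/P neighbour, plus halogens on carbon (SMARTS in `descriptors.py`) | count |
| SlogP | Crippen atomic-contribution logP | — |
| vsa_acc | Labute approximate-surface-area contributions summed over acceptor atoms | Å² |
| BalabanJ | J = q/(µ+1) · Σ_edges (s_i s_j)^(−1/2) on the heavy-atom graph, plain topological distances | — |
| a_donacc | distinct atoms that are H-bond donors or acceptors (union) | count |
| weinerPath | Σ shortest-path lengths over heavy-atom pairs | — |
| apol | Σ atomic polarizabilities incl. hydrogens, element table in `data/polarizabilities.json` | Å³ |

Donor = N/O bearing ≥ 1 H; acceptor = N/O with an available lone pair (not
positively charged, not pyrrole-type); an atom that is both counts once in
a_donacc.  Graph descriptors use the hydrogen-suppressed graph; apol
includes hydrogens.  Note RDKit's own BalabanJ weights aromatic bonds by
bond order in the distance matrix; this package follows the plain
shortest-path definition (the two coincide on saturated molecules, which is
how the cross-check test is scoped).  Single-atom molecules take BalabanJ =
0 by convention.  Fingerprints: MACCS (166 bits) and Morgan with diameter 8
(radius 4) folded to 1024 bits.  Scaffolds are Bemis–Murcko frameworks
keyed by canonical SMILES; acyclic molecules map to the empty scaffold.

## Multi-label machinery

Label-powerset assigns class Σᵢ yᵢ·2ⁱ over the label order (P-gp, BCRP):
(0,0)→0, (1,0)→1, (0,1)→2, (1,1)→3.  It refuses matrices with missing
cells.  Binary relevance trains one base learner per label on the rows
annotated for it.  The classifiers chain shuffles the label list under the
run's seed (an explicit order can be given), trains label k's model on the
original features plus the predicted scores of models 1..k−1, computed for
*all* compounds including unannotated ones.  Training-time augmentation
uses in-sample fitted scores — the literal protocol; an
`out_of_fold_scores` flag substitutes internal 5-fold cross-validated
scores for annotated rows (default off).  At prediction time the chain
always propagates its own scores, never ground truth, including on held-out
CV folds — anything else leaks labels.

Base learners are pluggable scikit-learn estimators; the shipped specs are
logistic regression (defaults), random forest (100 trees) and a
polynomial-kernel SVM of degree 2 (probability-calibrated so chain scores
live in [0, 1]).

Cross-validation assigns whole compounds to folds, stratified by annotation
pattern (the 0/1/missing tuple) so rare patterns spread across folds; plain
random folds are available by flag.  Fold assignment depends only on
(labels, folds, seed), so strategies compared under one seed see identical
splits — the chain is refit per fold (the only leakage-safe reading of
per-fold evaluation).  Per repeat, held-out scores are pooled across folds,
per-label metrics are computed on annotated cells, repeats are averaged,
and macro metrics are unweighted means over labels.  Metrics are
implemented from their formulas (MCC with the 0/0 → 0 convention; kappa
from the confusion matrix; AUC as the tie-corrected Mann–Whitney statistic;
multi-class AUC as the unweighted one-vs-rest mean — the multi-class
averaging convention of other toolkits may differ numerically), with
scikit-learn as the independent oracle in the tests.  A pooled fold with a
single truth class makes AUC undefined; it is recorded as a warning and
excluded from the mean.

## Interpretation

Bagged-tree importance is the mean over trees of the summed fraction of
training samples passing through each node where the feature splits: a
root-used feature sees 100 % of the data; with depth-1 stumps the score is
bounded by 1, in general by the tree depth.  The MCC threshold scan
evaluates the rule "value ≤ t ⇒ class A" at every midpoint between
consecutive distinct observed values and reports the signed peak (a
negative peak means the inverse rule separates better) — matching the
convention of plotting positive and negative peaks on one curve.  The
two-class selectivity rule (a_hyd ≤ 21 → class 2; else a_aro ≥ 24 → class
2; else class 1) is shipped as a fixed callable; no rule-induction engine
is re-implemented.  `rederive_rule_thresholds` fits a depth-2 decision tree
on (a_hyd, a_aro), keeps each feature's most-populated split, and reports
inclusive integer bounds in the rule's own direction (floor for the ≤ rule,
ceiling for the ≥ rule).  Scaffold enrichment is reported descriptively as
per-cluster label proportions; no hypothesis test is attached, heat-map
tables being the intended consumption.

## Synthetic generator

Defaults mirror the published dataset shape: 2191 compounds, dense-subset
fraction 161/2191, powerset-class balance 27:48:39:47.  Descriptor
distributions are class-conditional normals (mixtures where a class is
bimodal), chosen so the documented interpretation trends hold by
construction: P-gp-selective compounds are hydrophobic (a_hyd ≈ 28) with
mid-range SlogP (≈ 3.5); BCRP-selective compounds split into a
low-hydrophobicity branch (a_hyd ≈ 16) and an aromatic-rich branch (a_aro ≈
29), with low-or-high SlogP; dual inhibitors overlap both selective groups
and carry a slightly higher polarizability sum (78.2 vs 76.9).  The two
class-2 branches are deliberately disjoint in their defining descriptor so
that *both* clauses of the selectivity rule are needed — a generator whose
low-a_hyd compounds were also aromatic would be separable by one clause and
would not exercise the cascade.  Under these defaults the fixed rule scores
≈ 0.99 on the selective classes (the ≥ 0.85 recovery bound is comfortably
met) and a_hyd/a_aro correlate at r ≈ 0.2 (< 0.5, mirroring their reported
non-correlation).

Activity records expand each annotated cell into 1–3 assay measurements
drawn consistently with the label (actives: pActivity ∈ U(5.5, 8.5);
inactives: U(2.5, 4.5)), with a 10 % censored-relation rate, a 5 %
even-conflict rate (cells the 0.5-median rule must drop) and a 15 %
pre-curated subset whose labels must win.  Template-structure mode builds
real molecules on an eight-scaffold library (quinoline, flavone, acridone,
biphenyl, indole, benzimidazole, phenylpiperazine, chromone) with acyclic
class-dependent substituents — long alkyl chains for P-gp-type classes,
short polar chains otherwise — so computed descriptors track the planted
class and Murcko profiling recovers the planted clusters exactly (side
chains are acyclic by construction).

The label-dependence scenario plants the one structure where a classifiers
chain must beat binary relevance: label A is a noisy linear signal in 20 of
60 features, annotated everywhere; label B is A with 10 % of values
flipped, annotated for ~12 % of compounds, carrying no information beyond
A.  BR must relearn a 20-dimensional signal from ~95 rows; the chain
appends A's learned score and B's model weights a single strong column.

What the generator does **not** emulate: real medicinal-chemistry
diversity, descriptor covariance of the published sets, assay-specific
systematic shifts, and activity cliffs.  Passing the recovery tests
therefore demonstrates correctness of the machinery under planted signal,
not predictive performance on real transporter data; published
cross-validation figures depend on proprietary descriptor numerics and
specific learner internals and are deliberately not targets.

## Numerical choices and problem sizes

- Evaluation pools held-out predictions across folds before computing
  metrics (stabilizes AUC on small labels) and averages across repeats.
- Consensus, pivoting and collation are deterministic; all stochastic
  stages take explicit seeds, and `run_pipeline` derives per-stage seeds
  from one global seed, recorded in the run manifest.
- Study sizes used by the test suite and the acceptance script: n = 1000
  compounds (overlap 0.5, noise 0.1) for the BR random-forest recovery run;
  ten replicates of the n = 800 dependence scenario for the chain
  comparison; n = 1500 with three replicate draws for rule-threshold
  re-derivation (the region between the class modes is sparsely populated,
  so a single fit's cutpoint has ±1–2 integer noise; the replicate mean is
  reported); the full 2191-compound shape for collation and dataset-size
  checks.
- The package is a library: the pipeline stages are wired by
  `selprof.pipeline.run_pipeline` plus the `examples/` scripts rather than
  a shell CLI, since every intended use starts from Python.

## Known limitations

- Descriptor numerics are open re-definitions; absolute values differ from
  MOE's, so models and thresholds transfer qualitatively, not numerically.
- The washing step approximates a full standardizer: no tautomer
  canonicalization, no charge-parent search beyond rule-based
  neutralization.
- Multi-class AUC uses unweighted one-vs-rest; other conventions
  (pairwise, prevalence-weighted) give different numbers on imbalanced
  data.
- With two labels the chain's advantage is small by nature; it grows with
  label count and annotation sparsity, which the dependence scenario makes
  explicit.
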
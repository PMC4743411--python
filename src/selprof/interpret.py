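"""Interpretability machinery: feature importance, threshold scans, the
printed selectivity rule, and scaffold pharmacology profiling.

The feature-importance measure is the *fraction-of-samples-seen* used with
bagged trees: per tree, each feature accumulates the fraction of the
training samples that pass through the nodes where it splits (a feature at
the root sees 100 % of the data); fractions are averaged over the ensemble
and rank the features.

The two-class selectivity rule — BCRP-selective when a_hyd <= 21, or else
when a_aro >= 24, otherwise P-gp-selective — is shipped as a fixed callable
model; :func:`rederive_rule_thresholds` fits a small decision tree on
(a_hyd, a_aro) to recover comparable cutpoints from data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as M
from .collate import LabelMatrix
from .descriptors import murcko_scaffold

# ---------------------------------------------------------------------------
# Feature importance in bagging of trees
# ---------------------------------------------------------------------------


@dataclass
class FeatureImportanceReport:
    """Mean fraction-of-samples-seen per feature over a bagged-tree ensemble."""

    importances: dict[str, float]

    def ranking(self) -> list[tuple[str, float]]:
        return sorted(self.importances.items(), key=lambda kv: -kv[1])


def bagging_importance(ensemble, feature_names: Optional[Sequence[str]] = None
                       ) -> FeatureImportanceReport:
    """Fraction-of-samples-seen importances from fitted bagged trees.

    ``ensemble`` is any fitted scikit-learn tree ensemble exposing
    ``estimators_`` with ``tree_`` attributes (Bagging of decision trees,
    random forest).  Per tree, a feature's score is the sum over its split
    nodes of (samples reaching the node) / (samples at the root); scores are
    averaged over trees.  Unused features score 0.
    """
    if not hasattr(ensemble, "estimators_"):
        raise ValueError("ensemble is not fitted (no estimators_)")
    trees = [est.tree_ for est in np.asarray(ensemble.estimators_).ravel()]
    n_features = trees[0].n_features
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(n_features)]
    totals = np.zeros(n_features)
    for tree in trees:
        root = tree.n_node_samples[0]
        per_tree = np.zeros(n_features)
        for node in range(tree.node_count):
            feat = tree.feature[node]
            if feat >= 0:  # -2 marks leaves
                per_tree[feat] += tree.n_node_samples[node] / root
        totals += per_tree
    totals /= len(trees)
    return FeatureImportanceReport(
        {name: float(v) for name, v in zip(feature_names, totals)})


# ---------------------------------------------------------------------------
# MCC threshold scan
# ---------------------------------------------------------------------------


@dataclass
class ThresholdScan:
    """MCC of the rule "value <= t => class A" at every candidate threshold.

    Thresholds are the midpoints between consecutive distinct observed
    values.  ``peak_mcc`` is signed: a negative peak means the inverse rule
    (value <= t => class B) separates better.
    """

    descriptor: str
    class_a: int
    class_b: int
    thresholds: np.ndarray
    mcc_values: np.ndarray
    peak_threshold: float
    peak_mcc: float


def mcc_threshold_scan(values, classes, class_a=None, class_b=None,
                       descriptor: str = "") -> ThresholdScan:
    """Scan all midpoint thresholds of a 1-D descriptor for the best MCC.

    ``classes`` may be any binary labelling; ``class_a`` (default: the
    smaller label) is the class predicted below the threshold.  Raises when
    only one class is present.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(classes)
    present = sorted(set(c.tolist()))
    if len(present) != 2:
        raise ValueError("threshold scan needs exactly two classes present")
    a = present[0] if class_a is None else class_a
    b = present[1] if class_b is None else class_b
    truth_a = (c == a).astype(int)
    distinct = np.unique(v)
    if distinct.size < 2:
        raise ValueError("need at least two distinct descriptor values")
    thresholds = 0.5 * (distinct[:-1] + distinct[1:])
    mccs = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred_a = (v <= t).astype(int)
        mccs[i] = M.mcc(*M.confusion_counts(truth_a, pred_a))
    peak = int(np.argmax(np.abs(mccs)))
    return ThresholdScan(descriptor=descriptor, class_a=a, class_b=b,
                         thresholds=thresholds, mcc_values=mccs,
                         peak_threshold=float(thresholds[peak]),
                         peak_mcc=float(mccs[peak]))


# ---------------------------------------------------------------------------
# The fixed two-class selectivity rule
# ---------------------------------------------------------------------------

A_HYD_CUTOFF = 21
A_ARO_CUTOFF = 24


def selectivity_rule(a_hyd: int, a_aro: int) -> int:
    """Classify a selective inhibitor as BCRP- (2) or P-gp-selective (1).

    The rule cascade: a_hyd <= 21 -> class 2; else a_aro >= 24 -> class 2;
    else class 1.  BCRP-selective inhibitors are the less hydrophobic or
    more aromatic ones.
    """
    if a_hyd < 0 or a_aro < 0:
        raise ValueError("atom counts must be non-negative")
    if a_hyd <= A_HYD_CUTOFF:
        return 2
    if a_aro >= A_ARO_CUTOFF:
        return 2
    return 1


def apply_selectivity_rule(table: pd.DataFrame) -> pd.Series:
    """Vectorized rule over a DescriptorTable with a_hyd / a_aro columns."""
    return table.apply(
        lambda row: selectivity_rule(int(row["a_hyd"]), int(row["a_aro"])),
        axis=1)


def rederive_rule_thresholds(table: pd.DataFrame, classes,
                             seed: int = 0) -> dict:
    """Re-derive (a_hyd, a_aro) cutpoints with an off-the-shelf tree inducer.

    Fits a depth-2 decision tree on the two descriptors for a {1, 2} class
    vector and reads back the split thresholds per feature (rounded to the
    integer lattice the rule lives on).
    """
    from sklearn.tree import DecisionTreeClassifier

    X = table[["a_hyd", "a_aro"]].to_numpy(dtype=float)
    y = np.asarray(classes, dtype=int)
    tree = DecisionTreeClassifier(max_depth=2, random_state=seed)
    tree.fit(X, y)
    t = tree.tree_
    # per feature, keep the split backed by the most samples — deeper
    # refinements inside an almost-pure branch are noise
    cuts: dict[str, tuple[int, float]] = {}
    for node in range(t.node_count):
        if t.feature[node] >= 0:
            name = ["a_hyd", "a_aro"][t.feature[node]]
            n = int(t.n_node_samples[node])
            if name not in cuts or n > cuts[name][0]:
                cuts[name] = (n, float(t.threshold[node]))
    out = {"accuracy": float(tree.score(X, y))}
    # report inclusive integer bounds in the rule's own direction: a split at
    # a_hyd <= 21.5 is the printed "a_hyd <= 21", a split at a_aro <= 23.5
    # puts class 2 on the right, i.e. "a_aro >= 24"
    out["a_hyd"] = (float(np.floor(cuts["a_hyd"][1]))
                    if "a_hyd" in cuts else None)
    out["a_aro"] = (float(np.ceil(cuts["a_aro"][1]))
                    if "a_aro" in cuts else None)
    return out


# ---------------------------------------------------------------------------
# Scaffold pharmacology profiling
# ---------------------------------------------------------------------------


@dataclass
class ScaffoldCluster:
    """One Bemis-Murcko scaffold, its members and their label profile."""

    scaffold: str
    members: list[str]
    label_counts: dict  # target -> {0: n, 1: n, "missing": n}

    @property
    def size(self) -> int:
        return len(self.members)


def scaffold_profile(structures: dict[str, str],
                     matrix: Optional[LabelMatrix] = None
                     ) -> tuple[list[ScaffoldCluster], dict]:
    """Group compounds by canonical Murcko scaffold and profile their labels.

    Returns the clusters (largest first, scaffold key as tie-break — input
    order never matters) and a summary: unique scaffold count, mean members
    per scaffold, singleton count, and counts of scaffolds with >= 5 and
    > 20 members.
    """
    by_scaffold: dict[str, list[str]] = {}
    for key, smi in structures.items():
        by_scaffold.setdefault(murcko_scaffold(smi), []).append(key)
    labels = matrix.labels if matrix is not None else None
    clusters = []
    for scaff, members in by_scaffold.items():
        members = sorted(members)
        counts: dict = {}
        if labels is not None:
            for tgt in labels.columns:
                tally = {0: 0, 1: 0, "missing": 0}
                for m in members:
                    if m in labels.index and not np.isnan(labels.at[m, tgt]):
                        tally[int(labels.at[m, tgt])] += 1
                    else:
                        tally["missing"] += 1
                counts[tgt] = tally
        clusters.append(ScaffoldCluster(scaff, members, counts))
    clusters.sort(key=lambda c: (-c.size, c.scaffold))
    sizes = np.array([c.size for c in clusters])
    summary = {
        "n_scaffolds": int(sizes.size),
        "mean_compounds_per_scaffold": float(sizes.mean()) if sizes.size else 0.0,
        "n_singletons": int((sizes == 1).sum()),
        "n_with_5_or_more": int((sizes >= 5).sum()),
        "n_with_more_than_20": int((sizes > 20).sum()),
    }
    return clusters, summary


def cluster_heatmap_table(cluster: ScaffoldCluster,
                          matrix: LabelMatrix) -> pd.DataFrame:
    """Per-cluster binary heat-map table (members x targets, 0/1/NA)."""
    members = [m for m in cluster.members if m in matrix.labels.index]
    return matrix.labels.loc[members].copy()


# ---------------------------------------------------------------------------
# Group mean comparison
# ---------------------------------------------------------------------------

def class_mean_compare(values, group_mask) -> tuple[float, float]:
    """Arithmetic mean of a descriptor inside and outside a compound group.

    Used e.g. to compare the polarizability sum of dual inhibitors with that
    of all other compounds.  Both groups must be non-empty.
    """
    v = np.asarray(values, dtype=float)
    mask = np.asarray(group_mask, dtype=bool)
    if v.shape != mask.shape:
        raise ValueError("values and mask must align")
    if not mask.any() or mask.all():
        raise ValueError("both groups must be non-empty")
    return float(v[mask].mean()), float(v[~mask].mean())
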
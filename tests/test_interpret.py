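"""Feature importance, MCC threshold scans, the selectivity rule, scaffolds."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from selprof.collate import LabelMatrix
from selprof.interpret import (bagging_importance, class_mean_compare,
                               mcc_threshold_scan, rederive_rule_thresholds,
                               scaffold_profile, selectivity_rule)
from selprof import metrics as M


class TestBaggingImportance:
    def test_root_feature_sees_all_data(self, rng):
        X = np.column_stack([rng.integers(0, 2, 200), rng.random(200)])
        y = X[:, 0].astype(int)  # only feature 0 matters
        ens = BaggingClassifier(DecisionTreeClassifier(max_depth=1),
                                n_estimators=10, random_state=0).fit(X, y)
        report = bagging_importance(ens, ["informative", "noise"])
        assert report.importances["informative"] == pytest.approx(1.0)
        assert report.importances["noise"] == 0.0
        assert report.ranking()[0][0] == "informative"

    def test_unfitted_rejected(self):
        with pytest.raises(ValueError):
            bagging_importance(BaggingClassifier(DecisionTreeClassifier()))

    def test_stump_importance_bounded_by_one(self, rng):
        X = rng.random((300, 4))
        y = (X[:, 2] > 0.5).astype(int)
        ens = BaggingClassifier(DecisionTreeClassifier(max_depth=1),
                                n_estimators=25, random_state=1).fit(X, y)
        report = bagging_importance(ens)
        assert all(0.0 <= v <= 1.0 for v in report.importances.values())
        assert report.ranking()[0][0] == "f2"


class TestMccThresholdScan:
    def test_perfect_separation_peaks_at_one(self):
        values = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        classes = np.array([0, 0, 0, 1, 1, 1])
        scan = mcc_threshold_scan(values, classes, class_a=0)
        assert abs(scan.peak_mcc) == pytest.approx(1.0)
        assert 3.0 < scan.peak_threshold < 10.0

    def test_peak_equals_exhaustive_midpoint_search(self, rng):
        values = rng.normal(size=80)
        classes = (values + rng.normal(scale=1.5, size=80) > 0).astype(int)
        scan = mcc_threshold_scan(values, classes, class_a=0)
        distinct = np.unique(values)
        best = 0.0
        for t in 0.5 * (distinct[:-1] + distinct[1:]):
            m = M.mcc(*M.confusion_counts((classes == 0).astype(int),
                                          (values <= t).astype(int)))
            if abs(m) > abs(best):
                best = m
        assert scan.peak_mcc == pytest.approx(best)

    def test_identical_distributions_flat(self, rng):
        values = rng.normal(size=10 ** 4)
        classes = rng.integers(0, 2, size=10 ** 4)
        scan = mcc_threshold_scan(values, classes)
        assert abs(scan.peak_mcc) < 0.05

    def test_scan_covers_every_midpoint(self):
        values = np.array([1.0, 1.0, 2.0, 5.0])
        scan = mcc_threshold_scan(values, np.array([0, 0, 1, 1]))
        assert scan.thresholds.tolist() == [1.5, 3.5]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mcc_threshold_scan([1.0, 2.0], [1, 1])

    def test_qualitative_shape_mid_range_vs_bimodal(self, rng):
        """A mid-range class against a low-or-high bimodal class yields a
        strong peak; against an everywhere-overlapping class it stays flat."""
        mid = rng.normal(3.5, 0.8, 400)
        bimodal = np.concatenate([rng.normal(1.5, 0.7, 200),
                                  rng.normal(5.5, 0.7, 200)])
        overlapping = np.concatenate([rng.normal(3.5, 0.8, 200),
                                      rng.normal(5.5, 0.7, 200)])
        # mid-range vs the dual-like overlapping class: weak separation
        flat = mcc_threshold_scan(np.concatenate([mid, overlapping]),
                                  np.repeat([1, 3], 400), class_a=1)
        # mid-range vs the lower mode of the bimodal class: clear threshold
        lower = bimodal[bimodal < 3.5]
        peaked = mcc_threshold_scan(
            np.concatenate([mid, lower]),
            np.repeat([1, 2], [400, lower.size]), class_a=2)
        assert abs(peaked.peak_mcc) > abs(flat.peak_mcc) + 0.2


class TestSelectivityRule:
    @pytest.mark.parametrize("a_hyd,a_aro,expected", [
        (21, 0, 2),    # low hydrophobicity -> BCRP-selective
        (22, 24, 2),   # aromatic-rich -> BCRP-selective
        (22, 23, 1),   # otherwise P-gp-selective
        (0, 0, 2),
        (100, 100, 2),
        (100, 0, 1)])
    def test_rule_cascade(self, a_hyd, a_aro, expected):
        assert selectivity_rule(a_hyd, a_aro) == expected

    def test_lattice_boundary(self):
        """The decision boundary sits exactly at a_hyd 21/22 and a_aro 23/24."""
        for a_aro in range(0, 40):
            assert selectivity_rule(21, a_aro) == 2
            expected = 2 if a_aro >= 24 else 1
            assert selectivity_rule(22, a_aro) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            selectivity_rule(-1, 5)

    def test_rederive_from_planted_data(self):
        from selprof.synthetic import GeneratorSpec, generate_descriptors, generate_labels

        hyds, aros = [], []
        for seed in range(3):
            _, classes = generate_labels(GeneratorSpec(n_compounds=1500), seed)
            X = generate_descriptors(classes, seed + 50)
            mask = np.isin(classes, [1, 2])
            th = rederive_rule_thresholds(X[mask], classes[mask])
            hyds.append(th["a_hyd"])
            aros.append(th["a_aro"])
        assert abs(np.mean(hyds) - 21) <= 2
        assert abs(np.mean(aros) - 24) <= 2


class TestScaffoldProfile:
    def test_shared_scaffold_single_cluster(self):
        structs = {f"c{i}": f"{'C' * (i + 1)}c1ccc2ncccc2c1" for i in range(5)}
        clusters, summary = scaffold_profile(structs)
        assert summary["n_scaffolds"] == 1
        assert summary["mean_compounds_per_scaffold"] == 5.0

    def test_all_distinct_singletons(self):
        structs = {"a": "c1ccccc1", "b": "c1ccc2ncccc2c1", "c": "C1CCCCC1",
                   "d": "c1ccc2[nH]ccc2c1", "e": "C1CCNCC1"}
        clusters, summary = scaffold_profile(structs)
        assert summary["n_scaffolds"] == 5
        assert summary["n_singletons"] == 5
        assert summary["mean_compounds_per_scaffold"] == 1.0

    def test_label_profile_counts(self):
        structs = {"a": "Cc1ccccc1", "b": "CCc1ccccc1"}
        labels = pd.DataFrame([[1.0, 0.0], [1.0, np.nan]],
                              index=["a", "b"], columns=["P-gp", "BCRP"])
        clusters, _ = scaffold_profile(structs, LabelMatrix(labels=labels))
        (cluster,) = clusters
        assert cluster.label_counts["P-gp"] == {0: 0, 1: 2, "missing": 0}
        assert cluster.label_counts["BCRP"] == {0: 1, 1: 0, "missing": 1}

    def test_input_order_invariant(self, rng):
        structs = {f"c{i}": smi for i, smi in enumerate(
            ["Cc1ccccc1", "CCc1ccccc1", "Cc1ccc2ncccc2c1", "CCCCC", "CCCC"])}
        _, s1 = scaffold_profile(structs)
        items = list(structs.items())
        rng.shuffle(items)
        _, s2 = scaffold_profile(dict(items))
        assert s1 == s2


class TestClassMeanCompare:
    def test_constant_descriptor_equal_means(self):
        m_in, m_out = class_mean_compare([2.0] * 6, [True] * 3 + [False] * 3)
        assert m_in == m_out == 2.0

    def test_all_in_group_rejected(self):
        with pytest.raises(ValueError):
            class_mean_compare([1.0, 2.0], [True, True])

    def test_recovers_planted_shift(self, rng):
        inside = rng.normal(78.2, 6.0, 500)
        outside = rng.normal(76.9, 6.0, 500)
        values = np.concatenate([inside, outside])
        mask = np.repeat([True, False], 500)
        m_in, m_out = class_mean_compare(values, mask)
        se = 6.0 / np.sqrt(500)
        assert abs(m_in - 78.2) < 3 * se and abs(m_out - 76.9) < 3 * se
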
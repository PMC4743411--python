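"""Multi-label learning over label matrices with missing annotations.

Three problem transformations are provided:

* **label-powerset** — every complete label combination becomes one class of
  a multi-class problem (2^|L| classes for |L| labels); it needs the dense
  dataset because a row with a missing label has no class.
* **binary relevance** — one independent binary model per label, each trained
  on the rows annotated for that label.
* **classifiers chain** — per-label models trained sequentially: each fitted
  model predicts its label as a score in [0, 1] for *every* compound
  (annotated or not) and that score column is appended to the feature matrix
  before the next label's model is trained, letting later models exploit
  label dependence.

The cross-validation harness assigns whole compounds to folds, evaluates
per-label metrics on held-out annotated cells only, macro-averages across
labels, and reuses identical folds when strategies are compared.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import cross_val_predict
from sklearn.svm import SVC

from . import metrics as M
from .collate import LabelMatrix

# ---------------------------------------------------------------------------
# Label-powerset encoding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowersetEncoding:
    """Bijection between complete label tuples and class indices.

    With label order (P-gp, BCRP): (0,0) -> 0 non-inhibitors, (1,0) -> 1
    P-gp-selective, (0,1) -> 2 BCRP-selective, (1,1) -> 3 dual inhibitors.
    The i-th label contributes 2**i.
    """

    label_order: tuple[str, ...]

    @property
    def n_classes(self) -> int:
        return 2 ** len(self.label_order)

    def class_of(self, labels: Sequence[int]) -> int:
        if len(labels) != len(self.label_order):
            raise ValueError("label tuple length mismatch")
        return int(sum(int(y) << i for i, y in enumerate(labels)))

    def decode(self, cls: int) -> tuple[int, ...]:
        if not 0 <= cls < self.n_classes:
            raise ValueError(f"class {cls} out of range")
        return tuple((cls >> i) & 1 for i in range(len(self.label_order)))


def _labels_frame(Y) -> pd.DataFrame:
    return Y.labels if isinstance(Y, LabelMatrix) else pd.DataFrame(Y)


def powerset_encode(Y, encoding: Optional[PowersetEncoding] = None
                    ) -> tuple[np.ndarray, PowersetEncoding]:
    """Encode a dense label matrix into a class vector.

    Raises on any missing cell — the transformation is undefined there.
    """
    df = _labels_frame(Y)
    if df.isna().any().any():
        raise ValueError("label-powerset requires a dense (no-missing) matrix")
    enc = encoding or PowersetEncoding(tuple(str(c) for c in df.columns))
    classes = np.array([enc.class_of(row) for row in df.to_numpy(dtype=int)])
    return classes, enc


def subset_classes(classes: np.ndarray, keep: set[int],
                   *arrays) -> tuple:
    """Filter rows to the kept powerset classes; labels are unchanged.

    Any extra aligned arrays/DataFrames are filtered with the same mask.
    Raises if nothing survives.
    """
    classes = np.asarray(classes)
    mask = np.isin(classes, sorted(keep))
    if not mask.any():
        raise ValueError(f"no rows left after keeping classes {sorted(keep)}")
    out = [classes[mask]]
    for arr in arrays:
        if isinstance(arr, (pd.DataFrame, pd.Series)):
            out.append(arr.iloc[np.flatnonzero(mask)])
        else:
            out.append(np.asarray(arr)[mask])
    return tuple(out) if arrays else out[0]


# ---------------------------------------------------------------------------
# Base learners
# ---------------------------------------------------------------------------

def make_learner(spec: str | tuple, seed: Optional[int] = None):
    """Instantiate a base learner from its short spec.

    ``"logreg"`` — logistic regression, default parameters;
    ``"rf"`` — random forest, 100 trees;
    ``"svm_poly"`` — support vector machine, polynomial kernel of degree 2
    (with probability calibration so chain scores live in [0, 1]).
    A (name, params) tuple overrides hyperparameters.
    """
    name, params = (spec, {}) if isinstance(spec, str) else (spec[0], dict(spec[1]))
    rs = seed if seed is None else int(seed) % (2 ** 31)
    if name == "logreg":
        return LogisticRegression(max_iter=1000, **params)
    if name == "rf":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=rs, **params)
    if name == "svm_poly":
        params.setdefault("kernel", "poly")
        params.setdefault("degree", 2)
        params.setdefault("probability", True)
        return SVC(random_state=rs, **params)
    raise ValueError(f"unknown base learner {name!r}")


def _as_matrix(X) -> tuple[np.ndarray, Optional[list]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


def _score01(estimator, X: np.ndarray) -> np.ndarray:
    """Positive-class score in [0, 1]."""
    proba = estimator.predict_proba(X)
    pos = list(estimator.classes_).index(1)
    return proba[:, pos]


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


@dataclass
class MultiLabelModel:
    strategy: str  # binary_relevance | classifiers_chain | label_powerset
    base_learner: str | tuple
    label_order: tuple[str, ...]
    chain_order: Optional[tuple[str, ...]] = None
    submodels: dict = field(default_factory=dict)
    feature_names: Optional[list] = None
    encoding: Optional[PowersetEncoding] = None
    seed: Optional[int] = None


def _check_feature_schema(model: MultiLabelModel, X) -> np.ndarray:
    Xa, names = _as_matrix(X)
    if model.feature_names is not None:
        if names is not None and names != model.feature_names:
            raise ValueError("feature schema mismatch with training data")
        if Xa.shape[1] != len(model.feature_names):
            raise ValueError("feature count mismatch with training data")
    return Xa


def _fit_one_label(base_learner, seed, X, y, label):
    present = np.unique(y)
    if present.size < 2:
        raise ValueError(f"label {label!r} has a single class among annotated rows")
    est = make_learner(base_learner, seed)
    est.fit(X, y)
    return est


def fit_binary_relevance(X, Y, base_learner="rf",
                         seed: Optional[int] = None) -> MultiLabelModel:
    """One independent binary model per label, trained on its annotated rows."""
    df = _labels_frame(Y)
    Xa, names = _as_matrix(X)
    model = MultiLabelModel("binary_relevance", base_learner,
                            tuple(str(c) for c in df.columns),
                            feature_names=names, seed=seed)
    for k, label in enumerate(model.label_order):
        y = df[label].to_numpy(dtype=float)
        rows = ~np.isnan(y)
        model.submodels[label] = _fit_one_label(
            base_learner, None if seed is None else seed + k,
            Xa[rows], y[rows].astype(int), label)
    return model


def fit_classifiers_chain(X, Y, base_learner="rf", seed: Optional[int] = None,
                          chain_order: Optional[Sequence[str]] = None,
                          out_of_fold_scores: bool = False) -> MultiLabelModel:
    """Sequential per-label models with score augmentation.

    The label list is shuffled by ``seed`` unless an explicit ``chain_order``
    is given.  Model k is trained on the rows annotated for its label, using
    the original features plus the score columns of models 1..k-1; those
    scores are predicted for *all* compounds, including unannotated ones.
    By default augmentation scores during training are the in-sample fitted
    scores; ``out_of_fold_scores=True`` replaces them (on annotated rows)
    with internal 5-fold cross-validated scores to damp optimistic coupling.
    """
    df = _labels_frame(Y)
    Xa, names = _as_matrix(X)
    labels = [str(c) for c in df.columns]
    if chain_order is None:
        rng = np.random.default_rng(seed)
        chain_order = tuple(np.array(labels)[rng.permutation(len(labels))])
    else:
        chain_order = tuple(chain_order)
        if sorted(chain_order) != sorted(labels):
            raise ValueError("chain_order must permute the label columns")
    model = MultiLabelModel("classifiers_chain", base_learner, tuple(labels),
                            chain_order=chain_order, feature_names=names,
                            seed=seed)
    X_aug = Xa
    for k, label in enumerate(chain_order):
        y = df[label].to_numpy(dtype=float)
        rows = ~np.isnan(y)
        sub_seed = None if seed is None else seed + k
        est = _fit_one_label(base_learner, sub_seed, X_aug[rows],
                             y[rows].astype(int), label)
        model.submodels[label] = est
        scores = _score01(est, X_aug)
        if out_of_fold_scores:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                oof = cross_val_predict(
                    make_learner(base_learner, sub_seed), X_aug[rows],
                    y[rows].astype(int), cv=5, method="predict_proba")
            pos = 1 if oof.shape[1] > 1 else 0
            scores = scores.copy()
            scores[rows] = oof[:, pos]
        X_aug = np.column_stack([X_aug, scores])
    return model


def fit_label_powerset(X, Y, base_learner="rf",
                       seed: Optional[int] = None) -> MultiLabelModel:
    """Single multi-class model on the powerset classes of a dense matrix."""
    classes, enc = powerset_encode(Y)
    Xa, names = _as_matrix(X)
    est = make_learner(base_learner, seed)
    est.fit(Xa, classes)
    return MultiLabelModel("label_powerset", base_learner, enc.label_order,
                           submodels={"__powerset__": est},
                           feature_names=names, encoding=enc, seed=seed)


def predict(model: MultiLabelModel, X) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-label scores in [0, 1] and 0.5-thresholded binary predictions.

    Chain models replay the recorded chain order, feeding each submodel's
    scores (never truth) forward.  Label-powerset predictions are decoded
    back to label tuples; scores are per-label class-marginal sums.
    """
    Xa = _check_feature_schema(model, X)
    n = Xa.shape[0]
    scores = pd.DataFrame(index=range(n), columns=list(model.label_order),
                          dtype=float)
    if model.strategy == "binary_relevance":
        for label in model.label_order:
            scores[label] = _score01(model.submodels[label], Xa)
    elif model.strategy == "classifiers_chain":
        X_aug = Xa
        for label in model.chain_order:
            s = _score01(model.submodels[label], X_aug)
            scores[label] = s
            X_aug = np.column_stack([X_aug, s])
    elif model.strategy == "label_powerset":
        est = model.submodels["__powerset__"]
        proba = est.predict_proba(Xa)
        enc = model.encoding
        full = np.zeros((n, enc.n_classes))
        for idx, cls in enumerate(est.classes_):
            full[:, int(cls)] = proba[:, idx]
        for i, label in enumerate(model.label_order):
            on = [c for c in range(enc.n_classes) if (c >> i) & 1]
            scores[label] = full[:, on].sum(axis=1)
    else:
        raise ValueError(f"unknown strategy {model.strategy!r}")
    labels = (scores >= 0.5).astype(int)
    return scores, labels


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Per-label and macro-averaged metrics from repeated k-fold CV."""

    per_label: dict
    macro_accuracy: float
    macro_mcc: float
    macro_auc: float
    macro_kappa: float
    cv_spec: dict
    warnings: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"per_label": self.per_label, "macro_accuracy": self.macro_accuracy,
             "macro_mcc": self.macro_mcc, "macro_auc": self.macro_auc,
             "macro_kappa": self.macro_kappa, "cv_spec": self.cv_spec,
             "warnings": self.warnings}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def assign_folds(Y, folds: int, seed: int, stratify: bool = True) -> np.ndarray:
    """Fold index per compound; each compound lies entirely in one fold.

    Stratification groups compounds by their annotation pattern (the tuple of
    0 / 1 / missing across labels) and deals each group round-robin, so every
    fold sees every pattern that has at least ``folds`` members.
    """
    df = _labels_frame(Y)
    n = len(df)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError("more folds than compounds")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if not stratify:
        perm = rng.permutation(n)
        for pos, row in enumerate(perm):
            assignment[row] = pos % folds
        return assignment
    keys = np.array([str(tuple(row)) for row in
                     df.fillna(-1).astype(int).to_numpy()])
    start = 0
    for key in sorted(set(keys.tolist())):
        rows = np.flatnonzero(keys == key)
        rows = rows[rng.permutation(rows.size)]
        for pos, row in enumerate(rows):
            assignment[row] = (start + pos) % folds
        start += rows.size
    return assignment


def _fit_by_strategy(strategy, X, Y, base_learner, seed, chain_order,
                     out_of_fold_scores=False):
    if strategy == "binary_relevance":
        return fit_binary_relevance(X, Y, base_learner, seed)
    if strategy == "classifiers_chain":
        return fit_classifiers_chain(X, Y, base_learner, seed,
                                     chain_order=chain_order,
                                     out_of_fold_scores=out_of_fold_scores)
    if strategy == "label_powerset":
        return fit_label_powerset(X, Y, base_learner, seed)
    raise ValueError(f"unknown strategy {strategy!r}")


def cross_validate(X, Y, strategy="binary_relevance", base_learner="rf",
                   folds: int = 10, repeats: int = 1, seed: int = 0,
                   chain_order: Optional[Sequence[str]] = None,
                   stratify: bool = True,
                   out_of_fold_scores: bool = False) -> EvaluationReport:
    """Repeated k-fold cross-validation with macro-averaged metrics.

    Folds are over compounds and depend only on (Y, folds, repeat seed,
    stratify) — two strategies compared under the same seed see identical
    folds.  Per repeat, held-out scores are pooled across folds and per-label
    accuracy / MCC / AUC / kappa are computed on annotated cells only; the
    report averages repeats and then macro-averages across labels.
    """
    df = _labels_frame(Y)
    Xa, _ = _as_matrix(X)
    labels = [str(c) for c in df.columns]
    per_label_runs: dict[str, list[dict]] = {lab: [] for lab in labels}
    warns: list[str] = []
    for r in range(repeats):
        rep_seed = seed + 1000 * r
        fold_of = assign_folds(df, folds, rep_seed, stratify)
        pooled_scores = np.full((len(df), len(labels)), np.nan)
        for f in range(folds):
            test = fold_of == f
            train = ~test
            model = _fit_by_strategy(
                strategy, Xa[train], df.loc[train], base_learner,
                rep_seed + f, chain_order, out_of_fold_scores)
            s, _ = predict(model, Xa[test])
            pooled_scores[test] = s[labels].to_numpy()
        for j, lab in enumerate(labels):
            truth = df[lab].to_numpy(dtype=float)
            mask = ~np.isnan(truth)
            t = truth[mask].astype(int)
            s = pooled_scores[mask, j]
            p = (s >= 0.5).astype(int)
            tp, tn, fp, fn = M.confusion_counts(t, p)
            run = {"accuracy": M.accuracy(tp, tn, fp, fn),
                   "mcc": M.mcc(tp, tn, fp, fn),
                   "kappa": M.cohen_kappa(
                       [[tn, fp], [fn, tp]])}
            try:
                run["auc"] = M.auc(s, t)
            except ValueError:
                warns.append(f"AUC undefined for label {lab} in repeat {r}")
                run["auc"] = None
            per_label_runs[lab].append(run)
    per_label = {}
    for lab, runs in per_label_runs.items():
        agg = {}
        for key in ("accuracy", "mcc", "kappa", "auc"):
            vals = [run[key] for run in runs if run[key] is not None]
            agg[key] = float(np.mean(vals)) if vals else None
        per_label[lab] = agg
    macro = {key: M.macro_average(
        [per_label[lab][key] for lab in labels if per_label[lab][key] is not None])
        for key in ("accuracy", "mcc", "auc", "kappa")}
    return EvaluationReport(
        per_label=per_label, macro_accuracy=macro["accuracy"],
        macro_mcc=macro["mcc"], macro_auc=macro["auc"],
        macro_kappa=macro["kappa"],
        cv_spec={"strategy": strategy, "base_learner": str(base_learner),
                 "folds": folds, "repeats": repeats, "seed": seed,
                 "repeat_seeds": [seed + 1000 * r for r in range(repeats)],
                 "stratify": stratify},
        warnings=warns)


def cross_validate_powerset(X, classes: np.ndarray, base_learner="rf",
                            folds: int = 10, repeats: int = 1,
                            seed: int = 0) -> dict:
    """CV for a multi-class (label-powerset-encoded) problem.

    Accuracy here is the exact-match rate over complete label combinations —
    stricter than the macro-averaged per-label accuracy.  Kappa and the
    unweighted one-vs-rest AUC accompany it.
    """
    Xa, _ = _as_matrix(X)
    classes = np.asarray(classes, dtype=int)
    n_classes = int(classes.max()) + 1
    accs, kappas, aucs = [], [], []
    for r in range(repeats):
        rep_seed = seed + 1000 * r
        fold_of = assign_folds(pd.DataFrame({"c": classes}), folds, rep_seed)
        pooled_pred = np.empty_like(classes)
        pooled_proba = np.zeros((classes.size, n_classes))
        for f in range(folds):
            test = fold_of == f
            est = make_learner(base_learner, rep_seed + f)
            est.fit(Xa[~test], classes[~test])
            pooled_pred[test] = est.predict(Xa[test])
            proba = est.predict_proba(Xa[test])
            for idx, cls in enumerate(est.classes_):
                pooled_proba[test, int(cls)] = proba[:, idx]
        accs.append(float((pooled_pred == classes).mean()))
        conf = np.zeros((n_classes, n_classes))
        for t, p in zip(classes, pooled_pred):
            conf[t, p] += 1
        kappas.append(M.cohen_kappa(conf))
        aucs.append(M.multiclass_auc(pooled_proba, classes))
    return {"accuracy": float(np.mean(accs)), "kappa": float(np.mean(kappas)),
            "auc": float(np.mean(aucs)),
            "cv_spec": {"folds": folds, "repeats": repeats, "seed": seed,
                        "base_learner": str(base_learner)}}
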
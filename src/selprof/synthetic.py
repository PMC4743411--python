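"""Synthetic data generator for exercising the whole pipeline offline.

The generator emulates the statistical shape of a two-transporter (BCRP /
P-gp) inhibition dataset assembled from open and pre-curated sources:

* powerset-class proportions defaulting to the published dense-dataset
  balance 27 : 48 : 39 : 47 (non-inhibitors, P-gp-selective, BCRP-selective,
  dual) over 161 compounds, scaled to any n;
* an annotation-overlap fraction defaulting to 161/2191 — most compounds
  carry a label for only one transporter (the sparse dataset);
* class-conditional descriptor distributions reproducing the reported
  interpretation trends: BCRP-selective inhibitors have fewer hydrophobic
  atoms and/or more aromatic atoms (so the printed a_hyd <= 21 / a_aro >= 24
  rule is recoverable), take low-or-high SlogP values where P-gp-selective
  ones sit mid-range, and dual inhibitors carry a slightly higher atomic
  polarizability sum (78.2 vs 76.9);
* per compound-target cell, one to three assay measurements with occasional
  even-split conflicts (dropped by the 0.5-median rule), censored relation
  signs, and a pre-curated subset whose labels take priority.

Every function is a pure function of (spec, seed).  ``feature_only`` mode
draws descriptor vectors directly; ``template_structures`` mode builds real
molecules on a small scaffold library so chem I/O, descriptor computation
and scaffold profiling can be exercised end to end.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import ActivityRecord, CompoundEntry, compute_inchikey
from .collate import LabelMatrix
from .descriptors import PANEL
from .multilabel import PowersetEncoding

#: Published dense-dataset class counts (non / P-gp-sel / BCRP-sel / dual).
DENSE_CLASS_COUNTS = (27, 48, 39, 47)

DEFAULT_TARGETS = ("P-gp", "BCRP")


@dataclass(frozen=True)
class GeneratorSpec:
    """Conditions for synthetic data generation.

    Defaults mirror the published dataset shape: 2191 compounds of which a
    fraction 161/2191 is annotated for both transporters, class balance as
    in the dense dataset, 1-3 measurements per annotated cell with a 5 %
    even-conflict rate, 10 % censored relation signs, and a 15 % pre-curated
    subset.
    """

    n_compounds: int = 2191
    n_targets: int = 2
    targets: tuple[str, ...] = DEFAULT_TARGETS
    annotation_overlap: float = 161 / 2191
    class_proportions: tuple[float, ...] = tuple(
        c / sum(DENSE_CLASS_COUNTS) for c in DENSE_CLASS_COUNTS)
    label_noise: float = 0.0
    max_assays_per_cell: int = 3
    conflict_rate: float = 0.05
    relation_rate: float = 0.10
    precurated_rate: float = 0.15
    structure_mode: str = "feature_only"  # or "template_structures"

    def __post_init__(self):
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if len(self.class_proportions) != 2 ** self.n_targets:
            raise ValueError("need one proportion per powerset class")
        if not 0.0 <= self.annotation_overlap <= 1.0:
            raise ValueError("annotation_overlap must lie in [0, 1]")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if len(self.targets) != self.n_targets:
            raise ValueError("targets tuple must match n_targets")


def synthetic_inchikey(index: int) -> str:
    """Deterministic, distinct, InChIKey-shaped merge key for compound #i."""
    letters = string.ascii_uppercase
    first = ""
    v = index
    for _ in range(14):
        first += letters[v % 26]
        v //= 26
    second = ""
    v = index * 2654435761 % (26 ** 10)  # Knuth multiplicative scramble
    for _ in range(10):
        second += letters[v % 26]
        v //= 26
    return f"{first}-{second}-N"


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def generate_labels(spec: GeneratorSpec, seed: int
                    ) -> tuple[LabelMatrix, np.ndarray]:
    """Draw powerset classes and decode them into a dense truth matrix."""
    rng = np.random.default_rng(seed)
    props = np.asarray(spec.class_proportions, dtype=float)
    if (props < 0).any():
        raise ValueError("degenerate class proportions")
    enc = PowersetEncoding(spec.targets)
    classes = rng.choice(len(props), size=spec.n_compounds, p=props)
    rows = np.array([enc.decode(int(c)) for c in classes], dtype=float)
    keys = [synthetic_inchikey(i) for i in range(spec.n_compounds)]
    labels = pd.DataFrame(rows, index=keys, columns=list(spec.targets))
    return LabelMatrix(labels=labels), classes


def apply_label_noise(matrix: LabelMatrix, noise: float,
                      seed: int) -> LabelMatrix:
    """Flip each annotated cell independently with probability ``noise``."""
    rng = np.random.default_rng(seed)
    df = matrix.labels.copy()
    arr = df.to_numpy()
    flips = (rng.random(arr.shape) < noise) & ~np.isnan(arr)
    arr[flips] = 1.0 - arr[flips]
    return LabelMatrix(labels=pd.DataFrame(arr, index=df.index,
                                           columns=df.columns))


def sparsify(matrix: LabelMatrix, overlap: float, seed: int) -> LabelMatrix:
    """Blank one target's annotation in a fraction 1-overlap of the rows.

    Rows kept fully annotated are chosen Bernoulli(overlap); every other row
    loses exactly one target uniformly at random.  No row loses everything.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    df = matrix.labels.copy()
    n, m = df.shape
    keep_all = rng.random(n) < overlap
    drop_col = rng.integers(0, m, size=n)
    arr = df.to_numpy()
    for i in range(n):
        if not keep_all[i]:
            arr[i, drop_col[i]] = np.nan
    return LabelMatrix(labels=pd.DataFrame(arr, index=df.index,
                                           columns=df.columns))


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

#: Class-conditional distribution parameters for the interpretable panel.
#: Entries are (mean, sd) or a list of equally weighted (mean, sd) mixture
#: branches.  Classes: 0 non-inhibitor, 1 P-gp-selective, 2 BCRP-selective,
#: 3 dual.  Count descriptors are rounded and clipped at 0 after drawing.
DEFAULT_DESCRIPTOR_PARAMS = {
    "a_hyd":      {0: (22.0, 4.0), 1: (28.0, 2.5),
                   2: [(16.0, 2.5), (26.0, 2.0)], 3: (27.5, 3.0)},
    "a_aro":      {0: (18.0, 3.0), 1: (17.0, 2.5),
                   2: [(17.0, 2.5), (29.0, 2.0)], 3: (24.0, 3.0)},
    "SlogP":      {0: (2.5, 1.2), 1: (3.5, 0.8),
                   2: [(1.5, 0.7), (5.5, 0.7)], 3: [(3.5, 0.8), (5.5, 0.7)]},
    "vsa_acc":    {0: (30.0, 8.0), 1: (25.0, 6.0), 2: (40.0, 8.0),
                   3: (35.0, 8.0)},
    "BalabanJ":   {0: (1.9, 0.35), 1: (1.7, 0.30), 2: (2.0, 0.35),
                   3: (1.8, 0.30)},
    "a_donacc":   {0: (5.0, 1.5), 1: (4.0, 1.2), 2: (6.0, 1.5),
                   3: (5.0, 1.5)},
    "weinerPath": {0: (1400.0, 350.0), 1: (1600.0, 350.0),
                   2: (1300.0, 350.0), 3: (1700.0, 350.0)},
    "apol":       {0: (76.9, 6.0), 1: (76.9, 6.0), 2: (76.9, 6.0),
                   3: (78.2, 6.0)},
}

_COUNT_DESCRIPTORS = ("a_hyd", "a_aro", "a_donacc", "weinerPath")

# a_hyd and a_aro branches of class 2 are drawn coherently (the same mixture
# branch), matching the rule structure: low-hydrophobicity compounds need not
# be aromatic, highly aromatic ones may be hydrophobic.
_COUPLED = ("a_hyd", "a_aro", "SlogP")


def generate_descriptors(classes: Sequence[int], seed: int,
                         params: Optional[dict] = None,
                         keys: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Draw the descriptor panel conditionally on the powerset class.

    Class-2 (BCRP-selective) draws satisfy the printed selectivity rule for
    well over 90 % of compounds and class-1 (P-gp-selective) draws violate
    it equally rarely, so the rule is recoverable from the output.
    """
    rng = np.random.default_rng(seed)
    params = params or DEFAULT_DESCRIPTOR_PARAMS
    classes = np.asarray(classes, dtype=int)
    n = classes.size
    if keys is None:
        keys = [synthetic_inchikey(i) for i in range(n)]
    branch = rng.integers(0, 2, size=n)  # shared across coupled descriptors
    data = {}
    for name, by_class in params.items():
        col = np.empty(n)
        for cls in np.unique(classes):
            rows = classes == cls
            p = by_class[int(cls)]
            if isinstance(p, list):
                if name in _COUPLED:
                    b = branch[rows] % len(p)
                else:
                    b = rng.integers(0, len(p), size=int(rows.sum()))
                means = np.array([p[i][0] for i in b])
                sds = np.array([p[i][1] for i in b])
            else:
                means, sds = p[0], p[1]
            col[rows] = rng.normal(means, sds, size=int(rows.sum()))
        if name in _COUNT_DESCRIPTORS:
            col = np.clip(np.round(col), 0, None)
        data[name] = col
    return pd.DataFrame(data, index=list(keys))[
        [c for c in PANEL if c in data]]


# ---------------------------------------------------------------------------
# Raw activity records
# ---------------------------------------------------------------------------

def generate_activity_records(
    matrix: LabelMatrix, spec: GeneratorSpec, seed: int,
    structures: Optional[dict[str, str]] = None,
) -> tuple[list[ActivityRecord], dict]:
    """Expand every annotated cell into raw measurement records.

    Each cell yields 1..max_assays records whose binarized consensus equals
    the cell's label, except cells drawn as *conflicts*, which receive an
    even 1/0 split of open labels (the 0.5-median rule must drop them).  A
    pre-curated record carrying the true label is attached to a random
    subset of cells — including conflicted ones, where it must win.

    Returns the records plus an info dict with the conflict / pre-curated
    cell sets; :func:`expected_after_collation` derives the matrix the
    collation pipeline must reproduce.
    """
    rng = np.random.default_rng(seed)
    records: list[ActivityRecord] = []
    conflict_cells: set[tuple[str, str]] = set()
    precurated_cells: set[tuple[str, str]] = set()
    df = matrix.labels

    def entry(key: str, source: str) -> CompoundEntry:
        structure = structures.get(key, "") if structures else ""
        return CompoundEntry(compound_id=key, structure=structure,
                             inchikey=key, source=source)

    def measurement(key, target, label, assay_idx, source="open"):
        censored = rng.random() < spec.relation_rate
        if label == 1:
            p = rng.uniform(5.5, 8.5)
            relation = "<" if censored else "="
        else:
            p = rng.uniform(2.5, 4.5)
            relation = ">" if censored else "="
        value = 10.0 ** (9.0 - p)
        return ActivityRecord(
            compound=entry(key, source), target_id=target, endpoint="IC50",
            value_nM=value, relation=relation,
            assay_id=f"assay_{key[:6]}_{target}_{assay_idx}", source=source)

    for key, row in df.iterrows():
        for target, label in row.items():
            if np.isnan(label):
                continue
            label = int(label)
            cell = (key, target)
            if rng.random() < spec.conflict_rate:
                conflict_cells.add(cell)
                records.append(measurement(key, target, 1, 0))
                records.append(measurement(key, target, 0, 1))
            else:
                for a in range(int(rng.integers(1, spec.max_assays_per_cell + 1))):
                    records.append(measurement(key, target, label, a))
            if rng.random() < spec.precurated_rate:
                precurated_cells.add(cell)
                records.append(ActivityRecord(
                    compound=entry(key, "precurated"), target_id=target,
                    precomputed_label=label, assay_id=f"precurated_{key[:6]}",
                    source="precurated"))
    info = {"conflict_cells": conflict_cells,
            "precurated_cells": precurated_cells}
    return records, info


def expected_after_collation(matrix: LabelMatrix, info: dict) -> LabelMatrix:
    """Truth matrix with unresolved conflict cells blanked.

    A conflicted cell survives only when a pre-curated record overrides it.
    """
    df = matrix.labels.copy()
    for key, target in info["conflict_cells"] - info["precurated_cells"]:
        df.at[key, target] = np.nan
    return LabelMatrix(labels=df)


# ---------------------------------------------------------------------------
# Template structures
# ---------------------------------------------------------------------------

#: Scaffold library for template mode: ring systems seen in transporter
#: inhibitor series (quinoline, chromone/flavone, acridone cores and friends).
SCAFFOLD_LIBRARY = (
    "c1ccc2ncccc2c1",                    # quinoline
    "O=c1cc(-c2ccccc2)oc2ccccc12",       # flavone
    "O=C1c2ccccc2Nc2ccccc21",            # acridone
    "c1ccc(-c2ccccc2)cc1",               # biphenyl
    "c1ccc2[nH]ccc2c1",                  # indole
    "c1ccc2[nH]cnc2c1",                  # benzimidazole
    "C1CN(c2ccccc2)CCN1",                # phenylpiperazine
    "O=c1ccoc2ccccc12",                  # chromone
)

_CHAIN_ATOMS_APOLAR = ("C",)
_CHAIN_ATOMS_POLAR = ("O", "N", "C")


def _attach_chain(mol: Chem.RWMol, rng, length: int, polar: bool) -> None:
    """Graft an acyclic substituent onto a random substitutable ring atom."""
    mol.UpdatePropertyCache(strict=False)
    candidates = [a.GetIdx() for a in mol.GetAtoms()
                  if a.GetTotalNumHs() > 0 and a.IsInRing()
                  and a.GetSymbol() == "C"]
    if not candidates:
        return
    anchor = int(rng.choice(candidates))
    pool = _CHAIN_ATOMS_POLAR if polar else _CHAIN_ATOMS_APOLAR
    prev = anchor
    for i in range(length):
        sym = str(rng.choice(pool)) if i > 0 else "C"
        idx = mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(prev, idx, Chem.BondType.SINGLE)
        prev = idx


def generate_structures(classes: Sequence[int], seed: int,
                        scaffold_choices: Optional[Sequence[int]] = None
                        ) -> list[CompoundEntry]:
    """Build parseable molecules whose descriptors track the planted class.

    Each compound takes a scaffold from :data:`SCAFFOLD_LIBRARY` (uniformly,
    or as dictated by ``scaffold_choices``) and acyclic substituents chosen
    by class: P-gp-selective compounds get long alkyl chains (raising a_hyd),
    BCRP-selective ones short polar chains (keeping a_hyd low).  Murcko
    profiling on the output recovers the planted scaffold clusters because
    side chains are acyclic.
    """
    rng = np.random.default_rng(seed)
    classes = np.asarray(classes, dtype=int)
    entries = []
    for i, cls in enumerate(classes):
        s_idx = (int(scaffold_choices[i]) if scaffold_choices is not None
                 else int(rng.integers(0, len(SCAFFOLD_LIBRARY))))
        mol = Chem.RWMol(Chem.MolFromSmiles(SCAFFOLD_LIBRARY[s_idx]))
        polar = cls in (0, 2)
        n_chains = 1 + int(rng.integers(0, 2))
        for _ in range(n_chains):
            length = (int(rng.integers(4, 9)) if cls in (1, 3)
                      else int(rng.integers(1, 4)))
            _attach_chain(mol, rng, length, polar)
        out = mol.GetMol()
        Chem.SanitizeMol(out)
        entry = CompoundEntry(compound_id=f"synt_{i}",
                              structure=Chem.MolToSmiles(out))
        entries.append(compute_inchikey(entry))
    return entries


# ---------------------------------------------------------------------------
# Label-dependence scenario (chain vs binary relevance)
# ---------------------------------------------------------------------------

def generate_label_dependence_scenario(
    n: int = 800, n_features: int = 60, n_informative: int = 20,
    flip: float = 0.10, b_annotated: float = 0.12, seed: int = 0,
) -> tuple[pd.DataFrame, LabelMatrix]:
    """A two-label dataset where label coupling is the practical route to B.

    Label A is a noisy linear function of ``n_informative`` of the features
    and is annotated for every compound; label B is A with a fraction
    ``flip`` of its values inverted, annotated only for a small fraction
    ``b_annotated`` of the compounds.  B carries no information beyond A.

    A binary-relevance model for B must recover the ``n_informative``-
    dimensional signal from the handful of B-annotated rows and drowns in
    the noise features.  A classifiers chain ordered (A, B) first learns A
    from the full dataset, appends its predicted score — a learned one-
    dimensional summary of the signal — and the B model only has to weight
    that single column.  The chain's advantage on B is therefore planted by
    construction.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    w = np.zeros(n_features)
    w[:n_informative] = rng.normal(size=n_informative)
    w[:n_informative] /= np.linalg.norm(w[:n_informative])
    logits = 3.0 * (X @ w)
    a = (logits + rng.normal(scale=0.5, size=n) > 0).astype(float)
    b = a.copy()
    flips = rng.random(n) < flip
    b[flips] = 1.0 - b[flips]
    keys = [synthetic_inchikey(i) for i in range(n)]
    labels = pd.DataFrame({"A": a, "B": b}, index=keys)
    keep_b = rng.random(n) < b_annotated
    labels.loc[~keep_b, "B"] = np.nan
    features = pd.DataFrame(X, index=keys,
                            columns=[f"x{i}" for i in range(n_features)])
    return features, LabelMatrix(labels=labels)
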
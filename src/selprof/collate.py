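"""Collation of raw activity records into binary label matrices.

The pipeline mirrors a standard open-data curation protocol for transporter
inhibition: keep IC50/EC50/Ki values in nanomolar, drop values above 1e8 nM
(data-entry errors), convert to pActivity = -log10(molar), call a compound
active when pActivity exceeds 5 (i.e. more potent than 10 uM), resolve
censored relation signs conservatively, pivot on InChIKey x target, and take
a per-cell consensus: pre-curated labels win outright, otherwise the median
of the open-data labels decides and an exact 0.5 median (an even split)
removes the cell.

Two datasets fall out of the pivot: the *sparse* matrix (compounds annotated
for at least one target) and the *dense* matrix (compounds annotated for all
targets), the latter being the only one a label-powerset model can use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import ActivityRecord

AMBIGUOUS = "ambiguous"

#: Activity values above this (in nM) are treated as data errors and dropped.
SANITY_CAP_NM = 1e8

#: pActivity cutoff: > 5 (i.e. < 10 uM) defines an active compound.
ACTIVITY_CUTOFF = 5.0


def to_plog(value_nM: float) -> float:
    """Convert a nanomolar activity value to pActivity (-log10 molar).

    10000 nM (10 uM) maps to exactly 5.0, the activity cutoff.
    """
    if value_nM <= 0:
        raise ValueError(f"activity value must be positive, got {value_nM}")
    return -math.log10(value_nM * 1e-9)


def sanity_filter(record: ActivityRecord, cap_nM: float = SANITY_CAP_NM) -> bool:
    """True (keep) unless the value exceeds the cap; the bound is strict.

    Pre-curated label-only records always pass (they carry no value).
    """
    if record.value_nM is None:
        return record.precomputed_label is not None
    return record.value_nM <= cap_nM


def binarize(pactivity: float, relation: str = "=",
             cutoff: float = ACTIVITY_CUTOFF):
    """Map (pActivity, relation) to a binary label, or ``"ambiguous"``.

    For an exact measurement the cutoff is strict: active iff pActivity >
    cutoff.  A "<" / "<=" relation on the concentration means the true
    pActivity is at least the computed one (a lower bound): the record can
    only assert activity, and does so when the bound already reaches the
    cutoff.  Symmetrically ">" / ">=" gives an upper bound that can only
    assert inactivity.  Ambiguous records are excluded downstream — censored
    values weaker than 10 uM are never counted as actives.
    """
    if not math.isfinite(pactivity):
        raise ValueError("pActivity must be finite")
    if relation == "=":
        return 1 if pactivity > cutoff else 0
    if relation in ("<", "<="):
        return 1 if pactivity >= cutoff else AMBIGUOUS
    if relation in (">", ">="):
        return 0 if pactivity <= cutoff else AMBIGUOUS
    raise ValueError(f"unknown relation {relation!r}")


@dataclass(frozen=True)
class BinaryObservation:
    """One binarized measurement keyed by InChIKey and target."""

    inchikey: str
    target_id: str
    label: int
    assay_id: str = ""
    source: str = "open"

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def records_to_observations(
    records: Iterable[ActivityRecord],
    cutoff: float = ACTIVITY_CUTOFF,
    cap_nM: float = SANITY_CAP_NM,
    rejection_log: Optional[list] = None,
) -> list[BinaryObservation]:
    """Apply sanity filter + log transform + binarization to raw records.

    Records must already carry InChIKeys on their compounds.  Ambiguous
    relation-sign records and cap violations are dropped (and logged).
    """
    log = rejection_log if rejection_log is not None else []
    out: list[BinaryObservation] = []
    for rec in records:
        key = rec.compound.inchikey
        if not key:
            log.append((rec.compound.compound_id, "binarize", "missing_inchikey"))
            continue
        if not sanity_filter(rec, cap_nM):
            log.append((key, "sanity_filter", "value_above_cap"))
            continue
        if rec.precomputed_label is not None:
            label = rec.precomputed_label
        else:
            label = binarize(to_plog(rec.value_nM), rec.relation, cutoff)
            if label == AMBIGUOUS:
                log.append((key, "binarize", "ambiguous_relation"))
                continue
        out.append(BinaryObservation(key, rec.target_id, label,
                                     rec.assay_id, rec.source))
    return out


@dataclass
class LabelMatrix:
    """Compounds x targets binary labels with an explicit missing mask.

    ``labels`` is a DataFrame indexed by InChIKey with one column per target;
    cells are 0.0, 1.0 or NaN (missing).  ``provenance`` maps
    (inchikey, target) to the list of (assay_id, label, source) observations
    that produced the cell.
    """

    labels: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def inchikeys(self) -> list[str]:
        return list(self.labels.index)

    @property
    def targets(self) -> list[str]:
        return list(self.labels.columns)

    @property
    def shape(self):
        return self.labels.shape

    def n_annotated(self) -> int:
        return int(self.labels.notna().sum().sum())

    def to_tsv(self, path: str | Path) -> None:
        df = self.labels.copy()
        df.index.name = "inchikey"
        df.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabelMatrix":
        df = pd.read_csv(path, sep="\t", index_col="inchikey", na_values=["NA"])
        return cls(labels=df.astype(float))

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabelMatrix):
            return NotImplemented
        a, b = self.labels, other.labels
        return (a.index.equals(b.index) and a.columns.equals(b.columns)
                and a.fillna(-1).eq(b.fillna(-1)).all().all())


def consensus(cell: Sequence[tuple]) -> Optional[int]:
    """Resolve one cell's provenance list to a final label, or None (drop).

    Pre-curated labels take priority; if several pre-curated labels conflict
    the cell is dropped.  Otherwise the median of the open labels decides,
    and a median of exactly 0.5 (even split) drops the cell.  Order-invariant.
    """
    if not cell:
        raise ValueError("consensus of an empty provenance list")
    pre = {label for _, label, source in cell if source == "precurated"}
    if pre:
        return pre.pop() if len(pre) == 1 else None
    med = float(np.median([label for _, label, _ in cell]))
    if med == 0.5:
        return None
    return int(med > 0.5)


def pivot(observations: Iterable[BinaryObservation],
          targets: Optional[Sequence[str]] = None) -> LabelMatrix:
    """Group observations by InChIKey (rows) and target (columns).

    Each cell holds the consensus label of all observations for that pair;
    cells whose consensus drops (conflict) become missing but keep their
    provenance.  Row and column order follow first appearance unless a target
    order is given.
    """
    prov: dict = {}
    row_order: list[str] = []
    col_order: list[str] = list(targets) if targets else []
    for obs in observations:
        if obs.inchikey not in prov:
            prov[obs.inchikey] = {}
            row_order.append(obs.inchikey)
        if obs.target_id not in col_order:
            col_order.append(obs.target_id)
        prov[obs.inchikey].setdefault(obs.target_id, []).append(
            (obs.assay_id, obs.label, obs.source)
        )
    data = np.full((len(row_order), len(col_order)), np.nan)
    provenance = {}
    for i, key in enumerate(row_order):
        for j, tgt in enumerate(col_order):
            cell = prov[key].get(tgt)
            if cell is None:
                continue
            provenance[(key, tgt)] = list(cell)
            label = consensus(cell)
            if label is not None:
                data[i, j] = label
    labels = pd.DataFrame(data, index=row_order, columns=col_order)
    return LabelMatrix(labels=labels, provenance=provenance)


def build_datasets(matrix: LabelMatrix) -> tuple[LabelMatrix, LabelMatrix]:
    """Split the pivot into the (sparse, dense) datasets.

    Sparse keeps rows annotated for at least one target; dense keeps rows
    annotated for every target.  Dense is always a subset of sparse.
    """
    if matrix.labels.shape[1] == 0:
        raise ValueError("label matrix has no target columns")
    notna = matrix.labels.notna()
    sparse = matrix.labels.loc[notna.any(axis=1)]
    dense = matrix.labels.loc[notna.all(axis=1)]
    sub = lambda df: LabelMatrix(
        labels=df.copy(),
        provenance={k: v for k, v in matrix.provenance.items() if k[0] in df.index},
    )
    return sub(sparse), sub(dense)


def heatmap_table(matrix: LabelMatrix) -> pd.DataFrame:
    """Exportable binary heat-map table: rows compounds, columns targets.

    Cells are 0, 1 or NA; NA renders distinctly from 0.  Round-trips through
    TSV via :meth:`LabelMatrix.to_tsv` / :meth:`LabelMatrix.from_tsv`.
    """
    if matrix.labels.empty:
        raise ValueError("empty label matrix")
    return matrix.labels.copy()


def render_heatmap(matrix: LabelMatrix, path: str | Path) -> None:
    """Render the binary heat map to PNG/SVG (red=1, blue=0, grey=missing)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    arr = matrix.labels.to_numpy(dtype=float)
    masked = np.ma.masked_invalid(arr)
    cmap = ListedColormap(["#3b4cc0", "#b40426"])
    cmap.set_bad("#cccccc")
    fig, ax = plt.subplots(figsize=(2 + 0.6 * arr.shape[1], 2 + 0.08 * arr.shape[0]))
    ax.imshow(masked, aspect="auto", cmap=cmap, vmin=0, vmax=1, interpolation="nearest")
    ax.set_xticks(range(arr.shape[1]), matrix.targets, rotation=45, ha="right")
    ax.set_ylabel("compounds")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def collate(
    records: Iterable[ActivityRecord],
    cutoff: float = ACTIVITY_CUTOFF,
    cap_nM: float = SANITY_CAP_NM,
    targets: Optional[Sequence[str]] = None,
    rejection_log: Optional[list] = None,
) -> tuple[LabelMatrix, LabelMatrix, LabelMatrix]:
    """Full collation: records -> (pivot, sparse, dense).  Deterministic."""
    obs = records_to_observations(records, cutoff, cap_nM, rejection_log)
    matrix = pivot(obs, targets=targets)
    sparse, dense = build_datasets(matrix)
    return matrix, sparse, dense
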
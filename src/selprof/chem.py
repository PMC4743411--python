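"""Structure and activity-record input/output, standardization and compound keys.

Compounds arrive either as SDF files (pre-curated in-house sets) or as rows of a
delimited activity table (open-data exports).  Before any merging, every
structure is *washed*: salts stripped to the largest organic fragment, simple
protonation states neutralized, and mixtures, organometallics and molecules
containing elements outside the conventional drug-like set rejected.  The
27-character standard InChIKey of the washed structure is the merge key used
to pivot activity data across targets.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Elements tolerated in washed structures (the conventional drug-like set).
ALLOWED_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"]
)

#: Metals whose bond to carbon marks a molecule as organometallic.
_METALS = frozenset(
    ["Li", "Na", "K", "Rb", "Cs", "Be", "Mg", "Ca", "Sr", "Ba", "Al", "Ga",
     "In", "Tl", "Sn", "Pb", "Bi", "Fe", "Co", "Ni", "Cu", "Zn", "Mn", "Cr",
     "V", "Ti", "Sc", "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag",
     "Cd", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg"]
)

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

ENDPOINTS = ("IC50", "EC50", "Ki")
RELATIONS = ("=", "<", ">", "<=", ">=")


class RejectionError(ValueError):
    """A compound or record failed a curation rule; carries a reason code."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class CompoundEntry:
    """One compound: an opaque id, a structure string and its provenance."""

    compound_id: str
    structure: str  # SMILES (or InChI on input)
    inchikey: Optional[str] = None
    source: str = "open"  # "open" | "precurated"

    def mol(self) -> Chem.Mol:
        m = _parse_structure(self.structure)
        if m is None:
            raise RejectionError("unparseable_structure", self.structure)
        return m


@dataclass(frozen=True)
class ActivityRecord:
    """One raw compound-target measurement (or a pre-curated binary label)."""

    compound: CompoundEntry
    target_id: str
    endpoint: Optional[str] = None  # IC50 | EC50 | Ki; None for label rows
    value_nM: Optional[float] = None
    relation: str = "="
    assay_id: str = ""
    source: str = "open"
    precomputed_label: Optional[int] = None

    def __post_init__(self):
        if self.value_nM is None and self.precomputed_label is None:
            raise ValueError("record needs a value_nM or a precomputed_label")
        if self.value_nM is not None and self.value_nM <= 0:
            raise ValueError("value_nM must be positive")


def _parse_structure(structure: str) -> Optional[Chem.Mol]:
    if structure.startswith("InChI="):
        return Chem.MolFromInchi(structure)
    return Chem.MolFromSmiles(structure)


# ---------------------------------------------------------------------------
# SDF and activity-table input
# ---------------------------------------------------------------------------

def read_sdf(path: str | Path, source: str = "precurated") -> list[CompoundEntry]:
    """Read an SDF (V2000) file; one entry per parseable molecule block.

    Unparseable blocks are skipped and counted in the log.  Raises
    ``FileNotFoundError`` for a missing file and ``RejectionError`` when the
    file contains no parseable molecule at all.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    entries: list[CompoundEntry] = []
    skipped = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            skipped += 1
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf_{i}"
        entries.append(
            CompoundEntry(compound_id=cid, structure=Chem.MolToSmiles(mol), source=source)
        )
    if skipped:
        logger.warning("read_sdf(%s): skipped %d unparseable blocks", path, skipped)
    if not entries:
        raise RejectionError("empty_input", f"no parseable molecules in {path}")
    return entries


def write_sdf(entries: Iterable[CompoundEntry], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for e in entries:
            m = e.mol()
            m.SetProp("_Name", e.compound_id)
            writer.write(m)
    finally:
        writer.close()


#: Default column names for delimited activity tables.
DEFAULT_COLUMNS = {
    "compound_id": "compound_id",
    "structure": "structure",
    "target_id": "target_id",
    "endpoint": "endpoint",
    "value": "value",
    "unit": "unit",
    "relation": "relation",
    "assay_id": "assay_id",
    "source": "source",
    "label": "label",
}


def read_activity_table(
    path: str | Path,
    columns: Optional[dict] = None,
    delimiter: str = "\t",
    rejection_log: Optional[list] = None,
) -> list[ActivityRecord]:
    """Read a delimited activity table into raw records.

    Each row must carry either a measured value in nanomolar or a precomputed
    binary label.  Rows with other units, unknown relation symbols, unknown
    endpoints or non-positive values are rejected; rejections are appended to
    ``rejection_log`` as (row_index, stage, reason) when given.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    records: list[ActivityRecord] = []
    log = rejection_log if rejection_log is not None else []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        for i, row in enumerate(reader):
            try:
                records.append(_row_to_record(row, cols))
            except RejectionError as exc:
                log.append((i, "read_activity_table", exc.reason))
    if rejection_log is None and log:
        logger.warning("read_activity_table(%s): rejected %d rows", path, len(log))
    return records


_NM_UNITS = {"nm", "nanomolar"}


def _row_to_record(row: dict, cols: dict) -> ActivityRecord:
    get = lambda key: (row.get(cols[key]) or "").strip()
    label_txt = get("label")
    value_txt = get("value")
    entry = CompoundEntry(
        compound_id=get("compound_id") or get("structure"),
        structure=get("structure"),
        source=get("source") or "open",
    )
    if value_txt:
        unit = get("unit").lower()
        if unit and unit not in _NM_UNITS:
            raise RejectionError("unit_not_nanomolar", unit)
        relation = get("relation") or "="
        if relation not in RELATIONS:
            raise RejectionError("unknown_relation", relation)
        endpoint = get("endpoint")
        if endpoint not in ENDPOINTS:
            raise RejectionError("endpoint_not_allowed", endpoint)
        try:
            value = float(value_txt)
        except ValueError:
            raise RejectionError("unparseable_value", value_txt)
        if value <= 0:
            raise RejectionError("non_positive_value", value_txt)
        return ActivityRecord(
            compound=entry, target_id=get("target_id"), endpoint=endpoint,
            value_nM=value, relation=relation, assay_id=get("assay_id"),
            source=entry.source,
        )
    if label_txt in {"0", "1"}:
        return ActivityRecord(
            compound=entry, target_id=get("target_id"),
            precomputed_label=int(label_txt), assay_id=get("assay_id"),
            source=entry.source or "precurated",
        )
    raise RejectionError("unspecified_activity")


# ---------------------------------------------------------------------------
# Standardization ("wash")
# ---------------------------------------------------------------------------

_uncharger = rdMolStandardize.Uncharger()


def standardize(entry: CompoundEntry) -> CompoundEntry:
    """Wash a structure: keep the largest organic fragment and neutralize it.

    Raises :class:`RejectionError` for unparseable input, organometallics
    (metal-carbon bond), elements outside :data:`ALLOWED_ELEMENTS`, and
    mixtures whose two largest fragments tie on heavy-atom count (no unique
    parent can be chosen).  Idempotent on its own output.
    """
    mol = _parse_structure(entry.structure)
    if mol is None:
        raise RejectionError("unparseable_structure", entry.structure)

    for bond in mol.GetBonds():
        syms = {bond.GetBeginAtom().GetSymbol(), bond.GetEndAtom().GetSymbol()}
        if syms & _METALS and "C" in syms:
            raise RejectionError("organometallic", entry.compound_id)

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        organic = [f for f in frags if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
        pool = organic or list(frags)
        pool.sort(key=lambda f: f.GetNumHeavyAtoms(), reverse=True)
        if len(pool) > 1 and pool[0].GetNumHeavyAtoms() == pool[1].GetNumHeavyAtoms():
            raise RejectionError("unresolvable_mixture", entry.compound_id)
        mol = pool[0]

    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ALLOWED_ELEMENTS:
            raise RejectionError("rare_element", atom.GetSymbol())

    mol = _uncharger.uncharge(mol)
    Chem.SanitizeMol(mol)
    return replace(entry, structure=Chem.MolToSmiles(mol))


def compute_inchikey(entry: CompoundEntry) -> CompoundEntry:
    """Attach the standard 27-character InChIKey of the (washed) structure."""
    mol = entry.mol()
    key = Chem.MolToInchiKey(mol)
    if not key or not INCHIKEY_RE.match(key):
        raise RejectionError("inchi_failure", entry.compound_id)
    return replace(entry, inchikey=key)


def wash_pipeline(
    entries: Iterable[CompoundEntry],
    rejection_log: Optional[list] = None,
) -> list[CompoundEntry]:
    """standardize + compute_inchikey over a batch, logging rejections."""
    out = []
    log = rejection_log if rejection_log is not None else []
    for e in entries:
        try:
            out.append(compute_inchikey(standardize(e)))
        except RejectionError as exc:
            log.append((e.compound_id, "wash", exc.reason))
    return out


def write_rejection_log(log: Sequence[tuple], path: str | Path) -> None:
    """Rejection log as TSV: compound_id/row, stage, reason."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["compound_id", "stage", "reason"])
        for row in log:
            w.writerow(row)
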
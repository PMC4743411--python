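"""Interpretable molecular descriptors, fingerprints and Murcko scaffolds.

The panel is the small set of physically readable 2D descriptors that drive
transporter-selectivity interpretation: atom counts (aromatic, hydrophobic,
donor/acceptor), Crippen SlogP, the acceptor van-der-Waals surface area, two
distance-based topological indices (Wiener path sum and Balaban's J), and the
additive atomic-polarizability sum.  Names follow the MOE convention the
field uses (a_aro, a_hyd, SlogP, vsa_acc, BalabanJ, a_donacc, weinerPath,
apol) but the numerics are open re-definitions, documented here, not MOE's
proprietary ones.

Atom typing (hydrophobic, donor, acceptor) is fixed by the SMARTS patterns
below so every count is auditable.  Graph descriptors run on the
hydrogen-suppressed heavy-atom graph; apol includes hydrogens.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

PANEL = ["a_aro", "a_hyd", "SlogP", "vsa_acc", "BalabanJ", "a_donacc",
         "weinerPath", "apol"]

#: Hydrophobic atoms: carbons with no neighbouring heteroatom (N, O, S, P),
#: plus halogens bound to carbon.  Carbons next to a polar atom are excluded.
HYDROPHOBIC_SMARTS = ("[#6;!$([#6]~[#7,#8,#16,#15])]", "[F,Cl,Br,I;$(*[#6])]")

#: H-bond donor: N or O carrying at least one hydrogen.
DONOR_SMARTS = "[$([#7;!H0]),$([#8;!H0])]"

#: H-bond acceptor: N or O with a lone pair — not positively charged and not
#: a pyrrole-type aromatic N donating its pair into the ring.
ACCEPTOR_SMARTS = "[$([#8;-,X1,X2;!+]),$([#7;!+;!$([nH]);!$([N;H2;+0;!$(N-a)]C=O)])]"

_HYD_PATTERNS = [Chem.MolFromSmarts(s) for s in HYDROPHOBIC_SMARTS]
_DONOR = Chem.MolFromSmarts(DONOR_SMARTS)
_ACCEPTOR = Chem.MolFromSmarts(ACCEPTOR_SMARTS)

with resources.files("selprof.data").joinpath("polarizabilities.json").open() as _fh:
    _APOL_TABLE = {k: v for k, v in json.load(_fh).items() if not k.startswith("_")}


def _as_mol(mol) -> Chem.Mol:
    if isinstance(mol, str):
        m = Chem.MolFromSmiles(mol)
        if m is None:
            raise ValueError(f"unparseable SMILES {mol!r}")
        return m
    return mol


# ---------------------------------------------------------------------------
# Atom counts
# ---------------------------------------------------------------------------

def count_aromatic_atoms(mol) -> int:
    """a_aro: number of atoms the aromaticity perceiver flags aromatic."""
    mol = _as_mol(mol)
    return sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())


def count_hydrophobic_atoms(mol) -> int:
    """a_hyd: heavy atoms matching :data:`HYDROPHOBIC_SMARTS`.

    Methane counts 1; methanol counts 0 (its carbon touches oxygen).
    """
    mol = _as_mol(mol)
    matched = set()
    for patt in _HYD_PATTERNS:
        for (idx,) in mol.GetSubstructMatches(patt):
            matched.add(idx)
    return len(matched)


def a_donacc(mol) -> int:
    """Number of distinct H-bond donor or acceptor atoms (union, not sum)."""
    mol = _as_mol(mol)
    atoms = {i for (i,) in mol.GetSubstructMatches(_DONOR)}
    atoms |= {i for (i,) in mol.GetSubstructMatches(_ACCEPTOR)}
    return len(atoms)


# ---------------------------------------------------------------------------
# Continuous descriptors
# ---------------------------------------------------------------------------

def slogp(mol) -> float:
    """Crippen atomic-contribution logP (additive over disjoint fragments)."""
    return Crippen.MolLogP(_as_mol(mol))


def vsa_acc(mol) -> float:
    """Approximate van-der-Waals surface area (A^2) of H-bond acceptor atoms.

    Labute approximate-surface-area atomic contributions summed over atoms
    matching :data:`ACCEPTOR_SMARTS`.
    """
    mol = _as_mol(mol)
    contribs = rdMolDescriptors._CalcLabuteASAContribs(mol)[0]
    acceptors = {i for (i,) in mol.GetSubstructMatches(_ACCEPTOR)}
    return float(sum(contribs[i] for i in acceptors))


def apol(mol) -> float:
    """Sum of atomic polarizabilities (A^3), hydrogens included."""
    mol = _as_mol(mol)
    total = 0.0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in _APOL_TABLE:
            raise ValueError(f"no polarizability tabulated for element {sym}")
        total += _APOL_TABLE[sym] + atom.GetTotalNumHs() * _APOL_TABLE["H"]
    return total


# ---------------------------------------------------------------------------
# Topological indices (heavy-atom graph)
# ---------------------------------------------------------------------------

def _distance_matrix(mol) -> np.ndarray:
    """Topological (bond-count) distances between heavy atoms via BFS."""
    n = mol.GetNumAtoms()
    adj = [[] for _ in range(n)]
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        adj[i].append(j)
        adj[j].append(i)
    dist = np.full((n, n), -1, dtype=int)
    for s in range(n):
        dist[s, s] = 0
        queue = [s]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if dist[s, v] < 0:
                        dist[s, v] = dist[s, u] + 1
                        nxt.append(v)
            queue = nxt
    if (dist < 0).any():
        raise ValueError("molecular graph is disconnected; wash first")
    return dist


def wiener_path(mol) -> int:
    """weinerPath: sum of shortest-path lengths over heavy-atom pairs."""
    mol = _as_mol(mol)
    if mol.GetNumAtoms() < 2:
        return 0
    dist = _distance_matrix(mol)
    return int(dist.sum() // 2)


def balaban_j(mol) -> float:
    """Balaban's distance-sum connectivity index J.

    J = q/(mu+1) * sum over edges (s_i * s_j)^(-1/2), with q the number of
    heavy-atom bonds, mu = q - n + 1 the cyclomatic number and s_i the row
    sum of the topological distance matrix.  Single-atom molecules give 0 by
    convention.
    """
    mol = _as_mol(mol)
    n = mol.GetNumAtoms()
    if n < 2:
        return 0.0
    dist = _distance_matrix(mol)
    s = dist.sum(axis=1).astype(float)
    q = mol.GetNumBonds()
    mu = q - n + 1
    total = 0.0
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        total += 1.0 / np.sqrt(s[i] * s[j])
    return q / (mu + 1.0) * total


# ---------------------------------------------------------------------------
# Fingerprints and scaffolds
# ---------------------------------------------------------------------------

def maccs(mol) -> np.ndarray:
    """166-bit MACCS keys (rdkit emits 167 bits; bit 0 is always unset and
    dropped)."""
    fp = rdMolDescriptors.GetMACCSKeysFingerprint(_as_mol(mol))
    arr = np.zeros(167, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr[1:]


def morgan(mol, radius: int = 4, nbits: int = 1024) -> np.ndarray:
    """Morgan circular fingerprint, diameter 8 (radius 4), folded to 1024 bits."""
    from rdkit.Chem import rdFingerprintGenerator
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    fp = gen.GetFingerprint(_as_mol(mol))
    arr = np.zeros(nbits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def murcko_scaffold(mol) -> str:
    """Canonical SMILES of the Bemis-Murcko framework (rings + linkers).

    Acyclic molecules return the empty string.
    """
    mol = _as_mol(mol)
    scaff = MurckoScaffold.GetScaffoldForMol(mol)
    if scaff is None or scaff.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaff)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

_FUNCS = {
    "a_aro": count_aromatic_atoms,
    "a_hyd": count_hydrophobic_atoms,
    "SlogP": slogp,
    "vsa_acc": vsa_acc,
    "BalabanJ": balaban_j,
    "a_donacc": a_donacc,
    "weinerPath": wiener_path,
    "apol": apol,
}


def descriptor_table(
    structures: dict[str, str] | Sequence[tuple[str, str]],
    panel: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Compute the named descriptor panel for {compound_key: SMILES}.

    Returns a DataFrame indexed by compound key with one column per
    descriptor.  Write/read with ``to_csv(sep="\\t")`` — plain TSV.
    """
    items = structures.items() if isinstance(structures, dict) else structures
    panel = list(panel) if panel is not None else list(PANEL)
    rows = {}
    for key, smi in items:
        mol = _as_mol(smi)
        rows[key] = [_FUNCS[name](mol) for name in panel]
    return pd.DataFrame.from_dict(rows, orient="index", columns=panel)


def fingerprint_table(structures: dict[str, str], kind: str = "morgan",
                      **kwargs) -> pd.DataFrame:
    """Bit-fingerprint matrix (rows compounds) for 'morgan' or 'maccs'."""
    fn = {"morgan": morgan, "maccs": maccs}[kind]
    rows = {k: fn(smi, **kwargs) for k, smi in structures.items()}
    width = len(next(iter(rows.values())))
    cols = [f"{kind}_{i}" for i in range(width)]
    return pd.DataFrame.from_dict(rows, orient="index").set_axis(cols, axis=1)
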
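"""Collate raw multi-source activity records into label matrices.

Builds a handful of IC50/Ki measurements for two transporters — including a
conflicting pair of assays and a pre-curated label that overrides another
conflict — and runs the full collation: nanomolar values become pActivity
(-log10 molar), records binarize at the 10 uM cutoff (pActivity > 5),
observations pivot on InChIKey x target, and the median/priority consensus
resolves each cell.
"""

from selprof import ActivityRecord, CompoundEntry, collate

K1 = "A" * 14 + "-" + "A" * 10 + "-N"
K2 = "B" * 14 + "-" + "B" * 10 + "-N"
K3 = "C" * 14 + "-" + "C" * 10 + "-N"


def rec(key, target, value=None, relation="=", label=None, source="open",
        assay="a0"):
    return ActivityRecord(
        compound=CompoundEntry(key[:4], "CCO", inchikey=key, source=source),
        target_id=target, endpoint="IC50" if value else None,
        value_nM=value, relation=relation, assay_id=assay, source=source,
        precomputed_label=label)


records = [
    # compound 1: potent on P-gp (three concordant assays), weak on BCRP
    rec(K1, "P-gp", 120.0, assay="a1"),
    rec(K1, "P-gp", 250.0, assay="a2"),
    rec(K1, "P-gp", 90.0, assay="a3"),
    rec(K1, "BCRP", 50000.0, assay="a4"),
    # compound 2: conflicting open assays on BCRP (even split -> dropped)
    rec(K2, "BCRP", 800.0, assay="a5"),
    rec(K2, "BCRP", 60000.0, assay="a6"),
    rec(K2, "P-gp", 2000.0, assay="a7"),
    # compound 3: conflict on P-gp rescued by a pre-curated label
    rec(K3, "P-gp", 300.0, assay="a8"),
    rec(K3, "P-gp", 90000.0, assay="a9"),
    rec(K3, "P-gp", label=1, source="precurated", assay="lit"),
    # censored record: IC50 > 50 uM can only assert inactivity
    rec(K3, "BCRP", 50000.0, relation=">", assay="a10"),
]

matrix, sparse, dense = collate(records, targets=["P-gp", "BCRP"])

print("Pivoted label matrix (1 active, 0 inactive, NaN unresolved/missing):")
print(matrix.labels)
print()
print(f"sparse dataset: {len(sparse.inchikeys)} compounds with >=1 label")
print(f"dense dataset:  {len(dense.inchikeys)} compounds with both labels")
print()
print("Compound 2's BCRP cell is NaN: its two assays disagreed and the")
print("0.5-median rule removed it.  Compound 3's P-gp cell is 1: the")
print("pre-curated label took priority over the conflicting open assays.")
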
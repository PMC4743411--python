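"""End-to-end seeded pipeline runs with a reproducibility manifest.

`run_pipeline` wires the stages — simulate raw records, collate them into
sparse/dense matrices, train a multi-label model, cross-validate — from one
:class:`RunConfig`.  Every stochastic stage derives its seed from the
config's global seed, and every run writes a JSON manifest (config, derived
seeds, package version, output checksums) next to its outputs, so the same
config reproduces the same artifacts bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .collate import collate
from .multilabel import cross_validate
from .synthetic import (GeneratorSpec, apply_label_noise, expected_after_collation,
                        generate_activity_records, generate_descriptors,
                        generate_labels, sparsify)


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: generator conditions, model spec and CV spec."""

    n_compounds: int = 1000
    annotation_overlap: float = 0.5
    label_noise: float = 0.1
    strategy: str = "binary_relevance"
    base_learner: str = "rf"
    folds: int = 10
    repeats: int = 1
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> collate -> train -> evaluate under one seed.

    Returns a dict with the evaluation report, the dataset shapes and the
    manifest; when ``config.outdir`` is set, writes the sparse/dense matrices
    (TSV), the report (JSON) and the manifest (JSON) there.
    """
    spec = GeneratorSpec(n_compounds=config.n_compounds,
                         annotation_overlap=config.annotation_overlap,
                         label_noise=config.label_noise)
    seeds = {stage: config.seed + k for k, stage in enumerate(
        ["labels", "noise", "sparsify", "records", "descriptors", "cv"])}
    truth, classes = generate_labels(spec, seeds["labels"])
    observed = apply_label_noise(truth, spec.label_noise, seeds["noise"])
    observed = sparsify(observed, spec.annotation_overlap, seeds["sparsify"])
    records, info = generate_activity_records(observed, spec, seeds["records"])
    _, sparse, dense = collate(records, targets=list(spec.targets))
    X = generate_descriptors(classes, seeds["descriptors"],
                             keys=truth.inchikeys)
    X_sparse = X.loc[sparse.inchikeys]
    report = cross_validate(X_sparse, sparse, strategy=config.strategy,
                            base_learner=config.base_learner,
                            folds=config.folds, repeats=config.repeats,
                            seed=seeds["cv"])
    expected = expected_after_collation(observed, info)
    result = {
        "report": report,
        "n_sparse": len(sparse.inchikeys),
        "n_dense": len(dense.inchikeys),
        "collation_matches_expectation": sparse.labels.fillna(-1).eq(
            expected.labels.loc[sparse.inchikeys].fillna(-1)).all().all(),
    }
    manifest = {
        "config": dataclasses.asdict(config),
        "derived_seeds": seeds,
        "selprof_version": __version__,
        "n_sparse": result["n_sparse"],
        "n_dense": result["n_dense"],
        "macro_auc": report.macro_auc,
    }
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        sparse.to_tsv(out / "sparse.tsv")
        dense.to_tsv(out / "dense.tsv")
        report.to_json(out / "evaluation.json")
        manifest["checksums"] = {
            p.name: _sha256(p)
            for p in (out / "sparse.tsv", out / "dense.tsv",
                      out / "evaluation.json")}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    result["manifest"] = manifest
    return result
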
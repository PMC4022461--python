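"""Readers and writers for the on-disk cohort layout.

Layout of a cohort directory::

    labels.tsv                  region_id <TAB> label  (header required)
    behavior.csv                subject_id, RT_A, RT_M, CS_A, CS_M, DP_A, DP_M
    ground_truth.csv            subject_id, archetype          (synthetic only)
    manifest.json               subject ids, file map, checksums
    spec.yaml                   resolved generator config      (synthetic only)
    <subject_id>/sc.csv         square CSV, region_id header row + index column
    <subject_id>/fc_rest.csv
    <subject_id>/dfc_attention.csv   task FC as deviation from rest
    <subject_id>/dfc_memory.csv

Matrices are square CSVs whose header row and first column carry region ids;
loaders verify that the ordering matches ``labels.tsv``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    Cohort,
    ConnectomeError,
    LabelingError,
    RegionLabeling,
    SubjectConnectome,
    zero_diagonal,
)

MATRIX_FILES = {
    "sc": "sc.csv",
    "fc_rest": "fc_rest.csv",
    "fc_attention": "dfc_attention.csv",
    "fc_memory": "dfc_memory.csv",
}

BEHAVIOR_COLUMNS = ["subject_id", "RT_A", "RT_M", "CS_A", "CS_M", "DP_A", "DP_M"]


def read_labels(path: Path | str) -> RegionLabeling:
    """Read a 2-column TSV (region_id, label) with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"region_id", "label"}
    if not required.issubset(df.columns):
        raise LabelingError(f"{path}: label file needs columns {sorted(required)}")
    return RegionLabeling(labels=df["label"].tolist(), region_ids=df["region_id"].tolist())


def write_labels(labeling: RegionLabeling, path: Path | str) -> None:
    pd.DataFrame({"region_id": labeling.region_ids, "label": labeling.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_matrix(path: Path | str, labeling: Optional[RegionLabeling] = None) -> np.ndarray:
    """Read a square region-by-region CSV; verify ordering against a labeling."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ConnectomeError(f"{path}: matrix is not square: {df.shape}")
    cols = [str(c) for c in df.columns]
    rows = [str(r) for r in df.index]
    if cols != rows:
        raise ConnectomeError(f"{path}: row and column region ids differ")
    if labeling is not None and tuple(cols) != labeling.region_ids:
        raise ConnectomeError(
            f"{path}: region ordering does not match the label file"
        )
    return zero_diagonal(df.to_numpy(dtype=float), name=str(path))


def write_matrix(matrix: np.ndarray, labeling: RegionLabeling, path: Path | str) -> None:
    ids = list(labeling.region_ids)
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, float_format="%.6g")


def read_behavior(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: behavior table missing columns {missing}")
    return df[BEHAVIOR_COLUMNS].assign(subject_id=df["subject_id"].astype(str))


def read_subject(directory: Path | str, subject_id: str, labeling: RegionLabeling) -> SubjectConnectome:
    d = Path(directory)
    mats = {key: read_matrix(d / fname, labeling) for key, fname in MATRIX_FILES.items()}
    return SubjectConnectome(subject_id=subject_id, **mats)


def write_subject(subject: SubjectConnectome, labeling: RegionLabeling, directory: Path | str) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for key, fname in MATRIX_FILES.items():
        write_matrix(getattr(subject, key), labeling, d / fname)


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort(cohort: Cohort, directory: Path | str, spec_yaml: Optional[str] = None) -> Path:
    """Write a cohort directory (matrices, labels, behavior, manifest)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_labels(cohort.labeling, d / "labels.tsv")
    files = ["labels.tsv"]
    for s in cohort.subjects:
        write_subject(s, cohort.labeling, d / s.subject_id)
        files.extend(f"{s.subject_id}/{fname}" for fname in MATRIX_FILES.values())
    if cohort.behavior is not None:
        cohort.behavior.to_csv(d / "behavior.csv", index=False)
        files.append("behavior.csv")
    if cohort.ground_truth is not None:
        cohort.ground_truth.to_csv(d / "ground_truth.csv", index=False)
        files.append("ground_truth.csv")
    if spec_yaml is not None:
        (d / "spec.yaml").write_text(spec_yaml)
        files.append("spec.yaml")
    manifest = {
        "subjects": [s.subject_id for s in cohort.subjects],
        "n_regions": cohort.labeling.n_regions,
        "files": {f: _file_sha256(d / f) for f in sorted(files)},
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return d


def read_cohort(directory: Path | str) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    labeling = read_labels(d / "labels.tsv")
    subjects = [read_subject(d / sid, sid, labeling) for sid in manifest["subjects"]]
    behavior = read_behavior(d / "behavior.csv") if (d / "behavior.csv").exists() else None
    gt = pd.read_csv(d / "ground_truth.csv") if (d / "ground_truth.csv").exists() else None
    return Cohort(subjects=subjects, labeling=labeling, behavior=behavior, ground_truth=gt)
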
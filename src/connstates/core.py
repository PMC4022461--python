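"""Domain types shared across the pipeline.

The analysis compares structural connectivity (SC, streamline counts from
tractography) against functional connectivity (FC, Pearson correlations of
regional BOLD time series) within and between the task-positive (P) and
task-negative (N) resting-state networks; remaining regions are "other" (O).
Every region pair therefore falls into one of six unordered coupling classes
(PP, NN, PN, PO, NO, OO), and all downstream statistics are computed per
class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("connstates")

REGION_CLASSES = ("P", "N", "O")

#: The three cognitive states FC is measured in.
STATES = ("rest", "attention", "memory")

SYMMETRY_TOL = 1e-9


class CouplingClass(str, Enum):
    """Unordered class of a region pair.

    PP: both task-positive; NN: both task-negative; PN: one of each;
    PO/NO/OO involve "other" regions and are lumped as OTHER in some reports.
    """

    PP = "PP"
    NN = "NN"
    PN = "PN"
    PO = "PO"
    NO = "NO"
    OO = "OO"

    @property
    def lumped_other(self) -> bool:
        return self in (CouplingClass.PO, CouplingClass.NO, CouplingClass.OO)


#: Canonical ordering used for vectorized class indices.
COUPLING_CLASSES = (
    CouplingClass.PP,
    CouplingClass.NN,
    CouplingClass.PN,
    CouplingClass.PO,
    CouplingClass.NO,
    CouplingClass.OO,
)

_PAIR_TO_CLASS = {
    ("P", "P"): CouplingClass.PP,
    ("N", "N"): CouplingClass.NN,
    ("P", "N"): CouplingClass.PN,
    ("N", "P"): CouplingClass.PN,
    ("P", "O"): CouplingClass.PO,
    ("O", "P"): CouplingClass.PO,
    ("N", "O"): CouplingClass.NO,
    ("O", "N"): CouplingClass.NO,
    ("O", "O"): CouplingClass.OO,
}


class LabelingError(ValueError):
    """Raised for invalid region labels or labelings."""


class ConnectomeError(ValueError):
    """Raised for structurally invalid connectome matrices."""


def classify_pair(label_i: str, label_j: str) -> CouplingClass:
    """Coupling class of the unordered region pair (i, j).

    Symmetric: ``classify_pair(a, b) == classify_pair(b, a)``.
    """
    try:
        return _PAIR_TO_CLASS[(label_i, label_j)]
    except KeyError:
        raise LabelingError(
            f"unknown region label in pair ({label_i!r}, {label_j!r}); "
            f"labels must be in {REGION_CLASSES}"
        ) from None


@dataclass(frozen=True)
class RegionLabeling:
    """Per-region class assignment defining the six coupling classes."""

    labels: tuple[str, ...]
    region_ids: tuple[str, ...]

    def __init__(self, labels: Sequence[str], region_ids: Optional[Sequence[str]] = None):
        labels = tuple(labels)
        if region_ids is None:
            region_ids = tuple(f"region_{i:04d}" for i in range(len(labels)))
        region_ids = tuple(str(r) for r in region_ids)
        if len(labels) < 3:
            raise LabelingError("labeling needs at least 3 regions")
        if len(region_ids) != len(labels):
            raise LabelingError("region_ids and labels must have equal length")
        if len(set(region_ids)) != len(region_ids):
            raise LabelingError("region_ids must be unique")
        bad = sorted(set(labels) - set(REGION_CLASSES))
        if bad:
            raise LabelingError(f"unknown region labels {bad}; must be in {REGION_CLASSES}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "region_ids", region_ids)

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in REGION_CLASSES}

    def require_all_classes(self) -> None:
        """State-space analysis needs at least one region of each class."""
        missing = [c for c, k in self.class_counts().items() if k == 0]
        if missing:
            raise LabelingError(f"no regions labeled {missing}; all of P, N, O are required")

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype="U1")

    def pair_class_indices(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Vectorized class index (into COUPLING_CLASSES) for region-pair arrays."""
        return pair_class_indices(self.label_array(), rows, cols)


def pair_class_indices(labels: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Class index in COUPLING_CLASSES for each (rows[k], cols[k]) pair.

    Encodes P=0, N=1, O=2 and maps the symmetric code pair to the canonical
    six-class ordering; independent of pair orientation.
    """
    code = np.zeros(len(labels), dtype=np.int64)
    code[labels == "N"] = 1
    code[labels == "O"] = 2
    a = np.minimum(code[rows], code[cols])
    b = np.maximum(code[rows], code[cols])
    # (a,b) sorted codes: (0,0)->PP, (1,1)->NN, (0,1)->PN, (0,2)->PO, (1,2)->NO, (2,2)->OO
    lut = np.full((3, 3), -1, dtype=np.int64)
    lut[0, 0] = 0
    lut[1, 1] = 1
    lut[0, 1] = 2
    lut[0, 2] = 3
    lut[1, 2] = 4
    lut[2, 2] = 5
    return lut[a, b]


@dataclass
class SubjectConnectome:
    """One subject's SC matrix plus FC matrices for rest, attention, memory.

    ``fc_attention`` and ``fc_memory`` may hold either raw task FC or task
    deviations from rest (dFC); the pipeline thresholds deviations for task
    states and converts raw task FC via ``network.task_fc_deviation``.
    """

    subject_id: str
    sc: np.ndarray
    fc_rest: np.ndarray
    fc_attention: np.ndarray
    fc_memory: np.ndarray
    task_fc_is_deviation: bool = True

    def __post_init__(self):
        self.sc = np.asarray(self.sc, dtype=float)
        self.fc_rest = np.asarray(self.fc_rest, dtype=float)
        self.fc_attention = np.asarray(self.fc_attention, dtype=float)
        self.fc_memory = np.asarray(self.fc_memory, dtype=float)

    @property
    def n_regions(self) -> int:
        return self.sc.shape[0]

    def fc_for_state(self, state: str) -> np.ndarray:
        if state == "rest":
            return self.fc_rest
        if state == "attention":
            return self.fc_attention
        if state == "memory":
            return self.fc_memory
        raise ValueError(f"unknown state {state!r}; must be one of {STATES}")


@dataclass
class Cohort:
    """A set of subjects sharing one region labeling, with optional behavior."""

    subjects: list[SubjectConnectome]
    labeling: RegionLabeling
    behavior: Optional[pd.DataFrame] = None
    ground_truth: Optional[pd.DataFrame] = None

    def __post_init__(self):
        n = self.labeling.n_regions
        for s in self.subjects:
            if s.sc.shape != (n, n):
                raise ConnectomeError(
                    f"subject {s.subject_id}: SC shape {s.sc.shape} does not match "
                    f"labeling with {n} regions"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def sc_stack(self) -> np.ndarray:
        return np.stack([s.sc for s in self.subjects])


@dataclass
class ValidationReport:
    """Violations found in a subject's matrices; empty iff valid."""

    subject_id: str
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # truthy iff clean
        return not self.violations

    @property
    def ok(self) -> bool:
        return not self.violations


_MATRIX_NAMES = ("sc", "fc_rest", "fc_attention", "fc_memory")


def validate_connectome(subject: SubjectConnectome) -> ValidationReport:
    """Check symmetry, sign, range and diagonal constraints on one subject.

    SC must be square, symmetric (within 1e-9), nonnegative, zero diagonal.
    FC matrices must additionally lie in [-1, 1]. Shape mismatches between
    matrices raise ``ConnectomeError``; value violations are collected in
    the report.
    """
    report = ValidationReport(subject.subject_id)
    shape = subject.sc.shape
    if shape[0] != shape[1]:
        raise ConnectomeError(f"subject {subject.subject_id}: sc is not square: {shape}")
    for name in _MATRIX_NAMES:
        m = getattr(subject, name)
        if m.shape != shape:
            raise ConnectomeError(
                f"subject {subject.subject_id}: {name} shape {m.shape} != sc shape {shape}"
            )
        asym = np.abs(m - m.T).max() if m.size else 0.0
        if asym > SYMMETRY_TOL:
            report.violations.append(f"{name}: asymmetry {asym:.3g} exceeds {SYMMETRY_TOL}")
        diag = np.abs(np.diag(m)).max() if m.size else 0.0
        if diag > 0:
            idx = int(np.argmax(np.abs(np.diag(m))))
            report.violations.append(f"{name}: nonzero diagonal at region {idx}")
        if not np.isfinite(m).all():
            report.violations.append(f"{name}: non-finite entries")
    if (subject.sc < 0).any():
        i, j = np.unravel_index(int(np.argmin(subject.sc)), shape)
        report.violations.append(f"sc: negative SC at ({i}, {j})")
    for name in _MATRIX_NAMES[1:]:
        m = getattr(subject, name)
        if np.isfinite(m).all() and np.abs(m).max() > 1 + 1e-12:
            # task deviations are differences of correlations; bound is 2
            bound = 2.0 if (name != "fc_rest" and subject.task_fc_is_deviation) else 1.0
            if np.abs(m).max() > bound + 1e-12:
                report.violations.append(f"{name}: |FC| > {bound:g}")
    return report


def zero_diagonal(matrix: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Return a copy with the diagonal zeroed, warning if it was nonzero.

    Self-connections are meaningless for pair densities; loaders tolerate
    a nonzero diagonal (e.g. FC diagonals of 1) rather than erroring.
    """
    out = np.array(matrix, dtype=float, copy=True)
    if out.size and np.abs(np.diag(out)).max() > 0:
        warnings.warn(f"{name}: nonzero diagonal zeroed", stacklevel=2)
        np.fill_diagonal(out, 0.0)
    return out
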
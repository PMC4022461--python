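"""Analysis-ready network construction.

Because tractography-derived SC is sparse and variable across subjects, all
analyses are restricted to region pairs structurally connected (streamline
count >= 1) in at least a fixed fraction of subjects (default 80%). A
"representative" group network is the entrywise mean of the subject
matrices. Task FC enters the pipeline as deviations from rest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    Cohort,
    ConnectomeError,
    CouplingClass,
    COUPLING_CLASSES,
    RegionLabeling,
    STATES,
    SubjectConnectome,
)


class DegenerateMaskError(ValueError):
    """Raised when the consistency mask retains no PP, NN or PN edges."""


@dataclass
class EdgeMask:
    """Boolean symmetric matrix of region pairs retained for analysis."""

    mask: np.ndarray
    consistency_fraction: float

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.mask, k=1).sum())

    def edge_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle (row, col) indices of retained pairs."""
        iu, ju = np.triu_indices(self.mask.shape[0], k=1)
        keep = self.mask[iu, ju]
        return iu[keep], ju[keep]


def consistency_mask(
    sc_list: list[np.ndarray],
    fraction: float = 0.8,
    labeling: RegionLabeling | None = None,
) -> EdgeMask:
    """Region pairs with streamline count >= 1 in at least ``fraction`` of subjects.

    Ties at the boundary are retained (the rule is ">= fraction"). When a
    labeling is given, the mask is checked to retain at least one PP, NN
    and PN edge; an empty focus class makes the state-space undefined.
    """
    if not sc_list:
        raise ValueError("need at least one subject")
    stack = np.stack(sc_list)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ConnectomeError(f"SC matrices must be square; got stack shape {stack.shape}")
    presence = (stack >= 1).mean(axis=0)
    mask = presence >= fraction
    np.fill_diagonal(mask, False)
    mask &= mask.T
    em = EdgeMask(mask=mask, consistency_fraction=fraction)
    if labeling is not None:
        iu, ju = em.edge_indices()
        cls = labeling.pair_class_indices(iu, ju)
        for want, name in ((0, "PP"), (1, "NN"), (2, "PN")):
            if not (cls == want).any():
                raise DegenerateMaskError(
                    f"consistency mask at fraction {fraction} retains no {name} edges"
                )
    return em


@dataclass
class RepresentativeNetwork:
    """Group-mean SC and per-state FC matrices."""

    sc: np.ndarray
    fc: dict[str, np.ndarray]
    n_subjects: int

    def as_subject(self) -> SubjectConnectome:
        """View the representative network as a pseudo-subject for the pipeline."""
        return SubjectConnectome(
            subject_id="representative",
            sc=self.sc,
            fc_rest=self.fc["rest"],
            fc_attention=self.fc["attention"],
            fc_memory=self.fc["memory"],
        )


def representative_network(cohort: Cohort, fisher_z: bool = False) -> RepresentativeNetwork:
    """Entrywise mean of SC and of each state's FC across subjects.

    ``fisher_z=True`` averages FC through the arctanh transform instead of
    averaging correlations directly (off by default; direct averaging is
    what the construction describes).
    """
    if not cohort.subjects:
        raise ValueError("empty cohort")
    sc = np.mean([s.sc for s in cohort.subjects], axis=0)
    fc = {}
    for state in STATES:
        mats = np.stack([s.fc_for_state(state) for s in cohort.subjects])
        if fisher_z:
            fc[state] = np.tanh(np.arctanh(np.clip(mats, -0.999999, 0.999999)).mean(axis=0))
        else:
            fc[state] = mats.mean(axis=0)
    return RepresentativeNetwork(sc=sc, fc=fc, n_subjects=len(cohort.subjects))


def task_fc_deviation(fc_task: np.ndarray, fc_rest: np.ndarray) -> np.ndarray:
    """Task FC as entrywise deviation from rest: dFC = FC_task - FC_rest."""
    fc_task = np.asarray(fc_task, dtype=float)
    fc_rest = np.asarray(fc_rest, dtype=float)
    if fc_task.shape != fc_rest.shape:
        raise ConnectomeError(
            f"shape mismatch: task {fc_task.shape} vs rest {fc_rest.shape}"
        )
    return fc_task - fc_rest


def coupling_ccdf(
    fc_by_class: dict[CouplingClass | str, np.ndarray],
    thresholds: np.ndarray | None = None,
    n_grid: int = 101,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-class complementary CDF of FC values.

    Returns ``{class: (thresholds, survival)}`` with
    ``survival[k] = fraction of class values strictly greater than
    thresholds[k]``. Empty classes are omitted with a warning. A common
    threshold grid spanning the pooled value range is built when none is
    supplied.
    """
    cleaned: dict[str, np.ndarray] = {}
    for key, vals in fc_by_class.items():
        name = key.value if isinstance(key, CouplingClass) else str(key)
        vals = np.asarray(vals, dtype=float).ravel()
        if vals.size == 0:
            warnings.warn(f"coupling class {name} has no values; omitted", stacklevel=2)
            continue
        cleaned[name] = np.sort(vals)
    if not cleaned:
        raise ValueError("no nonempty coupling classes")
    if thresholds is None:
        pooled = np.concatenate(list(cleaned.values()))
        lo, hi = pooled.min(), pooled.max()
        pad = 1e-6 * max(1.0, abs(hi - lo))
        thresholds = np.linspace(lo - pad, hi + pad, n_grid)
    thresholds = np.asarray(thresholds, dtype=float)
    out = {}
    for name, vals in cleaned.items():
        # strictly-greater count via searchsorted on the sorted values
        survival = 1.0 - np.searchsorted(vals, thresholds, side="right") / vals.size
        out[name] = (thresholds, survival)
    return out


def fc_values_by_class(
    fc: np.ndarray, labeling: RegionLabeling, mask: EdgeMask | None = None
) -> dict[str, np.ndarray]:
    """Group FC entries over (masked) region pairs by coupling class."""
    n = labeling.n_regions
    if mask is not None:
        iu, ju = mask.edge_indices()
    else:
        iu, ju = np.triu_indices(n, k=1)
    cls = labeling.pair_class_indices(iu, ju)
    vals = fc[iu, ju]
    return {c.value: vals[cls == k] for k, c in enumerate(COUPLING_CLASSES)}
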
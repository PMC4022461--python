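"""Per-subject separation between cognitive states and the permutation null.

A subject's three state points (rest R, attention A, memory M) are compared
by the angular separation theta_ij between the origin-anchored vectors of
states i and j, in degrees. Subjects are grouped by the rank order of the
three separations: the smallest angle names the pair of states the subject's
structure-function relationships least distinguish.

The null model randomly reassigns the task-positive / task-negative / other
region labels (preserving class counts, one relabeling shared by the whole
cohort per permutation) and reruns the density -> state-point -> separation
pipeline, giving an empirical p-value for the observed separation structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .core import Cohort, RegionLabeling, STATES, pair_class_indices
from .density import (
    DEFAULT_MIN_EDGES,
    DEFAULT_QUANTILES,
    DegenerateGridError,
    EdgeTable,
    ThresholdGrid,
    build_threshold_grid,
    state_point,
    trajectory_from_table,
)
from .network import DegenerateMaskError, EdgeMask, consistency_mask, task_fc_deviation

logger = logging.getLogger("connstates")

GROUPS = ("primary", "secondary_RM", "secondary_RA")

PLANAR_TOL = 1e-9


class UndefinedAngleError(ValueError):
    """A state point sits at the origin; its direction is undefined."""


def angular_separation(p1, p2) -> float:
    """Angle in degrees, in [0, 180], between two origin-anchored state points.

    Accepts StatePoint objects or length-2 vectors. Computed with atan2 of
    the cross and dot products for accuracy near 0 and 180 degrees.
    """
    v1 = np.asarray(getattr(p1, "vector", p1), dtype=float)
    v2 = np.asarray(getattr(p2, "vector", p2), dtype=float)
    for v, p in ((v1, p1), (v2, p2)):
        if np.hypot(*v) <= 1e-12:
            name = getattr(p, "state", "point")
            raise UndefinedAngleError(f"{name}: state point at the origin, angle undefined")
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = v1 @ v2
    return float(np.degrees(np.arctan2(abs(cross), dot)))


@dataclass(frozen=True)
class SeparationTriple:
    """The three pairwise angular separations for one subject, in degrees."""

    theta_RA: float
    theta_AM: float
    theta_MR: float
    subject_id: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.theta_RA, self.theta_AM, self.theta_MR])

    @property
    def mean_theta(self) -> float:
        return float(self.as_array().mean())

    @property
    def min_theta(self) -> float:
        return float(self.as_array().min())


def separation_triple(rest, attention, memory, subject_id: str = "") -> SeparationTriple:
    """Pairwise angular separations between the three state points."""
    return SeparationTriple(
        theta_RA=angular_separation(rest, attention),
        theta_AM=angular_separation(attention, memory),
        theta_MR=angular_separation(memory, rest),
        subject_id=subject_id,
    )


@dataclass(frozen=True)
class GroupAssignment:
    """Rank-order group of one subject, from the argmin separation."""

    subject_id: str
    group: str
    argmin_pair: str  # "AM", "MR" or "RA"
    margin: float     # second-smallest minus smallest theta, degrees


# smallest theta_AM -> attention and memory least separated -> primary;
# smallest theta_MR -> rest/memory least separated -> secondary_RM;
# smallest theta_RA -> rest/attention least separated -> secondary_RA.
_GROUP_OF_PAIR = {"AM": "primary", "MR": "secondary_RM", "RA": "secondary_RA"}


def assign_group(triple: SeparationTriple) -> GroupAssignment:
    """Group by rank order of separations; ties favor primary, then RM."""
    candidates = [
        (triple.theta_AM, 0, "AM"),
        (triple.theta_MR, 1, "MR"),
        (triple.theta_RA, 2, "RA"),
    ]
    ordered = sorted(candidates)  # theta, then priority order on exact ties
    theta_min, _, pair = ordered[0]
    if ordered[0][0] == ordered[1][0]:
        logger.warning(
            "subject %s: tied angular separations %s; tie broken by priority",
            triple.subject_id, ordered[0][0],
        )
    return GroupAssignment(
        subject_id=triple.subject_id,
        group=_GROUP_OF_PAIR[pair],
        argmin_pair=pair,
        margin=float(ordered[1][0] - ordered[0][0]),
    )


# Equilateral reference triangle for the barycentric remapping.
_REF_VERTICES = np.array(
    [[0.0, 1.0],
     [-np.sqrt(3.0) / 2.0, -0.5],
     [np.sqrt(3.0) / 2.0, -0.5]]
)


@dataclass(frozen=True)
class TriangleEmbedding:
    """Planar triangle representing one subject's normalized separations.

    Each vertex is the barycentric image of one cyclic permutation of the
    normalized triple (theta_RA, theta_AM, theta_MR). Triangle size encodes
    asymmetry between the three separations (equal angles collapse to the
    centroid); rotation encodes their rank order.
    """

    vertices: np.ndarray  # (3, 2)
    area: float
    subject_id: str = ""


def triangle_embedding(triple: SeparationTriple) -> TriangleEmbedding:
    t = triple.as_array()
    total = t.sum()
    if total <= 0:
        return TriangleEmbedding(
            vertices=np.zeros((3, 2)), area=0.0, subject_id=triple.subject_id
        )
    bary = t / total
    verts = np.stack([np.roll(bary, -k) @ _REF_VERTICES for k in range(3)])
    a, b, c = verts
    area = 0.5 * abs(
        (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
    )
    return TriangleEmbedding(vertices=verts, area=float(area), subject_id=triple.subject_id)


# ---------------------------------------------------------------------------
# Cohort pipeline: cached per-subject edge data, rerun under any labeling.
# ---------------------------------------------------------------------------


class CohortPipeline:
    """Mask-respecting density->state-point->separation pipeline for a cohort.

    The consistency mask, per-subject edge weights, FC values and threshold
    grids are label-independent, so they are computed once; running the
    pipeline under a (possibly permuted) labeling only recomputes per-edge
    coupling classes. This is what makes the label-permutation null cheap.
    """

    def __init__(
        self,
        cohort: Cohort,
        consistency_fraction: float = 0.8,
        weighted: bool = True,
        quantiles: np.ndarray = DEFAULT_QUANTILES,
        min_edges: int = DEFAULT_MIN_EDGES,
    ):
        self.cohort = cohort
        self.weighted = weighted
        self.min_edges = min_edges
        self.mask: EdgeMask = consistency_mask(
            [s.sc for s in cohort.subjects], consistency_fraction, labeling=cohort.labeling
        )
        self._iu, self._ju = self.mask.edge_indices()
        self._subject_data: list[tuple[str, np.ndarray, dict[str, tuple[np.ndarray, ThresholdGrid]]]] = []
        for s in cohort.subjects:
            w = s.sc[self._iu, self._ju].astype(float)
            if not weighted:
                w = (w > 0).astype(float)
            per_state = {}
            for state in STATES:
                fc = s.fc_for_state(state)
                if state != "rest" and not s.task_fc_is_deviation:
                    fc = task_fc_deviation(fc, s.fc_rest)
                vals = fc[self._iu, self._ju]
                per_state[state] = (vals, build_threshold_grid(vals, quantiles, min_edges))
            self._subject_data.append((s.subject_id, w, per_state))

    def _class_indices(self, labels: np.ndarray) -> np.ndarray:
        cls = pair_class_indices(labels, self._iu, self._ju)
        for want, name in ((0, "PP"), (1, "NN"), (2, "PN")):
            if not (cls == want).any():
                raise DegenerateMaskError(f"labeling leaves no {name} edges in the mask")
        return cls

    def separations(self, labels: Optional[np.ndarray] = None) -> list[SeparationTriple]:
        """Separation triples for every subject under the given labeling."""
        if labels is None:
            labels = self.cohort.labeling.label_array()
        cls = self._class_indices(np.asarray(labels, dtype="U1"))
        triples = []
        for sid, w, per_state in self._subject_data:
            points = {}
            for state, (vals, grid) in per_state.items():
                table = EdgeTable(class_idx=cls, weights=w, fc=vals, weighted=self.weighted)
                points[state] = state_point(trajectory_from_table(table, grid, state))
            triples.append(
                separation_triple(points["rest"], points["attention"], points["memory"], sid)
            )
        return triples

    def separation_table(self, labels: Optional[np.ndarray] = None) -> pd.DataFrame:
        """Per-subject separations, group and margin as a tidy table."""
        rows = []
        for t in self.separations(labels):
            g = assign_group(t)
            rows.append(
                {
                    "subject_id": t.subject_id,
                    "theta_RA": t.theta_RA,
                    "theta_AM": t.theta_AM,
                    "theta_MR": t.theta_MR,
                    "group": g.group,
                    "argmin_pair": g.argmin_pair,
                    "margin": g.margin,
                }
            )
        return pd.DataFrame(rows)


_STATISTICS: dict[str, Callable[[list[SeparationTriple]], float]] = {
    "mean-theta": lambda ts: float(np.mean([t.mean_theta for t in ts])),
    "min-theta": lambda ts: float(np.mean([t.min_theta for t in ts])),
}


@dataclass
class NullResult:
    """Observed statistic versus its label-permutation null distribution."""

    observed: float
    null_samples: list[float]
    n_permutations: int
    seed: int
    statistic: str = "mean-theta"
    p_value: float = field(init=False)

    def __post_init__(self):
        ge = sum(1 for s in self.null_samples if s >= self.observed)
        # add-one estimator: the observed relabeling counts as one permutation
        self.p_value = (1 + ge) / (1 + self.n_permutations)


def permutation_null(
    cohort: Cohort,
    n_permutations: int = 99,
    seed: int = 0,
    statistic: str = "mean-theta",
    pipeline: Optional[CohortPipeline] = None,
    **pipeline_kwargs,
) -> NullResult:
    """Empirical p-value for the observed separation structure.

    Each permutation reshuffles the region-label vector uniformly (class
    counts preserved; one shared relabeling per permutation, as all subjects
    share the atlas) and recomputes the cohort statistic. Permutations that
    leave a focus class without masked edges are resampled, at most 10 times
    each.
    """
    if n_permutations < 19:
        raise ValueError("need at least 19 permutations for a p <= 0.05 resolution")
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}")
    stat_fn = _STATISTICS[statistic]
    if pipeline is None:
        pipeline = CohortPipeline(cohort, **pipeline_kwargs)
    observed = stat_fn(pipeline.separations())
    rng = np.random.default_rng(seed)
    labels = cohort.labeling.label_array()
    samples = []
    for _ in range(n_permutations):
        for attempt in range(10):
            perm = rng.permutation(labels)
            try:
                samples.append(stat_fn(pipeline.separations(perm)))
                break
            except (DegenerateMaskError, DegenerateGridError, UndefinedAngleError) as e:
                logger.info("degenerate permutation resampled (%s)", e)
        else:
            raise RuntimeError("10 consecutive degenerate permutations; cohort too sparse")
    return NullResult(
        observed=observed,
        null_samples=samples,
        n_permutations=n_permutations,
        seed=seed,
        statistic=statistic,
    )
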
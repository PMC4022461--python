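"""Fractional connection-number densities and the state-space mapping.

For each cognitive state, a variable threshold phi sweeps the distribution
of FC (rest) or dFC (tasks) over the masked region pairs. At each phi the
fractional number density n_c is the share of structural connection weight
(streamline counts; or edge counts in the unweighted variant) carried by
coupling class c among pairs whose FC exceeds phi:

    n_c(phi) = sum_{(i,j): FC_ij > phi, class=c} w_ij / sum_{FC_ij > phi} w_ij

Changes delta_n_c are taken relative to the no-threshold baseline. The 2-D
state-space coordinate of a state at threshold phi is

    x = delta_n_PN              (between-network coupling)
    y = delta_n_PP - delta_n_NN (within-network coupling: task-positive
                                 localization positive, task-negative negative)

and a state's summary point is the unweighted mean of (x, y) over the
admissible grid thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import COUPLING_CLASSES, RegionLabeling, STATES, SubjectConnectome
from .network import EdgeMask, task_fc_deviation

N_CLASSES = len(COUPLING_CLASSES)
_CLASS_NAMES = [c.value for c in COUPLING_CLASSES]

DEFAULT_QUANTILES = np.round(np.arange(0.0, 0.9001, 0.05), 10)
DEFAULT_MIN_EDGES = 10


class DegenerateGridError(ValueError):
    """No admissible threshold grid point."""


class EmptySelectionError(ValueError):
    """No edge survives the requested threshold."""


@dataclass
class ThresholdGrid:
    """Ordered FC thresholds derived from empirical quantiles."""

    phi_values: np.ndarray
    quantiles: np.ndarray
    min_edges: int

    def __post_init__(self):
        self.phi_values = np.asarray(self.phi_values, dtype=float)
        if np.any(np.diff(self.phi_values) <= 0):
            raise DegenerateGridError("thresholds must be strictly increasing")


def build_threshold_grid(
    fc_values: np.ndarray,
    quantiles: np.ndarray = DEFAULT_QUANTILES,
    min_edges: int = DEFAULT_MIN_EDGES,
) -> ThresholdGrid:
    """Quantile-based threshold grid over the masked FC values.

    Survival is strict (FC > phi), so the 0-quantile grid point is nudged
    just below the minimum value: there the full edge set survives and the
    grid's first point reproduces the baseline (all deltas zero). Grid
    points leaving fewer than ``min_edges`` surviving edges, and duplicate
    thresholds from tied quantiles, are dropped.
    """
    vals = np.sort(np.asarray(fc_values, dtype=float).ravel())
    if vals.size < min_edges:
        raise DegenerateGridError(
            f"only {vals.size} masked edges; min_edges={min_edges}"
        )
    quantiles = np.asarray(quantiles, dtype=float)
    phis = np.quantile(vals, quantiles)
    if quantiles[0] == 0.0:
        phis[0] = np.nextafter(vals[0], -np.inf)
    # surviving count under strict >
    surviving = vals.size - np.searchsorted(vals, phis, side="right")
    keep = surviving >= min_edges
    phis = phis[keep]
    kept_q = quantiles[keep]
    uniq = np.concatenate(([True], np.diff(phis) > 0))
    phis, kept_q = phis[uniq], kept_q[uniq]
    if phis.size == 0:
        raise DegenerateGridError(
            f"no grid point leaves >= {min_edges} edges surviving"
        )
    return ThresholdGrid(phi_values=phis, quantiles=kept_q, min_edges=min_edges)


@dataclass
class DensityProfile:
    """Per-class fractional densities at one threshold."""

    phi: float
    n_c: dict[str, float]
    weighted: bool
    n_edges_surviving: int
    delta_n_c: dict[str, float] = field(default_factory=dict)

    @property
    def n_other(self) -> float:
        """PO + NO + OO lumped, as in the pie-chart decomposition."""
        return self.n_c["PO"] + self.n_c["NO"] + self.n_c["OO"]

    @property
    def delta_n_other(self) -> float:
        return self.delta_n_c["PO"] + self.delta_n_c["NO"] + self.delta_n_c["OO"]


@dataclass
class EdgeTable:
    """Flat view of the masked edges: weights, classes, per-state FC values.

    The heavy lifting of the threshold sweep happens here: FC values are
    sorted once, class-weight cumulative sums over the descending order give
    every threshold's densities in O(E) total.
    """

    class_idx: np.ndarray
    weights: np.ndarray  # effective: streamline counts, or 1 (unweighted), 0 if absent
    fc: np.ndarray
    weighted: bool

    def __post_init__(self):
        order = np.argsort(self.fc, kind="stable")[::-1]  # descending FC
        self._fc_sorted_asc = self.fc[order[::-1]]
        w = self.weights[order]
        onehot = np.zeros((N_CLASSES, len(order)))
        onehot[self.class_idx[order], np.arange(len(order))] = w
        self._cum_class = np.cumsum(onehot, axis=1)  # class mass among top-k edges
        self._cum_total = np.cumsum(w)
        self._cum_count = np.cumsum(w > 0)

    @property
    def n_edges(self) -> int:
        return int((self.weights > 0).sum())

    def densities_at(self, phis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(n_c matrix [n_phi, 6], surviving positive-weight edge counts)."""
        phis = np.atleast_1d(np.asarray(phis, dtype=float))
        k = len(self.fc) - np.searchsorted(self._fc_sorted_asc, phis, side="right")
        out = np.zeros((len(phis), N_CLASSES))
        counts = np.zeros(len(phis), dtype=int)
        nz = k > 0
        idx = k[nz] - 1
        tot = self._cum_total[idx]
        counts[nz] = self._cum_count[idx]
        ok = tot > 0
        rows = np.nonzero(nz)[0][ok]
        out[rows] = (self._cum_class[:, idx[ok]] / tot[ok]).T
        return out, counts


def make_edge_table(
    sc: np.ndarray,
    fc: np.ndarray,
    labeling: RegionLabeling,
    mask: EdgeMask,
    weighted: bool = True,
) -> EdgeTable:
    """Edge table over masked pairs; absent structural connections get weight 0."""
    iu, ju = mask.edge_indices()
    cls = labeling.pair_class_indices(iu, ju)
    w = sc[iu, ju].astype(float)
    if not weighted:
        w = (w > 0).astype(float)
    return EdgeTable(class_idx=cls, weights=w, fc=fc[iu, ju], weighted=weighted)


def number_densities(table: EdgeTable, phi: float) -> DensityProfile:
    """Fractional number densities among edges with FC strictly above phi."""
    if len(table.fc) == 0:
        raise EmptySelectionError("edge table is empty")
    dens, counts = table.densities_at(np.array([phi]))
    if counts[0] == 0:
        raise EmptySelectionError(f"no edge survives phi={phi}")
    return DensityProfile(
        phi=float(phi),
        n_c=dict(zip(_CLASS_NAMES, dens[0])),
        weighted=table.weighted,
        n_edges_surviving=int(counts[0]),
    )


def baseline_densities(table: EdgeTable) -> DensityProfile:
    """Densities over all masked edges — the no-threshold baseline."""
    return number_densities(table, -np.inf)


def delta_densities(profile: DensityProfile, baseline: DensityProfile) -> DensityProfile:
    """Fill delta_n_c = n_c(phi) - n_c(baseline); the deltas sum to zero."""
    if set(profile.n_c) != set(baseline.n_c):
        raise ValueError("profiles cover different class sets")
    delta = {c: profile.n_c[c] - baseline.n_c[c] for c in profile.n_c}
    return DensityProfile(
        phi=profile.phi,
        n_c=dict(profile.n_c),
        weighted=profile.weighted,
        n_edges_surviving=profile.n_edges_surviving,
        delta_n_c=delta,
    )


@dataclass
class StateTrajectory:
    """Per-threshold state-space coordinates for one cognitive state."""

    state: str
    phis: np.ndarray
    x: np.ndarray  # delta_n_PN
    y: np.ndarray  # delta_n_PP - delta_n_NN
    profiles: list[DensityProfile] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.phis)


@dataclass(frozen=True)
class StatePoint:
    """Mean state-space coordinate of one cognitive state."""

    state: str
    x_bar: float
    y_bar: float

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.x_bar, self.y_bar])


def trajectory_from_table(
    table: EdgeTable, grid: ThresholdGrid, state: str, keep_profiles: bool = False
) -> StateTrajectory:
    """Sweep the grid and record (x, y) at each admissible threshold."""
    base_dens, _ = table.densities_at(np.array([-np.inf]))
    dens, counts = table.densities_at(grid.phi_values)
    admissible = counts >= grid.min_edges
    if not admissible.any():
        raise DegenerateGridError(
            f"state {state}: no grid point leaves >= {grid.min_edges} edges"
        )
    dens = dens[admissible]
    phis = grid.phi_values[admissible]
    counts = counts[admissible]
    delta = dens - base_dens[0]
    i_pp, i_nn, i_pn = 0, 1, 2  # canonical COUPLING_CLASSES order
    x = delta[:, i_pn]
    y = delta[:, i_pp] - delta[:, i_nn]
    profiles = []
    if keep_profiles:
        base_profile = DensityProfile(
            phi=-np.inf,
            n_c=dict(zip(_CLASS_NAMES, base_dens[0])),
            weighted=table.weighted,
            n_edges_surviving=table.n_edges,
        )
        for k, phi in enumerate(phis):
            p = DensityProfile(
                phi=float(phi),
                n_c=dict(zip(_CLASS_NAMES, dens[k])),
                weighted=table.weighted,
                n_edges_surviving=int(counts[k]),
            )
            profiles.append(delta_densities(p, base_profile))
    return StateTrajectory(state=state, phis=phis, x=x, y=y, profiles=profiles)


def statespace_trajectory(
    mask: EdgeMask,
    sc: np.ndarray,
    fc_state: np.ndarray,
    labeling: RegionLabeling,
    grid: Optional[ThresholdGrid] = None,
    weighted: bool = True,
    state: str = "rest",
    quantiles: np.ndarray = DEFAULT_QUANTILES,
    min_edges: int = DEFAULT_MIN_EDGES,
    keep_profiles: bool = False,
) -> StateTrajectory:
    """Full sweep for one state: mask -> edge table -> grid -> trajectory.

    ``fc_state`` is the matrix the state thresholds: resting FC for rest,
    deviation-from-rest matrices for the task states. The grid defaults to
    empirical quantiles of that matrix over the masked edges.
    """
    table = make_edge_table(sc, fc_state, labeling, mask, weighted=weighted)
    if grid is None:
        iu, ju = mask.edge_indices()
        grid = build_threshold_grid(fc_state[iu, ju], quantiles, min_edges)
    return trajectory_from_table(table, grid, state, keep_profiles=keep_profiles)


def state_point(trajectory: StateTrajectory) -> StatePoint:
    """Unweighted mean of (x, y) over the trajectory's admissible thresholds."""
    if len(trajectory) == 0:
        raise ValueError(f"state {trajectory.state}: empty trajectory")
    return StatePoint(
        state=trajectory.state,
        x_bar=float(trajectory.x.mean()),
        y_bar=float(trajectory.y.mean()),
    )


def subject_state_points(
    subject: SubjectConnectome,
    labeling: RegionLabeling,
    mask: EdgeMask,
    weighted: bool = True,
    quantiles: np.ndarray = DEFAULT_QUANTILES,
    min_edges: int = DEFAULT_MIN_EDGES,
) -> dict[str, StatePoint]:
    """State points for all three cognitive states of one subject.

    Task matrices are used as deviations from rest; raw task FC (flagged on
    the subject) is converted first.
    """
    points = {}
    for state in STATES:
        fc = subject.fc_for_state(state)
        if state != "rest" and not subject.task_fc_is_deviation:
            fc = task_fc_deviation(fc, subject.fc_rest)
        traj = statespace_trajectory(
            mask, subject.sc, fc, labeling,
            weighted=weighted, state=state,
            quantiles=quantiles, min_edges=min_edges,
        )
        points[state] = state_point(traj)
    return points
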
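"""Model/Results interface tying the pipeline stages together.

``StateSpaceModel`` is built from a :class:`~connstates.core.Cohort` (or a
cohort directory) and holds the analysis configuration; ``fit()`` runs the
consistency mask, threshold sweeps, state points, angular separations and
rank-order grouping, returning a ``StateSpaceResults`` carrying the
estimates. Uncertainty quantification (the label-permutation null) and the
behavioral group comparisons hang off the results object, as do basic
diagnostic plots and writers.

Example
-------
>>> from connstates import CohortSpec, generate_cohort, StateSpaceModel
>>> cohort = generate_cohort(CohortSpec(n_subjects=12, n_regions=60, seed=7))
>>> res = StateSpaceModel(cohort).fit()
>>> print(res.summary())                       # doctest: +SKIP
>>> null = res.permutation_null(n_permutations=99, seed=1)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io
from .behavior import (
    GroupTestResult,
    behavioral_deviations,
    group_behavior_report,
    group_behavior_tests,
)
from .core import Cohort, STATES
from .density import (
    DEFAULT_MIN_EDGES,
    DEFAULT_QUANTILES,
    StatePoint,
    StateTrajectory,
    state_point,
    statespace_trajectory,
)
from .network import RepresentativeNetwork, representative_network, task_fc_deviation
from .separation import (
    CohortPipeline,
    NullResult,
    SeparationTriple,
    TriangleEmbedding,
    permutation_null,
    triangle_embedding,
)


class StateSpaceModel:
    """State-space analysis of structure-function coupling for one cohort.

    Parameters
    ----------
    cohort : Cohort
        Subjects, region labeling and optional behavioral table.
    consistency_fraction : float
        Fraction of subjects in which a structural connection must be
        present (count >= 1) to enter the analysis mask. Default 0.8.
    weighted : bool
        Weight density fractions by streamline counts (default) or by edge
        presence only.
    quantiles, min_edges
        Threshold-grid construction: empirical FC quantiles swept, and the
        minimum surviving-edge count for a grid point to be admissible.
    fisher_z : bool
        Average FC through the Fisher z-transform when building the
        representative network (off by default: plain averaging).
    """

    def __init__(
        self,
        cohort: Cohort,
        consistency_fraction: float = 0.8,
        weighted: bool = True,
        quantiles: np.ndarray = DEFAULT_QUANTILES,
        min_edges: int = DEFAULT_MIN_EDGES,
        fisher_z: bool = False,
    ):
        self.cohort = cohort
        self.consistency_fraction = consistency_fraction
        self.weighted = weighted
        self.quantiles = np.asarray(quantiles, dtype=float)
        self.min_edges = min_edges
        self.fisher_z = fisher_z

    @classmethod
    def from_directory(cls, path: Path | str, **kwargs) -> "StateSpaceModel":
        """Build the model from an on-disk cohort directory."""
        return cls(io.read_cohort(path), **kwargs)

    def fit(self, representative: bool = True) -> "StateSpaceResults":
        """Run the full pipeline and return the results object."""
        pipeline = CohortPipeline(
            self.cohort,
            consistency_fraction=self.consistency_fraction,
            weighted=self.weighted,
            quantiles=self.quantiles,
            min_edges=self.min_edges,
        )
        triples = pipeline.separations()
        table = pipeline.separation_table()
        rep = rep_traj = rep_points = None
        if representative:
            rep = representative_network(self.cohort, fisher_z=self.fisher_z)
            rep_traj, rep_points = self._representative_statespace(rep, pipeline)
        subject_points = self._subject_points(pipeline)
        return StateSpaceResults(
            model=self,
            pipeline=pipeline,
            separations=table,
            triples=triples,
            subject_points=subject_points,
            representative=rep,
            representative_trajectories=rep_traj,
            representative_points=rep_points,
        )

    def _representative_statespace(self, rep: RepresentativeNetwork, pipeline: CohortPipeline):
        trajectories, points = {}, {}
        for state in STATES:
            fc = rep.fc[state]
            # per-subject task matrices are deviations already; their mean is too
            traj = statespace_trajectory(
                pipeline.mask, rep.sc, fc, self.cohort.labeling,
                weighted=self.weighted, state=state,
                quantiles=self.quantiles, min_edges=self.min_edges,
                keep_profiles=True,
            )
            trajectories[state] = traj
            points[state] = state_point(traj)
        return trajectories, points

    def _subject_points(self, pipeline: CohortPipeline) -> pd.DataFrame:
        rows = []
        labels = self.cohort.labeling.label_array()
        cls = pipeline._class_indices(labels)
        from .density import EdgeTable, trajectory_from_table  # local to avoid cycle noise

        for sid, w, per_state in pipeline._subject_data:
            for state, (vals, grid) in per_state.items():
                table = EdgeTable(class_idx=cls, weights=w, fc=vals, weighted=self.weighted)
                pt = state_point(trajectory_from_table(table, grid, state))
                rows.append(
                    {"subject_id": sid, "state": state, "x_bar": pt.x_bar, "y_bar": pt.y_bar}
                )
        return pd.DataFrame(rows)


@dataclass
class StateSpaceResults:
    """Estimates from a fitted :class:`StateSpaceModel`.

    Attributes
    ----------
    separations : DataFrame
        Per subject: theta_RA, theta_AM, theta_MR (degrees), rank-order
        group and decision margin.
    subject_points : DataFrame
        Per subject and state: mean state-space coordinates (x_bar, y_bar).
    representative_points : dict[str, StatePoint] or None
        State points of the group-mean (representative) network.
    """

    model: StateSpaceModel
    pipeline: CohortPipeline
    separations: pd.DataFrame
    triples: list[SeparationTriple]
    subject_points: pd.DataFrame
    representative: Optional[RepresentativeNetwork] = None
    representative_trajectories: Optional[dict[str, StateTrajectory]] = None
    representative_points: Optional[dict[str, StatePoint]] = None

    # -- derived ------------------------------------------------------------

    def group_census(self) -> pd.DataFrame:
        """Subject counts and fractions per rank-order group."""
        counts = self.separations["group"].value_counts()
        rows = []
        for g in ("primary", "secondary_RM", "secondary_RA"):
            n = int(counts.get(g, 0))
            rows.append({"group": g, "n": n, "fraction": n / len(self.separations)})
        return pd.DataFrame(rows)

    def triangles(self) -> list[TriangleEmbedding]:
        """Barycentric triangle remapping of every subject's separations."""
        return [triangle_embedding(t) for t in self.triples]

    # -- inference ----------------------------------------------------------

    def permutation_null(
        self, n_permutations: int = 99, seed: int = 0, statistic: str = "mean-theta"
    ) -> NullResult:
        """Label-permutation null for the cohort separation statistic."""
        return permutation_null(
            self.model.cohort,
            n_permutations=n_permutations,
            seed=seed,
            statistic=statistic,
            pipeline=self.pipeline,
        )

    def behavioral_deviations(self, normalize_rel: bool = False) -> pd.DataFrame:
        if self.model.cohort.behavior is None:
            raise ValueError("cohort has no behavioral table")
        return behavioral_deviations(self.model.cohort.behavior, normalize_rel=normalize_rel)

    def behavior_report(self, normalize_rel: bool = False) -> pd.DataFrame:
        return group_behavior_report(
            self.behavioral_deviations(normalize_rel), self.separations
        )

    def behavior_tests(
        self,
        columns: tuple[str, ...] = ("delta_RT_A", "delta_RT_M", "rel_DP", "rel_CS"),
        normalize_rel: bool = False,
    ) -> list[GroupTestResult]:
        """One-tailed secondary > primary Welch tests on deviation magnitudes."""
        return group_behavior_tests(
            self.behavioral_deviations(normalize_rel), self.separations, columns=columns
        )

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        cohort = self.model.cohort
        lines = [
            "State-space separation of cognitive states",
            "=" * 58,
            f"subjects: {cohort.n_subjects:>4d}    regions: {cohort.labeling.n_regions}"
            f"    masked edges: {self.pipeline.mask.n_edges}",
            f"consistency fraction: {self.model.consistency_fraction:.2f}"
            f"    weighted: {self.model.weighted}",
            "-" * 58,
            "group           n   fraction   mean theta_min (deg)",
        ]
        for _, row in self.group_census().iterrows():
            sub = self.separations[self.separations["group"] == row["group"]]
            tmin = (
                sub[["theta_RA", "theta_AM", "theta_MR"]].min(axis=1).mean()
                if len(sub)
                else float("nan")
            )
            lines.append(
                f"{row['group']:<14s}{row['n']:>4d}   {row['fraction']:>7.1%}   {tmin:>10.1f}"
            )
        lines.append("-" * 58)
        means = self.separations[["theta_RA", "theta_AM", "theta_MR"]].mean()
        lines.append(
            "cohort mean separations (deg): "
            f"RA {means['theta_RA']:.1f}  AM {means['theta_AM']:.1f}  MR {means['theta_MR']:.1f}"
        )
        if self.representative_points is not None:
            lines.append("representative-network state points (x, y):")
            for state, pt in self.representative_points.items():
                lines.append(f"  {state:<10s} ({pt.x_bar:+.4f}, {pt.y_bar:+.4f})")
        return "\n".join(lines)

    def save(self, outdir: Path | str) -> Path:
        """Write statepoints.csv, separations.csv and triangles.json."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.subject_points.to_csv(out / "statepoints.csv", index=False)
        self.separations.to_csv(out / "separations.csv", index=False)
        tris = {
            t.subject_id: {"vertices": t.vertices.tolist(), "area": t.area}
            for t in self.triangles()
        }
        (out / "triangles.json").write_text(json.dumps(tris, indent=2) + "\n")
        if self.representative_points is not None:
            pd.DataFrame(
                [
                    {"state": s, "x_bar": p.x_bar, "y_bar": p.y_bar}
                    for s, p in self.representative_points.items()
                ]
            ).to_csv(out / "representative_statepoints.csv", index=False)
        return out

    def plot_statespace(self, ax=None):
        """Representative-network trajectories in the (x, y) state space."""
        import matplotlib.pyplot as plt

        if self.representative_trajectories is None:
            raise ValueError("fit with representative=True to plot trajectories")
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        markers = {"rest": "o", "attention": "s", "memory": "^"}
        for state, traj in self.representative_trajectories.items():
            ax.plot(traj.x, traj.y, marker=markers[state], label=state, alpha=0.7)
        ax.axhline(0, color="grey", lw=0.5)
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_xlabel(r"between-network coupling  $\Delta n_{PN}$")
        ax.set_ylabel(r"within-network coupling  $\Delta n_{PP} - \Delta n_{NN}$")
        ax.legend()
        return ax

    def plot_triangles(self, ax=None):
        """All subjects' separation triangles in the barycentric remapping."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for tri in self.triangles():
            v = np.vstack([tri.vertices, tri.vertices[:1]])
            ax.plot(v[:, 0], v[:, 1], alpha=0.25, color="tab:blue")
        ax.set_aspect("equal")
        ax.set_title("separation triangles (cyclic permutations)")
        return ax
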
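"""Threshold grids, number densities (vs brute-force oracle), state space."""

import numpy as np
import pytest

from connstates import (
    COUPLING_CLASSES,
    RegionLabeling,
    build_threshold_grid,
    classify_pair,
    delta_densities,
    number_densities,
    state_point,
    statespace_trajectory,
)
from connstates.density import (
    DegenerateGridError,
    EdgeTable,
    EmptySelectionError,
    StateTrajectory,
    baseline_densities,
    make_edge_table,
)
from connstates.network import EdgeMask


def brute_force_densities(sc, fc, labels, mask, phi, weighted):
    """Independent oracle: nested loop over every region pair."""
    totals = {c.value: 0.0 for c in COUPLING_CLASSES}
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if not mask[i, j]:
                continue
            if fc[i, j] > phi:
                w = sc[i, j] if weighted else (1.0 if sc[i, j] > 0 else 0.0)
                totals[classify_pair(labels[i], labels[j]).value] += w
    grand = sum(totals.values())
    if grand == 0:
        return None
    return {c: v / grand for c, v in totals.items()}


def _random_problem(rng, n_max=12):
    n = int(rng.integers(4, n_max + 1))
    labels = rng.choice(list("PNO"), size=n)
    sc = np.triu(rng.integers(0, 6, (n, n)).astype(float), k=1)
    sc = sc + sc.T
    fc = np.triu(rng.uniform(-1, 1, (n, n)), k=1)
    fc = fc + fc.T
    mask = np.triu(rng.random((n, n)) < 0.8, k=1)
    mask = mask | mask.T
    return n, labels, sc, fc, mask


class TestDensityOracle:
    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_on_1000_random_networks(self, weighted):
        rng = np.random.default_rng(20240501)
        checked = 0
        for _ in range(1000):
            n, labels, sc, fc, mask = _random_problem(rng)
            phi = float(rng.uniform(-1, 1))
            expected = brute_force_densities(sc, fc, labels, mask, phi, weighted)
            table = make_edge_table(
                sc, fc, RegionLabeling(labels.tolist()),
                EdgeMask(mask, 0.8), weighted=weighted,
            )
            if expected is None:
                with pytest.raises(EmptySelectionError):
                    number_densities(table, phi)
                continue
            profile = number_densities(table, phi)
            for c, v in expected.items():
                assert profile.n_c[c] == pytest.approx(v, abs=1e-12)
            checked += 1
        assert checked > 500  # most random problems are non-degenerate


class TestNumberDensities:
    def _table(self, weights, fc_vals, classes=("PP", "NN", "PN", "OO")):
        cls_idx = np.array([[c.value for c in COUPLING_CLASSES].index(c) for c in classes])
        return EdgeTable(
            class_idx=cls_idx,
            weights=np.asarray(weights, dtype=float),
            fc=np.asarray(fc_vals, dtype=float),
            weighted=True,
        )

    def test_stated_weight_ratios_no_threshold(self):
        t = self._table([2, 3, 1, 4], [0.5, 0.6, 0.7, 0.8])
        p = number_densities(t, -10.0)
        assert (p.n_c["PP"], p.n_c["NN"], p.n_c["PN"], p.n_c["OO"]) == (0.2, 0.3, 0.1, 0.4)

    def test_excluding_one_edge_renormalizes(self):
        # phi excludes only the PN edge (lowest FC)
        t = self._table([2, 3, 1, 4], [0.5, 0.6, 0.1, 0.8])
        p = number_densities(t, 0.2)
        assert p.n_c["PP"] == pytest.approx(2 / 9)
        assert p.n_c["NN"] == pytest.approx(3 / 9)
        assert p.n_c["PN"] == 0.0
        assert p.n_c["OO"] == pytest.approx(4 / 9)

    def test_conservation_sums_to_one(self, rng):
        for _ in range(50):
            fc = rng.uniform(-1, 1, 4)
            t = self._table(rng.integers(1, 9, 4), fc)
            phi = float(rng.uniform(-1, fc.max()))  # keep at least one survivor
            p = number_densities(t, phi)
            assert sum(p.n_c.values()) == pytest.approx(1.0, abs=1e-12)

    def test_lumped_other(self):
        t = self._table([1, 1, 1, 1], [0.5] * 4, classes=("PP", "PO", "NO", "OO"))
        p = number_densities(t, 0.0)
        assert p.n_other == pytest.approx(0.75)


class TestDeltaDensities:
    def test_phi_at_baseline_gives_zero_deltas(self):
        t = EdgeTable(np.array([0, 1, 2]), np.ones(3), np.array([0.1, 0.2, 0.3]), True)
        base = baseline_densities(t)
        d = delta_densities(base, base)
        assert all(v == 0 for v in d.delta_n_c.values())

    def test_stated_subtraction(self):
        names = [c.value for c in COUPLING_CLASSES]
        from connstates import DensityProfile

        base = DensityProfile(0.0, dict(zip(names, [0.2, 0.3, 0.1, 0.4, 0, 0])), True, 4)
        at = DensityProfile(0.5, dict(zip(names, [0.25, 0.35, 0.0, 0.4, 0, 0])), True, 3)
        d = delta_densities(at, base)
        assert d.delta_n_c["PP"] == pytest.approx(0.05)
        assert d.delta_n_c["PN"] == pytest.approx(-0.1)
        assert sum(d.delta_n_c.values()) == pytest.approx(0.0, abs=1e-12)


class TestThresholdGrid:
    def test_median_quantile_strict_survival(self):
        vals = np.arange(1.0, 101.0)
        grid = build_threshold_grid(vals, quantiles=np.array([0.5]), min_edges=1)
        phi = grid.phi_values[0]
        assert phi == pytest.approx(50.5)
        assert int((vals > phi).sum()) == 50

    def test_zero_quantile_keeps_all_edges(self):
        vals = np.arange(1.0, 21.0)
        grid = build_threshold_grid(vals, quantiles=np.array([0.0]), min_edges=1)
        assert int((vals > grid.phi_values[0]).sum()) == 20

    def test_min_edges_exceeding_count_errors(self):
        with pytest.raises(DegenerateGridError):
            build_threshold_grid(np.arange(5.0), min_edges=10)

    def test_grid_points_below_min_edges_dropped(self):
        vals = np.arange(1.0, 101.0)
        grid = build_threshold_grid(
            vals, quantiles=np.array([0.0, 0.5, 0.95]), min_edges=10
        )
        # 0.95 quantile leaves 5 < 10 edges: dropped
        assert len(grid.phi_values) == 2


def _toy_statespace(fc_scale=1.0, seed=0, weighted=True, sc_scale=1.0):
    rng = np.random.default_rng(seed)
    n = 30
    labels = RegionLabeling((["P"] * 10 + ["N"] * 10 + ["O"] * 10))
    sc = np.triu(rng.integers(1, 5, (n, n)).astype(float), k=1) * sc_scale
    sc = sc + sc.T
    fc = np.triu(rng.uniform(-1, 1, (n, n)), k=1) * fc_scale
    fc = fc + fc.T
    mask = np.ones((n, n), dtype=bool)
    np.fill_diagonal(mask, False)
    return labels, sc, fc, EdgeMask(mask, 0.8)


class TestStateSpace:
    def test_constant_fc_trajectory_at_origin(self):
        labels, sc, fc, mask = _toy_statespace()
        fc = np.where(np.eye(30, dtype=bool), 0.0, 0.5)
        traj = statespace_trajectory(mask, sc, fc, labels)
        assert np.abs(traj.x).max() == 0 and np.abs(traj.y).max() == 0

    def test_sc_scale_invariance(self):
        labels, sc, fc, mask = _toy_statespace()
        t1 = statespace_trajectory(mask, sc, fc, labels)
        t2 = statespace_trajectory(mask, 7.3 * sc, fc, labels)
        np.testing.assert_allclose(t1.x, t2.x, atol=1e-12)
        np.testing.assert_allclose(t1.y, t2.y, atol=1e-12)

    def test_unit_weights_match_unweighted(self):
        labels, sc, fc, mask = _toy_statespace()
        unit_sc = (sc > 0).astype(float)
        t_w = statespace_trajectory(mask, unit_sc, fc, labels, weighted=True)
        t_u = statespace_trajectory(mask, unit_sc, fc, labels, weighted=False)
        np.testing.assert_allclose(t_w.x, t_u.x, atol=1e-12)
        np.testing.assert_allclose(t_w.y, t_u.y, atol=1e-12)

    def test_monotone_selection(self):
        labels, sc, fc, mask = _toy_statespace()
        traj = statespace_trajectory(mask, sc, fc, labels, keep_profiles=True)
        counts = [p.n_edges_surviving for p in traj.profiles]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_conservation_at_every_threshold(self):
        labels, sc, fc, mask = _toy_statespace(seed=4)
        traj = statespace_trajectory(mask, sc, fc, labels, keep_profiles=True)
        for p in traj.profiles:
            assert sum(p.n_c.values()) == pytest.approx(1.0, abs=1e-12)
            assert sum(p.delta_n_c.values()) == pytest.approx(0.0, abs=1e-12)


class TestStatePoint:
    def test_single_point_identity(self):
        t = StateTrajectory("rest", np.array([0.1]), np.array([0.3]), np.array([-0.2]))
        p = state_point(t)
        assert (p.x_bar, p.y_bar) == (0.3, -0.2)

    def test_mean_of_two_points(self):
        t = StateTrajectory("rest", np.array([0.1, 0.2]), np.array([0.0, 2.0]), np.array([0.0, 4.0]))
        p = state_point(t)
        assert (p.x_bar, p.y_bar) == (1.0, 2.0)

    def test_order_invariance(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        perm = rng.permutation(10)
        p1 = state_point(StateTrajectory("rest", np.arange(10.0), x, y))
        p2 = state_point(StateTrajectory("rest", np.arange(10.0), x[perm], y[perm]))
        assert p1.x_bar == pytest.approx(p2.x_bar) and p1.y_bar == pytest.approx(p2.y_bar)

    def test_empty_trajectory_errors(self):
        with pytest.raises(ValueError):
            state_point(StateTrajectory("rest", np.array([]), np.array([]), np.array([])))
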
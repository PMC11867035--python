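"""Tests for the satisfactory domain and the backward-grid viability kernel.

The core correctness check compares the backward induction against an
independent brute-force oracle that enumerates every control sequence from
every grid node, replicating the documented grid semantics (annual
constraint checks, nearest-node snapping at decision epochs).
"""

import numpy as np
import pytest

from viadapp.dapp import DecisionSchedule
from viadapp.viability import (
    ESBound,
    GridSpec,
    SatisfactoryDomain,
    compute_kernel,
    export_kernel,
    kernel_slice,
    load_kernel,
    margin,
    regulation_map,
)


SCHEDULE = DecisionSchedule(start_year=2020, horizon=10, step=5)  # 3 epochs
GRID = GridSpec((0.0, 0.0), (1.0, 1.0), (5, 5))


def _snap(grid, point):
    """Independent nearest-node lookup for the oracle."""
    lo = np.asarray(grid.lower)
    h = grid.steps
    idx_f = (np.asarray(point) - lo) / h
    if np.any(idx_f < -0.5) or np.any(idx_f > np.asarray(grid.n_points) - 0.5):
        return None
    idx = np.clip(np.rint(idx_f).astype(int), 0,
                  np.asarray(grid.n_points) - 1)
    return tuple(idx)


def _oracle_kernel(model, domain, schedule, grid):
    """Exhaustive enumeration of all control sequences from every node."""
    names = model.es_names
    nodes = grid.node_points()
    n_int = schedule.n_intervals

    def in_k(state):
        return bool(domain.contains(model.es_many(state[None, :]), names)[0])

    def interval(state, u):
        ok = True
        x = state.copy()
        for _ in range(schedule.step):
            x = model.step_many(x[None, :], u)[0]
            ok = ok and in_k(x)
        return x, ok

    node_state = {tuple(np.unravel_index(i, grid.shape)): nodes[i]
                  for i in range(len(nodes))}

    def viable_from(idx, k):
        state = node_state[idx]
        if not in_k(state):
            return False, set()
        if k == n_int:
            return True, set()
        good = set()
        for u in range(model.n_controls):
            end, ok = interval(state, u)
            if not ok:
                continue
            snapped = _snap(grid, end)
            if snapped is None:
                continue
            if viable_from(snapped, k + 1)[0]:
                good.add(u)
        return bool(good), good

    membership = {}
    controls = {}
    for k in range(n_int + 1):
        for idx in node_state:
            ok, good = viable_from(idx, k)
            membership[(k, idx)] = ok
            controls[(k, idx)] = good
    return membership, controls


class TestMargins:
    def test_level_at_threshold_is_boundary_member(self):
        domain = SatisfactoryDomain({"a": ESBound("service", 0.4)})
        report = margin(domain, ("a",), np.array([0.4]))
        assert report.raw[0] == pytest.approx(0.0)
        assert report.member

    def test_maximally_inside_scores_one(self):
        domain = SatisfactoryDomain({
            "svc": ESBound("service", 0.3),
            "dis": ESBound("disservice", 0.6),
        })
        report = margin(domain, ("svc", "dis"), np.array([1.0, 0.0]))
        assert report.normalized_sum == pytest.approx(1.0)

    def test_membership_matches_per_constraint_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            names = ("s1", "s2", "d1")
            thr = rng.uniform(0.05, 0.95, size=3)
            domain = SatisfactoryDomain({
                "s1": ESBound("service", thr[0]),
                "s2": ESBound("service", thr[1]),
                "d1": ESBound("disservice", thr[2]),
            })
            levels = rng.uniform(0, 1, size=3)
            want = (levels[0] >= thr[0] and levels[1] >= thr[1]
                    and levels[2] <= thr[2])
            assert margin(domain, names, levels).member == want


class TestKernelOracle:
    def test_membership_and_regulation_match_brute_force(
            self, toy_model, toy_domain):
        kernel = compute_kernel(toy_model, toy_domain, SCHEDULE, GRID)
        membership, controls = _oracle_kernel(
            toy_model, toy_domain, SCHEDULE, GRID)
        for k in range(SCHEDULE.epochs):
            got = kernel.membership[k].reshape(GRID.shape)
            for idx in np.ndindex(*GRID.shape):
                assert got[idx] == membership[(k, idx)], (k, idx)
        # regulation map equals the oracle's viable-control sets
        axes = GRID.axes()
        for k in range(SCHEDULE.epochs - 1):
            for idx in np.ndindex(*GRID.shape):
                state = np.array([axes[0][idx[0]], axes[1][idx[1]]])
                got = regulation_map(kernel, state, k)
                assert got == frozenset(controls[(k, idx)]), (k, idx)

    def test_vacuous_constraints_fill_grid(self, toy_model, vacuous_domain):
        kernel = compute_kernel(toy_model, vacuous_domain, SCHEDULE, GRID)
        assert kernel.membership.all()

    def test_unreachable_floor_empties_kernel(self, toy_model):
        # floors above every attractor: only the (1,1) corner satisfies them
        # instantaneously, and no control can hold any state there
        domain = SatisfactoryDomain({
            "es_x": ESBound("service", 0.999),
            "es_y": ESBound("service", 0.999),
        })
        kernel = compute_kernel(toy_model, domain, SCHEDULE, GRID)
        assert not kernel.membership[:-1].any()
        assert not kernel.viable_controls.any()


class TestRegulationMap:
    def test_outside_domain_state_has_empty_control_set(
            self, toy_model, toy_domain):
        kernel = compute_kernel(toy_model, toy_domain, SCHEDULE, GRID)
        assert regulation_map(kernel, np.array([0.0, 0.0]), 0) == frozenset()

    def test_interior_state_has_nonempty_subset(self, toy_model, toy_domain):
        kernel = compute_kernel(toy_model, toy_domain, SCHEDULE, GRID)
        controls = regulation_map(kernel, np.array([0.65, 0.65]), 0)
        assert controls
        assert controls <= frozenset(range(toy_model.n_controls))

    def test_state_outside_grid_rejected(self, toy_model, toy_domain):
        kernel = compute_kernel(toy_model, toy_domain, SCHEDULE, GRID)
        with pytest.raises(ValueError, match="outside the grid"):
            regulation_map(kernel, np.array([2.0, 0.5]), 0)

    def test_final_epoch_has_no_regulation(self, toy_model, toy_domain):
        kernel = compute_kernel(toy_model, toy_domain, SCHEDULE, GRID)
        with pytest.raises(ValueError, match="epoch"):
            regulation_map(kernel, np.array([0.5, 0.5]),
                           SCHEDULE.epochs - 1)


class TestSlices:
    def test_slice_matches_direct_lookup(self, toy_model, toy_domain):
        kernel = compute_kernel(toy_model, toy_domain, SCHEDULE, GRID)
        cut = kernel_slice(kernel, (0, 1), {})
        np.testing.assert_array_equal(cut, kernel.membership_grid(0))

    def test_empty_and_full_kernels_slice_uniformly(
            self, toy_model, toy_domain, vacuous_domain):
        full = compute_kernel(toy_model, vacuous_domain, SCHEDULE, GRID)
        assert kernel_slice(full, (0, 1), {}).all()
        empty_domain = SatisfactoryDomain({
            "es_x": ESBound("service", 1.0),
            "es_y": ESBound("service", 1.0),
        })
        empty = compute_kernel(toy_model, empty_domain, SCHEDULE, GRID)
        assert not kernel_slice(empty, (0, 1), {}).any()


class TestMonotonicity:
    def test_relaxing_constraints_grows_kernel(self, toy_model, toy_domain):
        tight = compute_kernel(toy_model, toy_domain, SCHEDULE, GRID)
        loose = compute_kernel(toy_model, toy_domain.relaxed(0.1),
                               SCHEDULE, GRID)
        assert np.all(loose.membership >= tight.membership)

    def test_longer_horizon_shrinks_epoch0_kernel(self, toy_model, toy_domain):
        short = compute_kernel(toy_model, toy_domain,
                               DecisionSchedule(2020, 10, 5), GRID)
        long = compute_kernel(toy_model, toy_domain,
                              DecisionSchedule(2020, 15, 5), GRID)
        assert np.all(long.membership[0] <= short.membership[0])

    def test_fixed_point_inside_domain_always_viable(self, toy_model,
                                                     toy_domain):
        # control 2 contracts toward (0.65, 0.65), strictly inside K_R
        fp = np.array([0.65, 0.65])
        for horizon in (5, 10, 20, 30):
            schedule = DecisionSchedule(2020, horizon, 5)
            kernel = compute_kernel(toy_model, toy_domain, schedule, GRID)
            flat, inb = GRID.snap(fp[None, :])
            assert inb[0] and kernel.membership[0][flat[0]]


class TestExport:
    def test_kernel_roundtrips_through_gzipped_json(
            self, tmp_path, toy_model, toy_domain):
        kernel = compute_kernel(toy_model, toy_domain, SCHEDULE, GRID)
        path = tmp_path / "kernel.json.gz"
        export_kernel(kernel, path)
        loaded = load_kernel(path)
        np.testing.assert_array_equal(loaded.membership, kernel.membership)
        np.testing.assert_array_equal(loaded.viable_controls,
                                      kernel.viable_controls)
        assert loaded.grid == kernel.grid
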
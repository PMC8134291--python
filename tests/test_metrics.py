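"""Displacement metric, ensemble spread and rotational stability."""

import numpy as np
import pytest

from emtcomp import metrics
from emtcomp.datamodel import EnvironmentDataset
from emtcomp.simulator import make_grid
from tests.conftest import synthetic_dataset


def brute_force_summary(measured, true):
    """Independent double-loop reference for displacement statistics."""
    errs = [m - t for m, t in zip(measured, true)]
    n = len(errs)
    rmse = (sum(e * e for e in errs) / n) ** 0.5
    mean = sum(errs) / n
    std = (sum((e - mean) ** 2 for e in errs) / (n - 1)) ** 0.5 if n > 1 else 0.0
    return rmse, std


class TestDisplacementPairs:
    def test_two_node_grid_yields_single_pitch_pair(self):
        g = make_grid(8, 2, 1, [0])
        ds = synthetic_dataset(g, z_shift=0.0)
        pairs = metrics.build_displacement_pairs(ds, g)
        assert pairs.n_pairs == 1
        assert pairs.true_dist[0] == pytest.approx(8.0)

    def test_all_pairs_counts_n_choose_2(self, small_grid):
        ds = synthetic_dataset(small_grid)
        pairs = metrics.build_displacement_pairs(ds, small_grid, scheme="all-pairs")
        n = len(ds)
        assert pairs.n_pairs == n * (n - 1) // 2

    def test_neighbor_scheme_matches_brute_force_enumeration(self, small_grid):
        ds = synthetic_dataset(small_grid)
        pairs = metrics.build_displacement_pairs(ds, small_grid)
        # brute force: adjacent means exactly one lattice step along one axis
        ijk = small_grid.node_ijk
        count = 0
        for i in range(small_grid.n_nodes):
            for j in range(i + 1, small_grid.n_nodes):
                if np.abs(ijk[i] - ijk[j]).sum() == 1:
                    count += 1
        assert pairs.n_pairs == count

    def test_unmapped_sample_rejected(self, small_grid):
        ds = synthetic_dataset(small_grid)
        ds.node_index[0] = small_grid.n_nodes + 5
        with pytest.raises(ValueError):
            metrics.build_displacement_pairs(ds, small_grid)


class TestDisplacementError:
    def test_perfect_measurement_gives_zero(self, small_grid):
        ds = synthetic_dataset(small_grid, z_shift=0.0)
        # constant z shift preserves distances; zero shift certainly does
        s = metrics.evaluate_dataset(ds, small_grid)
        assert s.rmse == pytest.approx(0.0, abs=1e-12)
        assert s.std == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_closed_form(self):
        g = make_grid(8, 2, 1, [0])
        ds = synthetic_dataset(g, z_shift=0.0)
        ds.values[1, 0] = 9.0  # measured 9 mm, true 8 mm
        s = metrics.evaluate_dataset(ds, g)
        assert s.rmse == pytest.approx(1.0)
        assert s.std == 0.0

    def test_matches_double_loop_oracle_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(2, 50)
            measured = rng.uniform(1, 20, n)
            true = rng.uniform(1, 20, n)
            ds = metrics.DisplacementSet(
                pairs=np.column_stack([np.arange(n), np.arange(n) + n]),
                node_pairs=np.column_stack([np.arange(n), np.arange(n) + n]),
                measured_dist=measured, true_dist=true)
            s = metrics.displacement_error(ds)
            rmse, std = brute_force_summary(measured, true)
            assert s.rmse == pytest.approx(rmse, abs=1e-12)
            assert s.std == pytest.approx(std, abs=1e-12)

    def test_invariant_to_rigid_motion_of_point_set(self, small_grid):
        ds = synthetic_dataset(small_grid, seed=5)
        before = metrics.evaluate_dataset(ds, small_grid)
        theta = 0.3
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1]])
        moved = ds.values.copy()
        moved[:, :3] = ds.values[:, :3] @ R.T + np.array([5.0, -3.0, 11.0])
        after = metrics.evaluate_dataset(ds.with_values(moved), small_grid)
        assert after.rmse == pytest.approx(before.rmse, abs=1e-9)
        assert after.std == pytest.approx(before.std, abs=1e-9)


class TestPredictionSpread:
    def test_identical_members_have_zero_spread(self):
        member = np.random.default_rng(0).normal(size=(1, 30, 7))
        per_point, agg = metrics.prediction_spread(np.repeat(member, 5, axis=0))
        assert np.all(per_point == 0.0) and agg == 0.0

    def test_constant_z_offset_closed_form(self):
        base = np.zeros((2, 10, 7))
        base[1, :, 2] = 2.0  # members differ by 2 mm in z only
        per_point, agg = metrics.prediction_spread(base)
        expected = np.std([0.0, 2.0], ddof=1)
        assert np.allclose(per_point, expected)
        assert agg == pytest.approx(expected)

    def test_matches_brute_force_and_is_permutation_invariant(self):
        rng = np.random.default_rng(3)
        members = rng.normal(size=(10, 25, 7))
        per_point, agg = metrics.prediction_spread(members)
        brute = np.array([
            np.sqrt(sum(np.std(members[:, i, ax], ddof=1) ** 2 for ax in range(3)))
            for i in range(25)])
        assert np.allclose(per_point, brute, atol=1e-12)
        assert agg == pytest.approx(brute.mean(), abs=1e-12)
        perm = members[rng.permutation(10)]
        _, agg2 = metrics.prediction_spread(perm)
        assert agg2 == pytest.approx(agg, abs=1e-12)

    def test_requires_two_members(self):
        with pytest.raises(ValueError):
            metrics.prediction_spread(np.zeros((1, 5, 7)))


class TestRotationalStability:
    def _traj(self, phi_x, phi_y, phi_z):
        n = len(phi_x)
        vals = np.column_stack([np.arange(n) * 8.0, np.zeros(n), np.zeros(n),
                                np.full(n, 5.0), phi_x, phi_y, phi_z])
        return EnvironmentDataset("t", "C", vals, np.arange(n),
                                  c_arm_distance_cm=9.0)

    def test_constant_angles_are_perfectly_stable(self):
        t = self._traj(np.full(5, 10.0), np.full(5, -20.0), np.zeros(5))
        out = metrics.rotational_stability(t)
        for stat in out.values():
            assert stat.std == pytest.approx(0.0, abs=1e-9)
            assert stat.max_drift == pytest.approx(0.0, abs=1e-9)

    def test_wraparound_does_not_inflate_std(self):
        t = self._traj(np.zeros(2), np.zeros(2), np.array([359.0, 1.0]))
        az = metrics.rotational_stability(t)["azimuth"]
        assert az.std == pytest.approx(1.0, abs=0.1)
        assert abs(az.mean) < 1.0

    def test_drift_uses_unwrapped_excursion(self):
        t = self._traj(np.array([0.0, 170.0, -170.0]), np.zeros(3), np.zeros(3))
        roll = metrics.rotational_stability(t)["roll"]
        assert roll.max_drift == pytest.approx(190.0)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            metrics.rotational_stability(self._traj(*(np.zeros(1),) * 3))


class TestCrossEnvironmentSpread:
    def test_identical_environments_have_zero_spread(self, small_grid):
        a = synthetic_dataset(small_grid, "a", seed=1)
        b = synthetic_dataset(small_grid, "b", seed=1)
        _, med = metrics.cross_environment_spread([a, b])
        assert med == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_gives_that_spread(self, small_grid):
        a = synthetic_dataset(small_grid, "a", seed=1)
        b = synthetic_dataset(small_grid, "b", seed=1)
        moved = b.values.copy()
        moved[:, 2] += 3.0
        _, med = metrics.cross_environment_spread([a, b.with_values(moved)])
        assert med == pytest.approx(3.0, abs=1e-9)
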
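"""Tracking-accuracy metrology.

Three families of statistics:

* the displacement error metric — measured inter-point distances compared to
  known lattice distances of the calibrated board.  Because it is built on
  relative displacements it needs no external measurement standard and is
  invariant to a rigid motion of the whole measured point set;
* the deep-ensemble predictive spread ``sigma_pred`` — the standard
  deviation of the compensated position across ensemble members;
* rotational-stability statistics of a sensor trajectory — circular mean and
  deviation of the azimuth (phi_z), elevation (phi_y) and roll (phi_x)
  channels, plus the maximum unwrapped drift from the starting orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import circmean, circstd

from .datamodel import EnvironmentDataset, GroundTruthGrid, wrap_angle

ANGLE_NAMES = {"azimuth": "phi_z", "elevation": "phi_y", "roll": "phi_x"}
_ANGLE_COL = {"phi_x": 4, "phi_y": 5, "phi_z": 6}


@dataclass(frozen=True)
class DisplacementSet:
    """Measured vs true inter-point distances for a list of node pairs."""

    pairs: np.ndarray          # (m, 2) sample indices
    node_pairs: np.ndarray     # (m, 2) grid node ids
    measured_dist: np.ndarray  # mm
    true_dist: np.ndarray      # mm

    def __post_init__(self):
        object.__setattr__(self, "pairs", np.asarray(self.pairs, dtype=int).reshape(-1, 2))
        object.__setattr__(self, "node_pairs", np.asarray(self.node_pairs, dtype=int).reshape(-1, 2))
        object.__setattr__(self, "measured_dist", np.asarray(self.measured_dist, dtype=float))
        object.__setattr__(self, "true_dist", np.asarray(self.true_dist, dtype=float))
        if np.any(self.node_pairs[:, 0] == self.node_pairs[:, 1]):
            raise ValueError("displacement pairs must join distinct nodes")
        if np.any(self.true_dist <= 0):
            raise ValueError("true distances must be strictly positive")

    @property
    def n_pairs(self) -> int:
        return len(self.measured_dist)


@dataclass(frozen=True)
class ErrorSummary:
    """Displacement RMSE and standard deviation, in mm."""

    rmse: float
    std: float
    n_pairs: int


def build_displacement_pairs(dataset: EnvironmentDataset, grid: GroundTruthGrid,
                             scheme: str = "lattice-neighbors") -> DisplacementSet:
    """Enumerate distance pairs among the dataset's grid nodes.

    Schemes:
      * ``"lattice-neighbors"`` (default): each node paired with its adjacent
        lattice nodes — one step along x or y within a layer, or the same
        board position on an adjacent elevation layer;
      * ``"all-pairs"``: every unordered node pair.

    The pair list is deterministic (ordered by sample index).
    """
    node_ids = dataset.node_index
    if len(node_ids) < 2:
        raise ValueError("need at least 2 samples to build displacement pairs")
    if np.any(node_ids < 0) or np.any(node_ids >= grid.n_nodes):
        raise ValueError("dataset contains samples unmapped to grid nodes")
    ijk = grid.node_ijk[node_ids]
    idx_i, idx_j = np.triu_indices(len(node_ids), k=1)
    if scheme == "all-pairs":
        keep = node_ids[idx_i] != node_ids[idx_j]
    elif scheme == "lattice-neighbors":
        diff = np.abs(ijk[idx_i] - ijk[idx_j])
        keep = diff.sum(axis=1) == 1
    else:
        raise ValueError(f"unknown pair scheme {scheme!r}")
    idx_i, idx_j = idx_i[keep], idx_j[keep]
    pos = dataset.positions
    measured = np.linalg.norm(pos[idx_i] - pos[idx_j], axis=1)
    true = grid.node_distance(node_ids[idx_i], node_ids[idx_j])
    return DisplacementSet(
        pairs=np.column_stack([idx_i, idx_j]),
        node_pairs=np.column_stack([node_ids[idx_i], node_ids[idx_j]]),
        measured_dist=measured, true_dist=true)


def displacement_error(ds: DisplacementSet) -> ErrorSummary:
    """Root-mean-square and sample std of per-pair distance errors (mm).

    The std uses the n-1 denominator (sample convention); a single pair has
    std 0 by definition.
    """
    if ds.n_pairs < 1:
        raise ValueError("displacement set is empty")
    err = ds.measured_dist - ds.true_dist
    rmse = float(np.sqrt(np.mean(err**2)))
    std = float(np.std(err, ddof=1)) if ds.n_pairs > 1 else 0.0
    return ErrorSummary(rmse=rmse, std=std, n_pairs=ds.n_pairs)


def evaluate_dataset(dataset: EnvironmentDataset, grid: GroundTruthGrid,
                     scheme: str = "lattice-neighbors") -> ErrorSummary:
    """Convenience: pairs + displacement error in one call."""
    return displacement_error(build_displacement_pairs(dataset, grid, scheme))


def prediction_spread(member_values: np.ndarray) -> tuple[np.ndarray, float]:
    """Epistemic spread of an ensemble's compensated positions.

    `member_values` is (n_members, n_points, >=3); only the positional
    columns enter.  Per point, the sample std (n-1) of each axis across
    members is combined as the Euclidean norm of the per-axis stds; the
    aggregate ``sigma_pred`` is the mean over points.  Returns
    ``(per_point, aggregate)`` in mm.
    """
    member_values = np.asarray(member_values, dtype=float)
    if member_values.ndim != 3:
        raise ValueError("expected (n_members, n_points, n_channels) array")
    if member_values.shape[0] < 2:
        raise ValueError("prediction spread requires >= 2 ensemble members")
    pos = member_values[:, :, :3]
    per_axis = np.std(pos, axis=0, ddof=1)
    # identical members must give exactly zero, not rounding residue
    per_axis[pos.max(axis=0) == pos.min(axis=0)] = 0.0
    per_point = np.linalg.norm(per_axis, axis=1)
    return per_point, float(per_point.mean())


@dataclass(frozen=True)
class AngleStability:
    """Circular summary of one orientation channel over a trajectory (deg)."""

    mean: float
    std: float
    max_drift: float


def rotational_stability(trajectory: EnvironmentDataset | np.ndarray) -> dict[str, AngleStability]:
    """Stability of azimuth/elevation/roll along an ordered trajectory.

    Mean and std are circular (wrap-aware); the drift is the largest
    excursion ``|theta_i - theta_0|`` of the unwrapped angle sequence.
    """
    values = trajectory.values if isinstance(trajectory, EnvironmentDataset) else np.asarray(trajectory)
    if len(values) < 2:
        raise ValueError("rotational stability requires >= 2 trajectory samples")
    out = {}
    for name, col in ((k, _ANGLE_COL[v]) for k, v in ANGLE_NAMES.items()):
        theta = wrap_angle(values[:, col])
        mean = float(circmean(theta, high=180.0, low=-180.0))
        if np.ptp(theta) == 0.0:  # constant channel: exactly stable
            mean, theta = float(theta[0]), theta
            std = 0.0
        else:
            std = float(circstd(theta, high=180.0, low=-180.0))
        unwrapped = np.unwrap(theta, period=360.0)
        drift = float(np.max(np.abs(unwrapped - unwrapped[0])))
        out[name] = AngleStability(mean=wrap_angle(mean).item(), std=std, max_drift=drift)
    return out


def cross_environment_spread(datasets: list[EnvironmentDataset]) -> tuple[np.ndarray, float]:
    """Consistency of per-node positions across environments.

    For every grid node present in at least two of the datasets, computes the
    mean pairwise Euclidean distance between the node's measured positions in
    the different environments.  Returns ``(per_node_spread, median)`` in mm.
    A consistent compensation maps the same physical node to nearly the same
    point regardless of the input environment.
    """
    if len(datasets) < 2:
        raise ValueError("need >= 2 environments to measure consistency")
    by_node: dict[int, list[np.ndarray]] = {}
    for ds in datasets:
        for node, pos in zip(ds.node_index, ds.positions):
            by_node.setdefault(int(node), []).append(pos)
    spreads = []
    for node in sorted(by_node):
        pts = np.asarray(by_node[node])
        if len(pts) < 2:
            continue
        ii, jj = np.triu_indices(len(pts), k=1)
        spreads.append(np.linalg.norm(pts[ii] - pts[jj], axis=1).mean())
    if not spreads:
        raise ValueError("no grid node is shared between the environments")
    spreads = np.asarray(spreads)
    return spreads, float(np.median(spreads))
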
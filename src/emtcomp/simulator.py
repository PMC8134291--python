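"""Synthetic EMT acquisition and C-arm distortion simulator.

No public measurement set exists for the bench/bedside protocol this package
targets, so every downstream stage (training, compensation, evaluation) is
exercised on simulated data.  The simulator emulates the acquisition
protocol: a calibrated pegboard lattice (8 mm pitch) measured at three
elevations, 500 noisy samples averaged per measuring point, a smooth
distortion field whose magnitude grows as the C-arm moves closer and which
predominantly displaces the z component, a quality channel coupled to the
local distortion magnitude, and smooth orientation perturbations.

The distortion field is an explicit modelling choice, not a physical model:
a low-order polynomial trend plus random radial-basis bumps, scaled by
``(reference_distance / carm_distance) ** falloff_exponent``.  This
reproduces the characteristic monotone distance–error trend of bedside
measurements without claiming electromagnetic fidelity.

All randomness flows from a single suite seed through per-environment
derived seeds, so a suite is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .datamodel import EnvironmentDataset, GroundTruthGrid

REFERENCE_DISTANCE_CM = 50.0


def make_grid(pitch_mm: float, nx: int, ny: int,
              layer_elevations: Sequence[float]) -> GroundTruthGrid:
    """Build the calibrated board lattice: `nx` x `ny` nodes per layer.

    Node ids are row-major (layer, then row, then column); the default
    acquisition board is 5 x 4 nodes at 8 mm pitch on three elevations,
    i.e. 60 measuring points.
    """
    return GroundTruthGrid(pitch=float(pitch_mm), nx=int(nx), ny=int(ny),
                           layer_elevations=tuple(layer_elevations))


@dataclass(frozen=True)
class QualityCoupling:
    """Monotone map from local displacement magnitude (mm) to the quality channel.

    ``higher_is_worse=True`` mimics a DC-tracker distortion indicator whose
    value grows with distortion.
    """

    baseline: float = 5.0
    gain_per_mm: float = 10.0
    noise_std: float = 0.3
    higher_is_worse: bool = True

    def __call__(self, magnitude_mm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        sign = 1.0 if self.higher_is_worse else -1.0
        return (self.baseline + sign * self.gain_per_mm * magnitude_mm
                + rng.normal(0.0, self.noise_std, size=np.shape(magnitude_mm)))


@dataclass(frozen=True)
class DistortionFieldSpec:
    """Parametric description of one simulated C-arm distortion environment.

    ``amplitude_mm`` is the per-axis RMS displacement scale (before axis
    weighting) at the reference distance; the realized scale is
    ``amplitude_mm * (reference / carm_distance_cm) ** falloff_exponent``,
    strictly decreasing in C-arm distance.  ``axis_weights`` split the
    displacement across (x, y, z); z receives the dominant share by default
    because it is the axis most susceptible to C-arm distortion.
    """

    amplitude_mm: float = 0.25
    carm_distance_cm: float | None = None
    length_scale_mm: float = 40.0
    axis_weights: tuple[float, float, float] = (0.15, 0.15, 0.70)
    quality_coupling: QualityCoupling = field(default_factory=QualityCoupling)
    angle_noise_deg: float = 0.5
    seed: int = 0
    falloff_exponent: float = 1.5
    reference_distance_cm: float = REFERENCE_DISTANCE_CM
    n_bumps: int = 12
    # Environments sharing one physical distorter (the same C-arm moved in
    # distance) see correlated fields: `seed` fixes the shared realization,
    # while `variation_seed`/`variation_frac` mix in a small independent
    # component representing repositioning and gantry effects.
    variation_frac: float = 0.0
    variation_seed: int = 0
    trend_weight: float = 0.5

    def __post_init__(self):
        w = np.asarray(self.axis_weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("axis_weights must be nonnegative and sum to 1")
        if self.amplitude_mm < 0 or self.length_scale_mm <= 0:
            raise ValueError("amplitude must be >= 0 and length scale > 0")

    @property
    def scale(self) -> float:
        """Realized per-axis displacement scale in mm."""
        if self.carm_distance_cm is None:
            return self.amplitude_mm
        return self.amplitude_mm * (
            self.reference_distance_cm / self.carm_distance_cm
        ) ** self.falloff_exponent


@dataclass(frozen=True)
class AcquisitionSpec:
    """Per-point repeated sampling and averaging, as in the bench protocol."""

    samples_per_point: int = 500
    noise_std_mm: float = 0.5
    noise_std_q: float = 1.0
    noise_std_deg: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.samples_per_point < 1:
            raise ValueError("samples_per_point must be >= 1")


def _smooth_fields(spec: DistortionFieldSpec, box_lo: np.ndarray, box_hi: np.ndarray,
                   n_channels: int) -> Callable[[np.ndarray], np.ndarray]:
    """Build `n_channels` smooth scalar fields of unit RMS over the box.

    Each channel is a linear trend plus `n_bumps` Gaussian radial-basis
    bumps of width `length_scale_mm`, with coefficients drawn from the
    spec seed.  Channels are normalized to unit RMS over a probe lattice
    spanning the box, so `spec.scale` sets physical units downstream.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length_scale_mm
    centers = rng.uniform(box_lo - 0.5 * L, box_hi + 0.5 * L,
                          size=(spec.n_bumps, 3))
    bump_coef = rng.normal(0.0, 1.0, size=(spec.n_bumps, n_channels))
    trend_coef = rng.normal(0.0, spec.trend_weight, size=(3, n_channels))
    mid = 0.5 * (box_lo + box_hi)

    def raw(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        phi = np.exp(-0.5 * d2 / L**2)
        return phi @ bump_coef + ((pts - mid) / L) @ trend_coef

    # probe lattice for RMS normalization (deterministic, independent of input)
    axes = [np.linspace(lo, hi, 7) for lo, hi in zip(box_lo, box_hi)]
    probe = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    rms = np.sqrt((raw(probe) ** 2).mean(axis=0))
    rms = np.where(rms > 0, rms, 1.0)

    def evaluate(points: np.ndarray) -> np.ndarray:
        return raw(points) / rms

    return evaluate


def apply_distortion(grid: GroundTruthGrid, spec: DistortionFieldSpec,
                     base_angles: Sequence[float] = (0.0, 0.0, 0.0),
                     positions: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the distortion at the grid nodes (or explicit `positions`).

    Returns an (n, 7) array of noise-free distorted channel values:
    displaced position, coupled quality, and perturbed orientation.
    Deterministic for a fixed spec (the quality noise uses the spec seed).
    """
    pos = grid.node_positions if positions is None else np.atleast_2d(positions)
    lo = grid.node_positions.min(axis=0)
    hi = grid.node_positions.max(axis=0)
    fields = _smooth_fields(spec, lo, hi, n_channels=6)
    g = fields(pos)
    if spec.variation_frac > 0:
        var_fields = _smooth_fields(replace(spec, seed=spec.variation_seed), lo, hi, 6)
        g = (g + spec.variation_frac * var_fields(pos)) / np.sqrt(
            1.0 + spec.variation_frac**2)
    w = np.asarray(spec.axis_weights)
    displacement = spec.scale * w * g[:, :3]
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]).generate_state(1)[0])
    magnitude = np.linalg.norm(displacement, axis=1)
    q = spec.quality_coupling(magnitude, rng)
    angle_scale = spec.angle_noise_deg * (spec.scale / max(spec.amplitude_mm, 1e-300)
                                          if spec.amplitude_mm > 0 else 0.0)
    angles = np.asarray(base_angles) + angle_scale * g[:, 3:]
    if spec.amplitude_mm == 0:
        displacement = np.zeros_like(displacement)
        angles = np.broadcast_to(np.asarray(base_angles, dtype=float), angles.shape).copy()
    return np.column_stack([pos + displacement, q, angles])


def simulate_acquisition(distorted_values: np.ndarray, acq: AcquisitionSpec,
                         node_index: np.ndarray | None = None,
                         name: str = "environment", domain: str = "C",
                         **dataset_kwargs) -> EnvironmentDataset:
    """Average `samples_per_point` noisy draws per node, as the bench protocol does.

    The stored value per node is the mean of i.i.d. Gaussian perturbations of
    the noise-free distorted value, so residual noise shrinks as
    ``1/sqrt(samples_per_point)``.
    """
    values = np.atleast_2d(np.asarray(distorted_values, dtype=float))
    rng = np.random.default_rng(acq.seed)
    sig = np.array([acq.noise_std_mm] * 3 + [acq.noise_std_q] + [acq.noise_std_deg] * 3)
    draws = values[None, :, :] + rng.normal(
        0.0, 1.0, size=(acq.samples_per_point,) + values.shape) * sig
    averaged = draws.mean(axis=0)
    if node_index is None:
        node_index = np.arange(len(values))
    return EnvironmentDataset(name=name, domain=domain, values=averaged,
                              node_index=node_index, **dataset_kwargs)


@dataclass(frozen=True)
class EnvironmentSpec:
    """One environment in a suite: the lab bench or a C-arm placement."""

    name: str
    domain: str  # "C" or "L"
    carm_distance_cm: float | None = None
    gantry_angle_deg: float | None = None
    layer_mask: tuple[bool, ...] | None = None


@dataclass(frozen=True)
class SuiteConfig:
    """Full description of a simulated measurement campaign.

    Defaults emulate the bench/bedside study design: one laboratory
    environment restricted to 2 of 3 elevation layers, C-arm environments at
    several source distances, 60-node board, 500-sample averaging.  The
    ``intrinsic_xy_warp_scale`` adds a small affine x-y warp common to every
    environment, standing in for the tracker's baseline field nonlinearity
    (present even on the bench); it is what the linear fine-tuning stage can
    learn and remove.
    """

    environments: tuple[EnvironmentSpec, ...] = (
        EnvironmentSpec("laboratory", "L", layer_mask=(True, True, False)),
        EnvironmentSpec("carm_08cm", "C", carm_distance_cm=8.0),
        EnvironmentSpec("carm_11cm", "C", carm_distance_cm=11.0),
        EnvironmentSpec("carm_50cm", "C", carm_distance_cm=50.0, gantry_angle_deg=60.0),
    )
    amplitude_mm: float = 3.6
    lab_amplitude_mm: float = 0.06
    length_scale_mm: float = 15.0
    axis_weights: tuple[float, float, float] = (0.15, 0.15, 0.70)
    quality_coupling: QualityCoupling = field(default_factory=QualityCoupling)
    angle_noise_deg: float = 2.0
    falloff_exponent: float = 0.4
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    carm_variation_frac: float = 0.1
    intrinsic_xy_warp_scale: float = 0.012
    base_angles: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0


def _derived_seed(master: int, *path: int) -> int:
    return int(np.random.SeedSequence([int(master), *path]).generate_state(1)[0] % (2**31))


def intrinsic_warp_matrix(cfg: SuiteConfig) -> np.ndarray:
    """Domain-common affine x-y warp: small random scale/shear plus offset.

    Returns a (2, 3) matrix ``A`` so that ``(x', y') = A @ (x, y, 1)``.
    Drawn once per suite seed; identical in every environment.
    """
    rng = np.random.default_rng(_derived_seed(cfg.seed, 999))
    s = cfg.intrinsic_xy_warp_scale
    lin = np.eye(2) + rng.normal(0.0, s, size=(2, 2))
    off = rng.normal(0.0, 0.5, size=2)
    return np.column_stack([lin, off])


def _apply_xy_warp(values: np.ndarray, warp: np.ndarray) -> np.ndarray:
    out = values.copy()
    xy1 = np.column_stack([values[:, 0], values[:, 1], np.ones(len(values))])
    out[:, :2] = xy1 @ warp.T
    return out


def field_spec_for(cfg: SuiteConfig, env: EnvironmentSpec, index: int) -> DistortionFieldSpec:
    """Field realization for one environment of the suite.

    All C-arm environments share one base realization (the same physical
    distorter at different distances) mixed with a small per-environment
    variation; the laboratory field is an independent, much weaker
    realization (a different room, residual background distortion only).
    """
    if env.domain == "L":
        return DistortionFieldSpec(
            amplitude_mm=cfg.lab_amplitude_mm,
            carm_distance_cm=None,
            length_scale_mm=cfg.length_scale_mm,
            axis_weights=cfg.axis_weights,
            quality_coupling=cfg.quality_coupling,
            angle_noise_deg=cfg.angle_noise_deg,
            falloff_exponent=cfg.falloff_exponent,
            seed=_derived_seed(cfg.seed, 555, index),
        )
    return DistortionFieldSpec(
        amplitude_mm=cfg.amplitude_mm,
        carm_distance_cm=env.carm_distance_cm,
        length_scale_mm=cfg.length_scale_mm,
        axis_weights=cfg.axis_weights,
        quality_coupling=cfg.quality_coupling,
        angle_noise_deg=cfg.angle_noise_deg,
        falloff_exponent=cfg.falloff_exponent,
        seed=_derived_seed(cfg.seed, 777),
        variation_frac=cfg.carm_variation_frac,
        variation_seed=_derived_seed(cfg.seed, index, 3),
    )


def generate_environment_suite(grid: GroundTruthGrid,
                               cfg: SuiteConfig) -> list[EnvironmentDataset]:
    """Simulate every environment in `cfg` on `grid`, fully seeded.

    Laboratory environments may be restricted to a subset of elevation
    layers (as when only 2 of 3 layers enter training); C-arm environments
    cover the full board.  Raw displacement error is ordered inversely with
    C-arm distance because the field scale follows the distance falloff law.
    """
    if not cfg.environments:
        raise ValueError("suite config names no environments")
    if not any(e.domain == "L" for e in cfg.environments):
        raise ValueError("suite config must include a laboratory environment")
    warp = intrinsic_warp_matrix(cfg)
    datasets = []
    for idx, env in enumerate(cfg.environments):
        node_ids = grid.active_node_ids(env.layer_mask)
        positions = grid.node_positions[node_ids]
        fspec = field_spec_for(cfg, env, idx)
        distorted = apply_distortion(grid, fspec, base_angles=cfg.base_angles,
                                     positions=positions)
        distorted = _apply_xy_warp(distorted, warp)
        acq = replace(cfg.acquisition, seed=_derived_seed(cfg.seed, idx, 1))
        datasets.append(simulate_acquisition(
            distorted, acq, node_index=node_ids, name=env.name, domain=env.domain,
            c_arm_distance_cm=env.carm_distance_cm,
            gantry_angle_deg=env.gantry_angle_deg))
    return datasets


def simulate_pullout(grid: GroundTruthGrid, cfg: SuiteConfig,
                     carm_distance_cm: float = 9.0,
                     n_steps: int = 13, step_mm: float = 8.0,
                     start: Sequence[float] = (-32.0, 12.0, 20.0),
                     base_angles: Sequence[float] = (0.0, 2.0, 0.0),
                     env_index: int = 101) -> EnvironmentDataset:
    """Simulate a straight sensor pull-out trajectory near the C-arm.

    The sensor retracts along +x in `n_steps` steps of `step_mm` (default
    13 steps of 8 mm) with a fixed true orientation, so azimuth/elevation/
    roll should be constant; the distortion field perturbs both position
    and orientation.  Used for the rotational-stability evaluation.
    """
    t = np.arange(n_steps)[:, None]
    positions = np.asarray(start, dtype=float) + t * np.array([step_mm, 0.0, 0.0])
    fspec = field_spec_for(
        cfg, EnvironmentSpec("pullout", "C", carm_distance_cm=carm_distance_cm),
        env_index)
    distorted = apply_distortion(grid, fspec, base_angles=base_angles,
                                 positions=positions)
    distorted = _apply_xy_warp(distorted, intrinsic_warp_matrix(cfg))
    acq = replace(cfg.acquisition, seed=_derived_seed(cfg.seed, env_index, 1))
    return simulate_acquisition(distorted, acq, name="pullout", domain="C",
                                c_arm_distance_cm=carm_distance_cm)
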
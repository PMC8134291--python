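"""Core record types for electromagnetic-tracking (EMT) measurements.

An EMT measuring point is the 7-tuple ``(x, y, z, q, phi_x, phi_y, phi_z)``:
position in tracker-frame millimetres, the tracker's dimensionless quality
(distortion) estimate, and orientation angles in degrees.  Points are grouped
into named environment datasets, each belonging to either the clean
laboratory/bench domain ``L`` or a C-arm-distorted bedside domain ``C``.

Datasets are stored as CSV (comma separated, dot decimal, UTF-8, mandatory
header ``node_id,x,y,z,q,phi_x,phi_y,phi_z``) with an optional YAML sidecar
carrying environment metadata (name, domain, C-arm distance, gantry angle).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

CHANNELS = ("x", "y", "z", "q", "phi_x", "phi_y", "phi_z")
ANGLE_CHANNELS = (4, 5, 6)
CSV_COLUMNS = ("node_id",) + CHANNELS


def wrap_angle(theta):
    """Wrap angle(s) in degrees to the interval [-180, 180)."""
    return (np.asarray(theta, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class EMTSample:
    """One averaged EMT measuring point."""

    x: float
    y: float
    z: float
    q: float
    phi_x: float
    phi_y: float
    phi_z: float

    def __post_init__(self):
        vec = self.as_array()
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"EMTSample components must be finite, got {vec}")
        for name, idx in zip(("phi_x", "phi_y", "phi_z"), ANGLE_CHANNELS):
            object.__setattr__(self, name, float(wrap_angle(vec[idx])))

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.x, self.y, self.z, self.q, self.phi_x, self.phi_y, self.phi_z]
        )

    @classmethod
    def from_array(cls, vec: Sequence[float]) -> "EMTSample":
        return cls(*(float(v) for v in vec))

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class GroundTruthGrid:
    """Calibrated lattice of measuring points (a pegboard at several elevations).

    Node ids enumerate the lattice in row-major order: layer by layer, then
    row (y), then column (x).  Pairwise distances between nodes follow in
    closed form from the integer lattice indices, which is what makes the
    displacement metric self-calibrating.
    """

    pitch: float
    nx: int
    ny: int
    layer_elevations: tuple[float, ...]
    layer_mask: tuple[bool, ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.pitch <= 0:
            raise ValueError(f"grid pitch must be positive, got {self.pitch}")
        if self.nx * self.ny * len(self.layer_elevations) < 2:
            raise ValueError("grid must contain at least 2 nodes")
        object.__setattr__(self, "layer_elevations", tuple(float(z) for z in self.layer_elevations))
        if self.layer_mask is None:
            object.__setattr__(self, "layer_mask", (True,) * len(self.layer_elevations))
        elif len(self.layer_mask) != len(self.layer_elevations):
            raise ValueError("layer_mask length must match layer_elevations")

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny * len(self.layer_elevations)

    @property
    def node_ijk(self) -> np.ndarray:
        """(n, 3) integer lattice indices (i along x, j along y, k the layer)."""
        k, j, i = np.meshgrid(
            np.arange(len(self.layer_elevations)),
            np.arange(self.ny),
            np.arange(self.nx),
            indexing="ij",
        )
        return np.column_stack([i.ravel(), j.ravel(), k.ravel()])

    @property
    def node_positions(self) -> np.ndarray:
        ijk = self.node_ijk
        z = np.asarray(self.layer_elevations)[ijk[:, 2]]
        return np.column_stack([ijk[:, 0] * self.pitch, ijk[:, 1] * self.pitch, z])

    def node_distance(self, node_i, node_j) -> np.ndarray:
        """Closed-form lattice distance between node ids (vectorized)."""
        ijk = self.node_ijk
        elev = np.asarray(self.layer_elevations)
        a, b = ijk[np.asarray(node_i)], ijk[np.asarray(node_j)]
        dx = (a[..., 0] - b[..., 0]) * self.pitch
        dy = (a[..., 1] - b[..., 1]) * self.pitch
        dz = elev[a[..., 2]] - elev[b[..., 2]]
        return np.sqrt(dx * dx + dy * dy + dz * dz)

    def active_node_ids(self, layer_mask: Sequence[bool] | None = None) -> np.ndarray:
        mask = np.asarray(self.layer_mask if layer_mask is None else layer_mask)
        return np.flatnonzero(mask[self.node_ijk[:, 2]])


@dataclass
class EnvironmentDataset:
    """A named set of EMT samples mapped to ground-truth grid nodes.

    ``values`` is an (n, 7) array in channel order ``CHANNELS``;
    ``node_index`` gives the grid node id of each sample.  Laboratory
    (domain ``L``) datasets carry no C-arm distance.
    """

    name: str
    domain: str
    values: np.ndarray
    node_index: np.ndarray
    c_arm_distance_cm: float | None = None
    gantry_angle_deg: float | None = None

    def __post_init__(self):
        if self.domain not in ("C", "L"):
            raise ValueError(f"domain must be 'C' or 'L', got {self.domain!r}")
        self.values = np.asarray(self.values, dtype=float).reshape(-1, 7)
        self.node_index = np.asarray(self.node_index, dtype=int).reshape(-1)
        if len(self.node_index) != len(self.values):
            raise ValueError("node_index and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"dataset {self.name!r} contains non-finite values")
        if self.domain == "L" and self.c_arm_distance_cm is not None:
            raise ValueError("laboratory datasets carry no C-arm distance")
        self.values[:, ANGLE_CHANNELS] = wrap_angle(self.values[:, ANGLE_CHANNELS])

    def __len__(self) -> int:
        return len(self.values)

    @property
    def samples(self) -> list[EMTSample]:
        return [EMTSample.from_array(v) for v in self.values]

    @property
    def positions(self) -> np.ndarray:
        return self.values[:, :3]

    def with_values(self, values: np.ndarray) -> "EnvironmentDataset":
        return replace(self, values=np.array(values, dtype=float))


@dataclass(frozen=True)
class NormalizationBounds:
    """Per-channel min/max mapping the 7 channels onto the unit interval.

    Out-of-range inputs are mapped linearly past [0, 1] rather than clamped:
    clamping would silently destroy positional information when a trained
    model is applied in an unseen environment.
    """

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.minimum, dtype=float).reshape(7)
        hi = np.asarray(self.maximum, dtype=float).reshape(7)
        object.__setattr__(self, "minimum", lo)
        object.__setattr__(self, "maximum", hi)
        bad = np.flatnonzero(hi <= lo)
        if bad.size:
            names = ", ".join(CHANNELS[i] for i in bad)
            raise ValueError(f"degenerate normalization channel(s): {names}")

    @property
    def span(self) -> np.ndarray:
        return self.maximum - self.minimum

    def normalize(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("cannot normalize non-finite values")
        return (values - self.minimum) / self.span

    def denormalize(self, unit_values: np.ndarray) -> np.ndarray:
        return np.asarray(unit_values, dtype=float) * self.span + self.minimum

    def to_dict(self) -> dict:
        return {"minimum": self.minimum.tolist(), "maximum": self.maximum.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationBounds":
        return cls(np.asarray(d["minimum"]), np.asarray(d["maximum"]))


def fit_normalization(datasets: Iterable[EnvironmentDataset]) -> NormalizationBounds:
    """Fit unit-interval bounds on the union of all samples in `datasets`.

    Bounds are fitted globally (both domains together) and stored with the
    trained model pair so that inference on unseen environments reuses the
    training-time scaling.
    """
    datasets = list(datasets)
    if not datasets or all(len(d) == 0 for d in datasets):
        raise ValueError("fit_normalization requires at least one sample")
    stacked = np.vstack([d.values for d in datasets if len(d)])
    return NormalizationBounds(stacked.min(axis=0), stacked.max(axis=0))


def normalize_sample(sample: EMTSample, bounds: NormalizationBounds) -> np.ndarray:
    return bounds.normalize(sample.as_array())


def denormalize_sample(vec: np.ndarray, bounds: NormalizationBounds) -> EMTSample:
    return EMTSample.from_array(bounds.denormalize(vec))


# -- CSV / sidecar I/O ---------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_dataset(dataset: EnvironmentDataset, path) -> None:
    path = Path(path)
    df = pd.DataFrame(dataset.values, columns=list(CHANNELS))
    df.insert(0, "node_id", dataset.node_index)
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {
        "name": dataset.name,
        "domain": dataset.domain,
        "c_arm_distance_cm": dataset.c_arm_distance_cm,
        "gantry_angle_deg": dataset.gantry_angle_deg,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta), encoding="utf-8")


def read_dataset(path, name: str | None = None, domain: str | None = None) -> EnvironmentDataset:
    """Read an environment dataset from CSV (+ YAML sidecar if present)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df = df[list(CSV_COLUMNS)]
    numeric = df.apply(pd.to_numeric, errors="coerce").astype(float)
    bad = numeric.isna() | ~np.isfinite(numeric)
    if len(df) and bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.loc[row][bad.loc[row]].index[0]
        raise ValueError(
            f"{path}: non-numeric or non-finite value in row {row}, column {col!r}"
        )
    meta = {"name": path.stem, "domain": "C", "c_arm_distance_cm": None, "gantry_angle_deg": None}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta.update(yaml.safe_load(sidecar.read_text(encoding="utf-8")) or {})
    if name is not None:
        meta["name"] = name
    if domain is not None:
        meta["domain"] = domain
    return EnvironmentDataset(
        name=meta["name"],
        domain=meta["domain"],
        values=numeric[list(CHANNELS)].to_numpy(),
        node_index=numeric["node_id"].to_numpy().astype(int),
        c_arm_distance_cm=meta.get("c_arm_distance_cm"),
        gantry_angle_deg=meta.get("gantry_angle_deg"),
    )
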
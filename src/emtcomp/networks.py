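"""Generators and discriminators for the two-way domain translation.

Two generators translate 7-channel points between the C-arm (C) and
laboratory (L) domains: ``G_CL`` maps C -> L and, once trained, performs
compensation; ``G_LC`` maps L -> C and exists to close the consistency
cycle.  Each receives the full normalized point ``(x, y, z, q, phi_x,
phi_y, phi_z)`` and outputs the five channels it may alter: ``(z_hat,
q_hat, phi_x_hat, phi_y_hat, phi_z_hat)``.  The positional x and y
components pass through untouched by construction — this is a structural
property of the compensation wrapper, not something the networks learn —
which keeps the translation from moving points to arbitrary places in the
target domain.

The discriminators ``D_CL`` / ``D_LC`` judge whether a full 7-channel point
looks like a genuine member of the corresponding target domain; their
sigmoid head keeps outputs strictly inside (0, 1).

Architectures (dense stacks, widths fixed):
  generator:      7 -> 16 -> 16 -> 16 -> 5, leaky rectifier (slope 0.01),
                  linear head;
  discriminator:  7 -> 16 -> 16 -> 1, leaky rectifier (slope 0.2),
                  sigmoid head.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, affine, concat
from .datamodel import (ANGLE_CHANNELS, EMTSample, EnvironmentDataset,
                        NormalizationBounds, wrap_angle)

GEN_SIZES = (7, 16, 16, 16, 5)
DISC_SIZES = (7, 16, 16, 1)
GEN_SLOPE = 0.01
DISC_SLOPE = 0.2


@dataclass(frozen=True)
class GeneratorSpec:
    sizes: tuple[int, ...] = GEN_SIZES
    hidden_slope: float = GEN_SLOPE
    final_activation: str = "linear"


@dataclass(frozen=True)
class DiscriminatorSpec:
    sizes: tuple[int, ...] = DISC_SIZES
    hidden_slope: float = DISC_SLOPE
    final_activation: str = "sigmoid"


class DenseNet:
    """A seeded fully connected stack over the autodiff core.

    Weights and biases are initialized uniformly on
    ``[-1/sqrt(fan_in), 1/sqrt(fan_in)]`` per layer (the conventional
    default for dense layers), drawn from a ``numpy`` generator so that the
    same seed always yields the same parameters.
    """

    def __init__(self, sizes, hidden_slope, final_activation, seed):
        self.sizes = tuple(int(s) for s in sizes)
        self.hidden_slope = float(hidden_slope)
        if final_activation not in ("linear", "sigmoid"):
            raise ValueError(f"unknown final activation {final_activation!r}")
        self.final_activation = final_activation
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for n_in, n_out in zip(self.sizes[:-1], self.sizes[1:]):
            bound = 1.0 / np.sqrt(n_in)
            self.weights.append(Tensor(rng.uniform(-bound, bound, (n_in, n_out)),
                                       requires_grad=True))
            self.biases.append(Tensor(rng.uniform(-bound, bound, n_out),
                                      requires_grad=True))

    @property
    def parameters(self) -> list[Tensor]:
        return self.weights + self.biases

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters)

    def forward(self, x, logits: bool = False) -> Tensor:
        """Forward pass; ``logits=True`` returns the pre-sigmoid head output
        (training uses it for a numerically stable cross-entropy)."""
        h = x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x))
        if h.data.ndim != 2 or h.data.shape[1] != self.sizes[0]:
            raise ValueError(
                f"expected input of width {self.sizes[0]}, got shape {h.data.shape}")
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = affine(h, W, b)
            if i < last:
                h = h.leaky_relu(self.hidden_slope)
        if logits:
            if self.final_activation != "sigmoid":
                raise ValueError("logits output requires a sigmoid head")
            return h
        if self.final_activation == "sigmoid":
            h = h.sigmoid()
        return h

    def __call__(self, x) -> Tensor:
        return self.forward(x)

    def state(self) -> dict:
        return {
            "sizes": list(self.sizes),
            "hidden_slope": self.hidden_slope,
            "final_activation": self.final_activation,
            "seed": self.seed,
            "weights": [w.data.tolist() for w in self.weights],
            "biases": [b.data.tolist() for b in self.biases],
        }

    @classmethod
    def from_state(cls, state: dict) -> "DenseNet":
        net = cls(state["sizes"], state["hidden_slope"],
                  state["final_activation"], state["seed"])
        for w, data in zip(net.weights, state["weights"]):
            w.data = np.asarray(data, dtype=np.float64)
        for b, data in zip(net.biases, state["biases"]):
            b.data = np.asarray(data, dtype=np.float64)
        return net


def build_generator(seed: int, spec: GeneratorSpec = GeneratorSpec()) -> DenseNet:
    return DenseNet(spec.sizes, spec.hidden_slope, spec.final_activation, seed)


def build_discriminator(seed: int, spec: DiscriminatorSpec = DiscriminatorSpec()) -> DenseNet:
    return DenseNet(spec.sizes, spec.hidden_slope, spec.final_activation, seed)


@dataclass
class ModelPair:
    """The four trained networks plus the normalization they were trained under."""

    G_CL: DenseNet
    G_LC: DenseNet
    D_CL: DenseNet
    D_LC: DenseNet
    bounds: NormalizationBounds
    seed: int = 0

    @classmethod
    def initialize(cls, bounds: NormalizationBounds, seed: int) -> "ModelPair":
        ss = np.random.SeedSequence(seed).generate_state(4) % (2**31)
        return cls(G_CL=build_generator(int(ss[0])),
                   G_LC=build_generator(int(ss[1])),
                   D_CL=build_discriminator(int(ss[2])),
                   D_LC=build_discriminator(int(ss[3])),
                   bounds=bounds, seed=int(seed))

    def translate(self, generator: DenseNet, x_norm: Tensor) -> Tensor:
        """Full 7-channel translated point: x, y passed through, rest generated."""
        out5 = generator(x_norm)
        return concat([x_norm[:, 0:2], out5], axis=1)

    # -- inference ---------------------------------------------------------

    def compensate_values(self, values: np.ndarray) -> np.ndarray:
        """Translate raw (n, 7) C-domain values into the laboratory domain.

        x and y are copied bit-exactly from the input; z, q and orientation
        come from ``G_CL``, denormalized back to physical units.
        """
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if not np.all(np.isfinite(values)):
            raise ValueError("cannot compensate non-finite input")
        x_norm = self.bounds.normalize(values)
        out5 = self.G_CL(Tensor(x_norm)).data
        full = np.column_stack([x_norm[:, 0:2], out5])
        out = self.bounds.denormalize(full)
        out[:, 0:2] = values[:, 0:2]  # structural pass-through, bit-exact
        out[:, ANGLE_CHANNELS] = wrap_angle(out[:, ANGLE_CHANNELS])
        return out

    def compensate_dataset(self, dataset: EnvironmentDataset) -> EnvironmentDataset:
        out = dataset.with_values(self.compensate_values(dataset.values))
        out.domain = "L"
        out.c_arm_distance_cm = None
        out.name = dataset.name + "_compensated"
        return out

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        state = {
            "G_CL": self.G_CL.state(), "G_LC": self.G_LC.state(),
            "D_CL": self.D_CL.state(), "D_LC": self.D_LC.state(),
            "bounds": self.bounds.to_dict(), "seed": self.seed,
        }
        blob = json.dumps(state, sort_keys=True)
        state["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
        path.write_text(json.dumps(state), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "ModelPair":
        state = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(G_CL=DenseNet.from_state(state["G_CL"]),
                   G_LC=DenseNet.from_state(state["G_LC"]),
                   D_CL=DenseNet.from_state(state["D_CL"]),
                   D_LC=DenseNet.from_state(state["D_LC"]),
                   bounds=NormalizationBounds.from_dict(state["bounds"]),
                   seed=state["seed"])


def compensate_point(pair: ModelPair, sample: EMTSample) -> EMTSample:
    """Translate a single C-domain measuring point to the laboratory domain."""
    out = pair.compensate_values(sample.as_array()[None, :])[0]
    out_sample = EMTSample.from_array(out)
    # enforce the bit-exact pass-through even through dataclass round-trip
    object.__setattr__(out_sample, "x", sample.x)
    object.__setattr__(out_sample, "y", sample.y)
    return out_sample
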
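"""Linear fine-tuning of residual x-y error in the laboratory domain.

The domain translation replaces z, quality and orientation but passes x and
y through untouched, so positional error in the x-y plane survives it.
Because translated points always lie in the laboratory domain, a corrector
fitted on laboratory data applies to them as well.  The corrector is a
linear regression with input features ``(x, y, z, q)`` predicting additive
offsets ``(dx, dy)`` in mm toward grid-anchored targets.

Fitting the offsets against absolute grid targets (rather than only against
inter-point distances) is a deliberate interpretation: distance-only
fitting is under-determined up to a rigid motion of the whole point set.
No separate rigid pre-alignment is needed — a rigid 2-D transform is affine
in (x, y), and the regression design (x, y plus intercept) already spans
every affine x-y map, so ordinary least squares absorbs any global pose
offset along with the linear warp.  Two independent least-squares fits
(for dx and dy) share the 4-feature design; the fit is closed-form and
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datamodel import EnvironmentDataset, GroundTruthGrid
from .trainer import CompensationResult
from .metrics import prediction_spread

FEATURES = ("x", "y", "z", "q")


@dataclass(frozen=True)
class LinearCompensator:
    """Affine map from features (x, y, z, q) to corrective x-y offsets (mm)."""

    coefficients: np.ndarray  # (2, 4): rows dx, dy; columns x, y, z, q
    intercepts: np.ndarray    # (2,)
    residual_rmse: float      # planar residual on the fitted set, mm

    def __post_init__(self):
        object.__setattr__(self, "coefficients",
                           np.asarray(self.coefficients, dtype=float).reshape(2, 4))
        object.__setattr__(self, "intercepts",
                           np.asarray(self.intercepts, dtype=float).reshape(2))

    @classmethod
    def zero(cls) -> "LinearCompensator":
        return cls(np.zeros((2, 4)), np.zeros(2), 0.0)

    def offsets(self, values: np.ndarray) -> np.ndarray:
        """Corrective (dx, dy) for (n, 7) channel values."""
        feats = np.atleast_2d(values)[:, :4]
        return feats @ self.coefficients.T + self.intercepts

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "features": list(FEATURES),
            "coefficients": self.coefficients.tolist(),
            "intercepts": self.intercepts.tolist(),
            "residual_rmse": self.residual_rmse,
        }), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "LinearCompensator":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(np.asarray(d["coefficients"]), np.asarray(d["intercepts"]),
                   float(d["residual_rmse"]))


def fit_linear_compensator(dataset: EnvironmentDataset,
                           grid: GroundTruthGrid) -> LinearCompensator:
    """Least-squares fit of x-y offsets toward the dataset's grid nodes.

    `dataset` is laboratory-domain data (typically already domain-translated),
    each sample mapped to a grid node supplying its target (x, y).
    Raises on fewer points than features + 1 or a rank-deficient design.
    """
    n_min = len(FEATURES) + 1
    if len(dataset) < n_min:
        raise ValueError(f"need at least {n_min} points to fit, got {len(dataset)}")
    design = np.column_stack([dataset.values[:, :4], np.ones(len(dataset))])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify which columns are linearly dependent on the others
        names = list(FEATURES) + ["intercept"]
        degenerate = [names[i] for i in range(design.shape[1])
                      if np.linalg.matrix_rank(np.delete(design, i, axis=1)) == rank]
        raise ValueError(
            "rank-deficient regression design (columns "
            f"{degenerate} are linearly dependent)")
    targets = grid.node_positions[dataset.node_index][:, :2]
    offsets = targets - dataset.values[:, :2]
    beta, *_ = np.linalg.lstsq(design, offsets, rcond=None)
    residual = offsets - design @ beta
    rmse = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return LinearCompensator(coefficients=beta[:4].T, intercepts=beta[4],
                             residual_rmse=rmse)


def apply_compensator(model: LinearCompensator, values: np.ndarray) -> np.ndarray:
    """Shift x and y of (n, 7) channel values by the model's offsets."""
    out = np.atleast_2d(np.asarray(values, dtype=float)).copy()
    out[:, :2] += model.offsets(out)
    return out


def apply_finetune(model: LinearCompensator,
                   result: CompensationResult) -> CompensationResult:
    """Apply the x-y corrector to an ensemble compensation result.

    Only x and y change; z, q and orientation are untouched.  The corrector
    is applied to the ensemble mean and to every member, and the predictive
    spread is recomputed so it reflects the fine-tuned positions (with one
    shared corrector the x-y spread across members stays zero; per-member
    correctors — see :func:`finetune_ensemble` — contribute additional
    spread).
    """
    models = [model] * len(result.member_values)
    return _apply_models(models, model, result)


def finetune_ensemble(members_lab: list[EnvironmentDataset],
                      grid: GroundTruthGrid,
                      result: CompensationResult) -> tuple[list[LinearCompensator],
                                                           CompensationResult]:
    """Fit one corrector per ensemble member and apply it member-wise.

    `members_lab` holds each member's compensated laboratory dataset.  The
    member-wise correctors make the fine-tuning stage itself a source of
    predictive uncertainty, which the recomputed spread accounts for; the
    mean output uses the average corrector.
    """
    models = [fit_linear_compensator(d, grid) for d in members_lab]
    mean_model = LinearCompensator(
        np.mean([m.coefficients for m in models], axis=0),
        np.mean([m.intercepts for m in models], axis=0),
        float(np.mean([m.residual_rmse for m in models])))
    return models, _apply_models(models, mean_model, result)


def _apply_models(models: list[LinearCompensator], mean_model: LinearCompensator,
                  result: CompensationResult) -> CompensationResult:
    member_values = np.stack([
        apply_compensator(m, vals)
        for m, vals in zip(models, result.member_values)])
    mean_values = apply_compensator(mean_model, result.dataset.values)
    if len(member_values) >= 2:
        sigma_per_point, sigma = prediction_spread(member_values)
    else:
        sigma_per_point = np.zeros(len(mean_values))
        sigma = 0.0
    return CompensationResult(dataset=result.dataset.with_values(mean_values),
                              member_values=member_values,
                              sigma_per_point=sigma_per_point, sigma_pred=sigma)
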
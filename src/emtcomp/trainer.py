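"""Cycle-consistent adversarial training for EMT error compensation.

Two generator/discriminator pairs are trained on *unpaired* batches from the
C-arm (C) and laboratory (L) domains.  The generator objective is a weighted
sum of three terms:

* adversarial loss ``L_adv`` — binary cross-entropy reflecting how well each
  generator fools its discriminator,
  ``BCE(D_CL(G_CL(x_C)), l_valid) + BCE(D_LC(G_LC(x_L)), l_valid)``;
* cycle loss ``L_cycle = L_recov_L + L_recov_C`` — L1 recovery residual of
  the round trips L->C->L and C->L->C, which regularizes the otherwise
  under-constrained unpaired translation;
* compensation loss ``L_comp = MSE(d_G_CL, d_true)`` — squared error between
  pairwise distances of compensated points (in mm) and the known lattice
  distances, penalized only in the laboratory domain.

``L_total = lambda_adv * L_adv + lambda_cycle * L_cycle + lambda_comp *
L_comp`` with default weights 0.5, 10 and 1e-5.  Discriminators train with
soft labels (valid ~ U[0.8, 1.0], fake ~ U[0.0, 0.2]) on real samples and
gradient-detached generated samples, each with its own Adam optimizer, while
the two generators share one.  The learning rate is constant for the first
100 epochs and then decays linearly to zero at epoch 200.

Epistemic uncertainty comes from a deep ensemble: the same architecture is
trained from several random initializations (10 by default) and the spread
of the compensated positions across members approximates the model
uncertainty ``sigma_pred``, while their average is the compensated output.

``mode="vanilla_gan"`` drops the cycle term (an ablation); the compensation
path then reduces to a single adversarially trained generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import circmean

from ._autodiff import Adam, Tensor
from .datamodel import (ANGLE_CHANNELS, EnvironmentDataset, GroundTruthGrid,
                        NormalizationBounds, fit_normalization, wrap_angle)
from .metrics import prediction_spread
from .networks import DenseNet, ModelPair

_EPS = 1e-12  # BCE clipping


@dataclass(frozen=True)
class TrainConfig:
    lambda_adv: float = 0.5
    lambda_cycle: float = 10.0
    lambda_comp: float = 1e-5
    lr: float = 0.0005
    decay_start_epoch: int = 100
    total_epochs: int = 200
    batch_size: int = 16
    ensemble_size: int = 10
    soft_label_valid: tuple[float, float] = (0.8, 1.0)
    soft_label_fake: tuple[float, float] = (0.0, 0.2)
    mode: str = "cyclegan"
    seed: int = 0
    # Identity regularization from the original cycle-consistent recipe:
    # target-domain samples fed through a generator must come back
    # unchanged, |G_CL(x_L) - x_L| + |G_LC(x_C) - x_C|, customarily
    # weighted at half the cycle weight.  It anchors the absolute scale
    # and offset of the translated channels, which the adversarial and
    # cycle terms alone leave unconstrained.  Dropped in vanilla_gan mode
    # together with the cycle term.
    lambda_identity: float = 5.0
    # Historical-averaging regularization (from the same stabilization
    # toolbox as the soft labels): each player is penalized by
    # lambda_hist * ||theta - theta_hist||^2 toward an exponential moving
    # average of its own parameters, damping the generator/discriminator
    # oscillation that otherwise dominates at this data scale.
    lambda_hist: float = 0.3
    hist_decay: float = 0.99
    # Model selection: keep the generator weights from the epoch with the
    # lowest mean displacement RMSE on the validation environments (the
    # split reserves C-arm environments for exactly this purpose).  Without
    # validation data the final-epoch weights are kept.
    select_on_validation: bool = True

    def __post_init__(self):
        if min(self.lambda_adv, self.lambda_cycle, self.lambda_comp) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 <= self.decay_start_epoch < self.total_epochs:
            raise ValueError("decay_start_epoch must lie inside [0, total_epochs)")
        if self.mode not in ("cyclegan", "vanilla_gan"):
            raise ValueError(f"unknown training mode {self.mode!r}")


@dataclass(frozen=True)
class LossBreakdown:
    """Per-step (or per-epoch mean) generator loss components."""

    L_adv: float
    L_recov_L: float
    L_recov_C: float
    L_cycle: float
    L_comp: float
    L_total: float


def lr_schedule(cfg: TrainConfig, epoch: int) -> float:
    """Constant lr until `decay_start_epoch`, then linear to 0 at `total_epochs`."""
    if epoch < cfg.decay_start_epoch:
        return cfg.lr
    remaining = cfg.total_epochs - epoch
    return cfg.lr * remaining / (cfg.total_epochs - cfg.decay_start_epoch)


def bce(pred: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of sigmoid outputs against (soft) labels."""
    p = pred.clip(_EPS, 1.0 - _EPS)
    labels = np.asarray(labels, dtype=float).reshape(pred.data.shape)
    return -((p.log() * labels + (1.0 - p).log() * (1.0 - labels)).mean())


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean BCE computed from pre-sigmoid logits.

    ``BCE(sigmoid(s), l) = softplus(s) - l*s``; the gradient with respect
    to the logit is ``sigmoid(s) - l``, which never vanishes when the
    discriminator saturates — the probability-space form loses that
    gradient to rounding once ``sigmoid(s)`` underflows.
    """
    labels = np.asarray(labels, dtype=float).reshape(logits.data.shape)
    return (logits.softplus() - logits * labels).mean()


def adversarial_loss(batch_C: np.ndarray, batch_L: np.ndarray, pair: ModelPair,
                     label_valid_C: np.ndarray, label_valid_L: np.ndarray) -> Tensor:
    """How well each generator fools its discriminator (sum of two BCE terms).

    Batches are normalized 7-channel arrays; labels are the per-sample soft
    valid labels the generators try to elicit.
    """
    if len(batch_C) == 0 or len(batch_L) == 0:
        raise ValueError("adversarial loss requires nonempty batches")
    fake_L = pair.translate(pair.G_CL, Tensor(batch_C))
    fake_C = pair.translate(pair.G_LC, Tensor(batch_L))
    return (bce_with_logits(pair.D_CL.forward(fake_L, logits=True), label_valid_C)
            + bce_with_logits(pair.D_LC.forward(fake_C, logits=True), label_valid_L))


def cycle_loss(batch_C: np.ndarray, batch_L: np.ndarray,
               pair: ModelPair) -> tuple[Tensor, Tensor, Tensor]:
    """L1 recovery residuals of the two round trips, averaged over batch and channels.

    Returns ``(L_recov_L, L_recov_C, L_cycle)`` where the cycle loss is the
    sum of the two recovery terms.  The passed-through x and y channels are
    recovered exactly by construction and contribute zero residual.
    """
    if len(batch_C) == 0 or len(batch_L) == 0:
        raise ValueError("cycle loss requires nonempty batches")
    xC, xL = Tensor(batch_C), Tensor(batch_L)
    rec_L = pair.translate(pair.G_CL, pair.translate(pair.G_LC, xL))
    rec_C = pair.translate(pair.G_LC, pair.translate(pair.G_CL, xC))
    L_recov_L = (rec_L - xL).abs().mean()
    L_recov_C = (rec_C - xC).abs().mean()
    return L_recov_L, L_recov_C, L_recov_L + L_recov_C


def compensation_loss(batch_C_mm: np.ndarray, node_ids: np.ndarray,
                      pair: ModelPair, grid: GroundTruthGrid) -> Tensor:
    """MSE between compensated pairwise distances and lattice truth (mm^2).

    The batch is arranged as consecutive sample pairs (rows 0-1, 2-3, ...),
    each pair joining two distinct grid nodes so the true lattice distance
    is defined.  Distances are computed on the denormalized compensated
    positions: pass-through x, y in mm plus the generated z.
    """
    batch_C_mm = np.atleast_2d(batch_C_mm)
    if len(batch_C_mm) < 2:
        raise ValueError("compensation loss requires at least one sample pair")
    if len(batch_C_mm) % 2:
        raise ValueError("compensation batch must contain whole pairs")
    node_ids = np.asarray(node_ids, dtype=int)
    d_true = grid.node_distance(node_ids[0::2], node_ids[1::2])
    x_norm = pair.bounds.normalize(batch_C_mm)
    out5 = pair.G_CL(Tensor(x_norm))
    z_mm = out5[:, 0:1] * pair.bounds.span[2] + pair.bounds.minimum[2]
    dz = z_mm[0::2, :] - z_mm[1::2, :]
    dxy = batch_C_mm[0::2, 0:2] - batch_C_mm[1::2, 0:2]
    d2 = (dz * dz)[:, 0] + Tensor((dxy**2).sum(axis=1))
    d = d2.sqrt()
    diff = d - Tensor(d_true)
    return (diff * diff).mean()


def total_generator_loss(parts: dict, cfg: TrainConfig):
    """Weighted sum of the generator loss terms; cycle excluded in vanilla mode."""
    lam_cycle = 0.0 if cfg.mode == "vanilla_gan" else cfg.lambda_cycle
    return (cfg.lambda_adv * parts["L_adv"] + lam_cycle * parts["L_cycle"]
            + cfg.lambda_comp * parts["L_comp"])


def discriminator_step(disc: DenseNet, opt: Adam, real: np.ndarray,
                       fake: np.ndarray, label_valid: np.ndarray,
                       label_fake: np.ndarray,
                       hist: "_HistoricalAverage | None" = None) -> float:
    """One update of a single discriminator on real vs generated samples.

    `fake` must already be detached (a plain array), so no generator
    parameter receives gradient from this step.
    """
    if len(real) == 0 or len(fake) == 0:
        raise ValueError("discriminator step requires nonempty batches")
    opt.zero_grad()
    loss = (bce_with_logits(disc.forward(Tensor(real), logits=True), label_valid)
            + bce_with_logits(disc.forward(Tensor(fake), logits=True), label_fake))
    loss.backward()
    if hist is not None:
        hist.add_gradient()
    opt.step()
    if hist is not None:
        hist.update()
    return loss.item()


class _HistoricalAverage:
    """Historical-averaging regularizer for one player's parameters."""

    def __init__(self, params, lam: float, decay: float):
        self.params = list(params)
        self.lam = lam
        self.decay = decay
        self.avg = [p.data.copy() for p in self.params]

    def add_gradient(self) -> None:
        if self.lam <= 0:
            return
        for p, a in zip(self.params, self.avg):
            if p.grad is None:
                p.grad = np.zeros_like(p.data)
            p.grad += 2.0 * self.lam * (p.data - a)

    def update(self) -> None:
        for p, a in zip(self.params, self.avg):
            a *= self.decay
            a += (1.0 - self.decay) * p.data


class FakeBuffer:
    """History buffer of generated samples for discriminator updates.

    Following the customary cycle-consistent training recipe, discriminators
    are shown a mix of fresh and previously generated samples: each new fake
    is swapped with a stored one with probability 1/2 once the buffer (50
    samples) is full.  This damps the generator-discriminator chase that
    otherwise leaves the translated distribution oscillating around the
    target domain.
    """

    def __init__(self, rng: np.random.Generator, capacity: int = 50):
        self.rng = rng
        self.capacity = capacity
        self.store: list[np.ndarray] = []

    def sample(self, fakes: np.ndarray) -> np.ndarray:
        out = []
        for row in fakes:
            if len(self.store) < self.capacity:
                self.store.append(row)
                out.append(row)
            elif self.rng.random() < 0.5:
                k = self.rng.integers(0, self.capacity)
                out.append(self.store[k])
                self.store[k] = row
            else:
                out.append(row)
        return np.asarray(out)


def _neighbor_pairs(datasets: list[EnvironmentDataset], grid: GroundTruthGrid,
                    offsets: list[int]) -> np.ndarray:
    """Global-index sample pairs joining lattice-adjacent nodes, per dataset."""
    pairs = []
    for ds, off in zip(datasets, offsets):
        ijk = grid.node_ijk[ds.node_index]
        ii, jj = np.triu_indices(len(ds), k=1)
        keep = np.abs(ijk[ii] - ijk[jj]).sum(axis=1) == 1
        pairs.append(np.column_stack([ii[keep] + off, jj[keep] + off]))
    out = np.vstack(pairs)
    if len(out) == 0:
        raise ValueError("no lattice-neighbor pairs available for training")
    return out


def train(cfg: TrainConfig, data_C: list[EnvironmentDataset],
          data_L: list[EnvironmentDataset], grid: GroundTruthGrid,
          bounds: NormalizationBounds | None = None,
          data_val: list[EnvironmentDataset] | None = None,
          record: str = "epoch") -> tuple[ModelPair, list[LossBreakdown]]:
    """Train one generator/discriminator quartet; fully seeded.

    Returns the trained ``ModelPair`` and the loss log (per epoch by
    default, per step with ``record="step"``).  Minibatches are drawn
    independently from each domain (unpaired); C-domain batches are sampled
    as lattice-neighbor sample pairs so the compensation loss has defined
    ground-truth distances.

    When `data_val` is given (held-out C-arm environments) and
    ``cfg.select_on_validation`` is set, the generators returned are those
    of the epoch with the lowest mean validation displacement RMSE — the
    adversarial game keeps orbiting its equilibrium even when damped, and
    the self-calibrating displacement metric identifies the best visit.
    """
    from .metrics import evaluate_dataset  # local import avoids cycle at module load

    if not data_C or not data_L:
        raise ValueError("need at least one dataset per domain")
    if bounds is None:
        bounds = fit_normalization(list(data_C) + list(data_L))
    pair = ModelPair.initialize(bounds, cfg.seed)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 4242]).generate_state(1)[0])

    C_vals = np.vstack([d.values for d in data_C])
    C_nodes = np.concatenate([d.node_index for d in data_C])
    offsets = np.cumsum([0] + [len(d) for d in data_C])[:-1].tolist()
    cpairs = _neighbor_pairs(list(data_C), grid, offsets)
    L_vals = np.vstack([d.values for d in data_L])
    C_norm_all = bounds.normalize(C_vals)
    L_norm_all = bounds.normalize(L_vals)

    gen_params = pair.G_CL.parameters + pair.G_LC.parameters
    gen_opt = Adam(gen_params, cfg.lr)
    d_opt_CL = Adam(pair.D_CL.parameters, cfg.lr)
    d_opt_LC = Adam(pair.D_LC.parameters, cfg.lr)
    all_params = gen_params + pair.D_CL.parameters + pair.D_LC.parameters
    gen_hist = _HistoricalAverage(gen_params, cfg.lambda_hist, cfg.hist_decay)
    d_hist_CL = _HistoricalAverage(pair.D_CL.parameters, cfg.lambda_hist, cfg.hist_decay)
    d_hist_LC = _HistoricalAverage(pair.D_LC.parameters, cfg.lambda_hist, cfg.hist_decay)

    steps_per_epoch = math.ceil(max(len(C_vals), len(L_vals)) / cfg.batch_size)
    n_batch_pairs = max(1, cfg.batch_size // 2)
    buffer_L = FakeBuffer(rng)
    buffer_C = FakeBuffer(rng)
    lo_v, hi_v = cfg.soft_label_valid
    lo_f, hi_f = cfg.soft_label_fake
    log: list[LossBreakdown] = []
    best_val = np.inf
    best_weights: list[np.ndarray] | None = None

    for epoch in range(cfg.total_epochs):
        lr = lr_schedule(cfg, epoch)
        gen_opt.lr = d_opt_CL.lr = d_opt_LC.lr = lr
        epoch_parts = np.zeros(4)  # adv, recovL, recovC, comp
        for _ in range(steps_per_epoch):
            sel = cpairs[rng.integers(0, len(cpairs), n_batch_pairs)]
            idx_C = sel.reshape(-1)
            idx_L = rng.integers(0, len(L_vals), cfg.batch_size)
            batch_C, batch_L = C_norm_all[idx_C], L_norm_all[idx_L]

            # -- generator update (shared optimizer) -----------------------
            lv_C = rng.uniform(lo_v, hi_v, (len(idx_C), 1))
            lv_L = rng.uniform(lo_v, hi_v, (len(idx_L), 1))
            for p in all_params:
                p.grad = None
            L_adv = adversarial_loss(batch_C, batch_L, pair, lv_C, lv_L)
            if cfg.mode == "vanilla_gan":
                L_recov_L = L_recov_C = L_cycle = Tensor(0.0)
            else:
                L_recov_L, L_recov_C, L_cycle = cycle_loss(batch_C, batch_L, pair)
            L_comp = compensation_loss(C_vals[idx_C], C_nodes[idx_C], pair, grid)
            parts = {"L_adv": L_adv, "L_cycle": L_cycle, "L_comp": L_comp}
            L_total = total_generator_loss(parts, cfg)
            if cfg.lambda_identity > 0 and cfg.mode != "vanilla_gan":
                xC_t, xL_t = Tensor(batch_C), Tensor(batch_L)
                L_idt = ((pair.translate(pair.G_CL, xL_t) - xL_t).abs().mean()
                         + (pair.translate(pair.G_LC, xC_t) - xC_t).abs().mean())
                L_total = L_total + cfg.lambda_identity * L_idt
            L_total.backward()
            gen_hist.add_gradient()
            gen_opt.step()
            gen_hist.update()

            # -- discriminator updates (individual optimizers) -------------
            with np.errstate(over="ignore"):
                fake_L = buffer_L.sample(pair.translate(pair.G_CL, Tensor(batch_C)).data)
                fake_C = buffer_C.sample(pair.translate(pair.G_LC, Tensor(batch_L)).data)
            discriminator_step(
                pair.D_CL, d_opt_CL, L_norm_all[rng.integers(0, len(L_vals), cfg.batch_size)],
                fake_L, rng.uniform(lo_v, hi_v, (cfg.batch_size, 1)),
                rng.uniform(lo_f, hi_f, (len(fake_L), 1)), hist=d_hist_CL)
            discriminator_step(
                pair.D_LC, d_opt_LC, C_norm_all[rng.integers(0, len(C_vals), cfg.batch_size)],
                fake_C, rng.uniform(lo_v, hi_v, (cfg.batch_size, 1)),
                rng.uniform(lo_f, hi_f, (len(fake_C), 1)), hist=d_hist_LC)

            step_vals = np.array([L_adv.item(), L_recov_L.item(),
                                  L_recov_C.item(), L_comp.item()])
            epoch_parts += step_vals
            if record == "step":
                log.append(_breakdown(cfg, *step_vals))
        if record == "epoch":
            log.append(_breakdown(cfg, *(epoch_parts / steps_per_epoch)))
        if data_val and cfg.select_on_validation:
            val_rmse = float(np.mean([
                evaluate_dataset(pair.compensate_dataset(d), grid).rmse
                for d in data_val]))
            if val_rmse < best_val:
                best_val = val_rmse
                best_weights = [p.data.copy() for p in gen_params]
    if best_weights is not None:
        for p, w in zip(gen_params, best_weights):
            p.data = w
    return pair, log


def _breakdown(cfg: TrainConfig, adv: float, recov_L: float, recov_C: float,
               comp: float) -> LossBreakdown:
    cycle = recov_L + recov_C
    lam_cycle = 0.0 if cfg.mode == "vanilla_gan" else cfg.lambda_cycle
    total = cfg.lambda_adv * adv + lam_cycle * cycle + cfg.lambda_comp * comp
    return LossBreakdown(L_adv=adv, L_recov_L=recov_L, L_recov_C=recov_C,
                         L_cycle=cycle, L_comp=comp, L_total=total)


def derived_member_seed(master_seed: int, member: int) -> int:
    """Seed for ensemble member `member`: master seed + member index."""
    return (int(master_seed) + int(member)) % (2**31)


def train_ensemble(cfg: TrainConfig, data_C: list[EnvironmentDataset],
                   data_L: list[EnvironmentDataset], grid: GroundTruthGrid,
                   bounds: NormalizationBounds | None = None,
                   data_val: list[EnvironmentDataset] | None = None) -> list[ModelPair]:
    """Sequentially train `cfg.ensemble_size` independent initializations."""
    if cfg.ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    if bounds is None:
        bounds = fit_normalization(list(data_C) + list(data_L))
    members = []
    for i in range(cfg.ensemble_size):
        member_cfg = replace(cfg, seed=derived_member_seed(cfg.seed, i))
        member, _ = train(member_cfg, data_C, data_L, grid, bounds=bounds,
                          data_val=data_val)
        members.append(member)
    return members


@dataclass
class CompensationResult:
    """Ensemble-mean compensated dataset plus the per-point epistemic spread."""

    dataset: EnvironmentDataset
    member_values: np.ndarray        # (n_members, n_points, 7)
    sigma_per_point: np.ndarray      # mm
    sigma_pred: float                # mm, mean over points


def ensemble_compensate(members: list[ModelPair],
                        dataset: EnvironmentDataset) -> CompensationResult:
    """Average the members' compensated outputs and summarize their spread.

    x and y pass through untouched; z and q are averaged linearly and the
    orientation channels with a circular mean.  ``sigma_pred`` follows the
    positional-spread convention of :func:`emtcomp.metrics.prediction_spread`
    (zero for a single member).
    """
    if not members:
        raise ValueError("ensemble_compensate requires >= 1 member")
    member_values = np.stack([m.compensate_values(dataset.values) for m in members])
    mean = member_values.mean(axis=0)
    for col in ANGLE_CHANNELS:
        mean[:, col] = wrap_angle(
            circmean(member_values[:, :, col], high=180.0, low=-180.0, axis=0))
    mean[:, 0:2] = dataset.values[:, 0:2]
    if len(members) >= 2:
        sigma_per_point, sigma = prediction_spread(member_values)
    else:
        sigma_per_point = np.zeros(len(dataset))
        sigma = 0.0
    out = dataset.with_values(mean)
    out.domain = "L"
    out.c_arm_distance_cm = None
    return CompensationResult(dataset=out, member_values=member_values,
                              sigma_per_point=sigma_per_point, sigma_pred=sigma)
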
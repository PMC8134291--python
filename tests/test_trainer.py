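"""Loss terms, schedule, discriminator isolation, determinism, ensembles."""

import math
from dataclasses import replace

import numpy as np
import pytest

from emtcomp._autodiff import Adam, Tensor
from emtcomp.datamodel import fit_normalization
from emtcomp.networks import ModelPair, build_discriminator
from emtcomp.trainer import (LossBreakdown, TrainConfig, adversarial_loss,
                             bce, bce_with_logits, compensation_loss,
                             cycle_loss, derived_member_seed,
                             discriminator_step, ensemble_compensate,
                             lr_schedule, total_generator_loss, train,
                             train_ensemble)
from tests.conftest import synthetic_dataset

QUICK = dict(total_epochs=4, decay_start_epoch=2, ensemble_size=2,
             lambda_hist=0.0, select_on_validation=False)


@pytest.fixture()
def pair(toy_domains):
    return ModelPair.initialize(toy_domains["bounds"], seed=0)


class TestLossTerms:
    def test_bce_closed_form_at_half(self):
        # output 0.5 against hard label 1 -> -ln(0.5) per sample
        pred = Tensor(np.full((8, 1), 0.5))
        assert bce(pred, np.ones((8, 1))).item() == pytest.approx(math.log(2.0))
        logits = Tensor(np.zeros((8, 1)))
        assert bce_with_logits(logits, np.ones((8, 1))).item() == pytest.approx(math.log(2.0))

    def test_adversarial_loss_matches_hand_rolled_bce(self, toy_domains, pair):
        rng = np.random.default_rng(0)
        bC = toy_domains["bounds"].normalize(toy_domains["carm"].values[:8])
        bL = toy_domains["bounds"].normalize(toy_domains["lab"].values[:8])
        lvC = rng.uniform(0.8, 1.0, (8, 1))
        lvL = rng.uniform(0.8, 1.0, (8, 1))
        loss = adversarial_loss(bC, bL, pair, lvC, lvL).item()
        fake_L = pair.translate(pair.G_CL, Tensor(bC)).data
        fake_C = pair.translate(pair.G_LC, Tensor(bL)).data
        pL = pair.D_CL(Tensor(fake_L)).data
        pC = pair.D_LC(Tensor(fake_C)).data
        hand = (-np.mean(lvC * np.log(pL) + (1 - lvC) * np.log(1 - pL))
                - np.mean(lvL * np.log(pC) + (1 - lvL) * np.log(1 - pC)))
        assert loss == pytest.approx(hand, abs=1e-9)

    def test_cycle_loss_is_sum_of_recovery_terms(self, toy_domains, pair):
        bC = toy_domains["bounds"].normalize(toy_domains["carm"].values[:8])
        bL = toy_domains["bounds"].normalize(toy_domains["lab"].values[:8])
        rL, rC, cyc = cycle_loss(bC, bL, pair)
        assert cyc.item() == pytest.approx(rL.item() + rC.item(), abs=1e-15)
        # brute-force recomputation of one recovery term
        rec_C = pair.translate(pair.G_LC, pair.translate(pair.G_CL, Tensor(bC))).data
        assert rC.item() == pytest.approx(np.abs(rec_C - bC).mean(), abs=1e-12)

    def test_identity_generators_have_zero_cycle_loss(self, toy_domains, pair):
        bC = toy_domains["bounds"].normalize(toy_domains["carm"].values[:8])
        # force both generators to reproduce their input channels exactly:
        # zero all hidden layers, wire the head to pass z,q,angles through
        for g in (pair.G_CL, pair.G_LC):
            for w, b in zip(g.weights, g.biases):
                w.data[:] = 0.0
                b.data[:] = 0.0
        rL, rC, cyc = cycle_loss(bC, bC, pair)
        # outputs are constant zero, so recovery error equals mean |input|
        # on the generated channels; x,y recover exactly by construction
        expected = np.abs(bC[:, 2:]).mean() * 5 / 7
        assert rC.item() == pytest.approx(expected, abs=1e-12)

    def test_compensation_loss_single_pair_closed_form(self, toy_domains):
        grid = toy_domains["grid"]
        pair = ModelPair.initialize(toy_domains["bounds"], seed=1)
        g = pair.G_CL
        for w in g.weights:
            w.data[:] = 0.0
        for b in g.biases:
            b.data[:] = 0.0
        # head outputs z_norm = constant c for both points -> dz = 0,
        # so compensated distance is the planar distance
        c = 0.4
        g.biases[-1].data[0] = c
        batch = np.array([[0, 0, 0, 5, 0, 0, 0], [9.0, 0, 0, 5, 0, 0, 0]])
        loss = compensation_loss(batch, np.array([0, 1]), pair, grid).item()
        assert loss == pytest.approx((9.0 - 8.0) ** 2, abs=1e-9)

    def test_compensation_loss_matches_double_loop(self, toy_domains):
        grid = toy_domains["grid"]
        pair = ModelPair.initialize(toy_domains["bounds"], seed=2)
        ds = toy_domains["carm"]
        batch = ds.values[:8]
        nodes = ds.node_index[:8]
        loss = compensation_loss(batch, nodes, pair, grid).item()
        z = pair.compensate_values(batch)[:, 2]
        total = 0.0
        for k in range(0, 8, 2):
            d = np.sqrt((batch[k, 0] - batch[k+1, 0]) ** 2
                        + (batch[k, 1] - batch[k+1, 1]) ** 2
                        + (z[k] - z[k+1]) ** 2)
            dt = np.linalg.norm(grid.node_positions[nodes[k]]
                                - grid.node_positions[nodes[k+1]])
            total += (d - dt) ** 2
        assert loss == pytest.approx(total / 4, abs=1e-9)

    def test_total_loss_weighted_sum(self):
        cfg = TrainConfig()
        parts = {"L_adv": 1.0, "L_cycle": 1.0, "L_comp": 1.0}
        assert total_generator_loss(parts, cfg) == pytest.approx(10.50001)
        zero = {"L_adv": 0.0, "L_cycle": 0.0, "L_comp": 0.0}
        assert total_generator_loss(zero, cfg) == 0.0
        vanilla = replace(cfg, mode="vanilla_gan")
        assert total_generator_loss(parts, vanilla) == pytest.approx(0.5 + 1e-5)


class TestSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (0, 0.0005), (99, 0.0005), (100, 0.0005), (150, 0.00025), (200, 0.0)])
    def test_linear_decay_after_epoch_100(self, epoch, expected):
        assert lr_schedule(TrainConfig(), epoch) == pytest.approx(expected)

    def test_invalid_decay_start_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(decay_start_epoch=200, total_epochs=200)


class TestDiscriminatorStep:
    def test_updates_only_that_discriminator(self, toy_domains, pair):
        rng = np.random.default_rng(0)
        before = {
            "G_CL": [p.data.copy() for p in pair.G_CL.parameters],
            "G_LC": [p.data.copy() for p in pair.G_LC.parameters],
            "D_LC": [p.data.copy() for p in pair.D_LC.parameters],
            "D_CL": [p.data.copy() for p in pair.D_CL.parameters],
        }
        opt = Adam(pair.D_CL.parameters, 0.0005)
        real = toy_domains["bounds"].normalize(toy_domains["lab"].values[:16])
        fake = rng.uniform(0, 1, (16, 7))
        discriminator_step(pair.D_CL, opt, real, fake,
                           rng.uniform(0.8, 1, (16, 1)), rng.uniform(0, 0.2, (16, 1)))
        for name in ("G_CL", "G_LC", "D_LC"):
            net = getattr(pair, name)
            assert all(np.array_equal(b, p.data)
                       for b, p in zip(before[name], net.parameters))
        assert any(not np.array_equal(b, p.data)
                   for b, p in zip(before["D_CL"], pair.D_CL.parameters))

    def test_perfect_discriminator_reaches_bce_floor(self):
        d = build_discriminator(0)
        rng = np.random.default_rng(1)
        real = np.zeros((64, 7)); fake = np.ones((64, 7)) * 10
        opt = Adam(d.parameters, 0.005)
        for _ in range(300):
            discriminator_step(d, opt, real, fake,
                               np.ones((64, 1)), np.zeros((64, 1)))
        p_real = d(real).data.mean()
        p_fake = d(fake).data.mean()
        assert p_real > 0.95 and p_fake < 0.05


class TestTraining:
    def test_short_run_is_seed_deterministic(self, toy_domains):
        cfg = TrainConfig(seed=3, **QUICK)
        args = ([toy_domains["carm"]], [toy_domains["lab"]], toy_domains["grid"])
        a, log_a = train(cfg, *args, bounds=toy_domains["bounds"])
        b, log_b = train(cfg, *args, bounds=toy_domains["bounds"])
        for pa, pb in zip(a.G_CL.parameters, b.G_CL.parameters):
            assert np.array_equal(pa.data, pb.data)
        assert log_a == log_b

    def test_loss_identities_hold_at_every_step(self, toy_domains):
        cfg = TrainConfig(seed=1, **QUICK)
        _, log = train(cfg, [toy_domains["carm"]], [toy_domains["lab"]],
                       toy_domains["grid"], bounds=toy_domains["bounds"],
                       record="step")
        assert len(log) > 0
        for step in log:
            assert step.L_cycle == step.L_recov_L + step.L_recov_C
            assert step.L_total == (cfg.lambda_adv * step.L_adv
                                    + cfg.lambda_cycle * step.L_cycle
                                    + cfg.lambda_comp * step.L_comp)

    def test_xy_passthrough_survives_training(self, toy_domains):
        cfg = TrainConfig(seed=2, **QUICK)
        pair, _ = train(cfg, [toy_domains["carm"]], [toy_domains["lab"]],
                        toy_domains["grid"], bounds=toy_domains["bounds"])
        vals = toy_domains["carm"].values
        out = pair.compensate_values(vals)
        assert np.array_equal(out[:, :2], vals[:, :2])

    def test_empty_domain_rejected(self, toy_domains):
        with pytest.raises(ValueError):
            train(TrainConfig(**QUICK), [], [toy_domains["lab"]],
                  toy_domains["grid"])


class TestEnsemble:
    def test_member_seeds_are_master_plus_index(self):
        assert derived_member_seed(100, 3) == 103
        assert derived_member_seed(2**31 - 1, 1) == 0

    def test_single_member_ensemble_equals_plain_train(self, toy_domains):
        cfg = TrainConfig(seed=5, **{**QUICK, "ensemble_size": 1})
        members = train_ensemble(cfg, [toy_domains["carm"]], [toy_domains["lab"]],
                                 toy_domains["grid"], bounds=toy_domains["bounds"])
        solo, _ = train(replace(cfg, seed=derived_member_seed(5, 0)),
                        [toy_domains["carm"]], [toy_domains["lab"]],
                        toy_domains["grid"], bounds=toy_domains["bounds"])
        for pa, pb in zip(members[0].G_CL.parameters, solo.G_CL.parameters):
            assert np.array_equal(pa.data, pb.data)

    def test_members_differ(self, toy_domains):
        cfg = TrainConfig(seed=6, **QUICK)
        members = train_ensemble(cfg, [toy_domains["carm"]], [toy_domains["lab"]],
                                 toy_domains["grid"], bounds=toy_domains["bounds"])
        assert any(not np.array_equal(a.data, b.data)
                   for a, b in zip(members[0].G_CL.parameters,
                                   members[1].G_CL.parameters))

    def test_ensemble_compensate_matches_brute_force(self, toy_domains):
        cfg = TrainConfig(seed=7, **QUICK)
        members = train_ensemble(cfg, [toy_domains["carm"]], [toy_domains["lab"]],
                                 toy_domains["grid"], bounds=toy_domains["bounds"])
        ds = toy_domains["carm"]
        res = ensemble_compensate(members, ds)
        stack = np.stack([m.compensate_values(ds.values) for m in members])
        assert np.allclose(res.member_values, stack, atol=1e-12)
        assert np.allclose(res.dataset.values[:, 2], stack[:, :, 2].mean(axis=0),
                           atol=1e-12)
        per_axis = np.std(stack[:, :, :3], axis=0, ddof=1)
        brute = np.linalg.norm(per_axis, axis=1).mean()
        assert res.sigma_pred == pytest.approx(brute, abs=1e-12)

    def test_single_member_has_zero_sigma(self, toy_domains, pair):
        res = ensemble_compensate([pair], toy_domains["carm"])
        assert res.sigma_pred == 0.0

    def test_soft_labels_drawn_within_stated_ranges(self):
        rng = np.random.default_rng(0)
        lo, hi = TrainConfig().soft_label_valid
        draws = rng.uniform(lo, hi, 1000)
        assert draws.min() >= 0.8 and draws.max() <= 1.0
        lo, hi = TrainConfig().soft_label_fake
        draws = rng.uniform(lo, hi, 1000)
        assert draws.min() >= 0.0 and draws.max() <= 0.2
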
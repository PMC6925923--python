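"""Schedule, determinism, checkpoint resume, unpaired sampling, toy runs."""

import numpy as np
import pytest
from scipy.stats import chisquare

import cyclect as cc
from cyclect import losses as L
from cyclect.training import (GANState, TrainConfig, WeightState, denoise,
                              epoch_pairings, lr_at_epoch, train, training_step)


def toy_cfg(**kw):
    base = dict(total_epochs=4, decay_start_epoch=2, width=4, n_res_blocks=1,
                seed=0)
    base.update(kw)
    return TrainConfig(**base)


def toy_dataset(n=6, side=32, seed=0):
    rng = np.random.default_rng(seed)
    low = [cc.CTSlice(pixels=1000 + 200 * rng.random((side, side)),
                      dose_fraction=0.05, id=i) for i in range(n)]
    ref = [cc.CTSlice(pixels=1000 + 200 * rng.random((side, side)), id=i)
           for i in range(n)]
    ds = cc.build_unpaired_dataset(low, ref, seed)
    priors = cc.build_prior_set(ds, method="gaussian")
    return ds, priors


class TestLRSchedule:
    def test_constant_then_linear_decay(self):
        cfg = TrainConfig(lr0=2e-4, total_epochs=20000, decay_start_epoch=10000)
        assert lr_at_epoch(0, cfg) == 2e-4
        assert lr_at_epoch(9999, cfg) == 2e-4
        assert lr_at_epoch(15000, cfg) == pytest.approx(1e-4)
        assert lr_at_epoch(20000, cfg) == 0.0

    def test_non_increasing_and_continuous_at_decay_start(self):
        cfg = TrainConfig(lr0=1e-3, total_epochs=100, decay_start_epoch=40)
        lrs = [lr_at_epoch(e, cfg) for e in range(101)]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))
        assert lrs[40] == pytest.approx(cfg.lr0)

    def test_out_of_range_rejected(self):
        cfg = TrainConfig(total_epochs=10, decay_start_epoch=5)
        with pytest.raises(ValueError):
            lr_at_epoch(11, cfg)
        with pytest.raises(ValueError):
            lr_at_epoch(-1, cfg)


class TestTrainingStep:
    def test_same_seed_identical_loss_sequences(self):
        ds, priors = toy_dataset()
        reports = []
        for _ in range(2):
            st = GANState(toy_cfg())
            seq = [training_step(ds.source_X[i % 6].pixels,
                                 ds.target_Y[(i + 2) % 6].pixels,
                                 priors[i % 6].pixels, st).as_dict()
                   for i in range(4)]
            reports.append(seq)
        assert reports[0] == reports[1]

    def test_missing_prior_rejected(self):
        ds, _ = toy_dataset()
        st = GANState(toy_cfg(use_prior=True))
        with pytest.raises(ValueError):
            training_step(ds.source_X[0].pixels, ds.target_Y[0].pixels, None, st)

    def test_all_components_finite_and_consistent(self):
        ds, priors = toy_dataset()
        st = GANState(toy_cfg())
        rep = training_step(ds.source_X[0].pixels, ds.target_Y[0].pixels,
                            priors[0].pixels, st)
        assert rep.is_finite()
        w = st.cfg.weights
        assert rep.total_G == pytest.approx(
            rep.g_adv_N + rep.g_adv_L + w.lambda_cyc * rep.cycle
            + w.alpha_prior * rep.prior)


class TestTrain:
    def test_zero_epochs_yields_initialization_only(self):
        ds, priors = toy_dataset()
        series = train(ds, priors, toy_cfg(total_epochs=0, decay_start_epoch=1))
        assert len(series.checkpoints) == 1
        assert series.checkpoints[0].epoch == 0

    def test_toy_run_finite_losses(self):
        ds, priors = toy_dataset()
        log = []
        series = train(ds, priors, toy_cfg(), log=log)
        assert len(log) == 4 * 6
        assert all(np.isfinite(list(r.values())).all() for r in
                   ({k: v for k, v in rec.items() if k != "step"} for rec in log))
        assert series.last().epoch == 4

    def test_no_prior_ablation_reports_zero_prior(self):
        ds, _ = toy_dataset()
        log = []
        train(ds, None, toy_cfg(use_prior=False,
                                weights=cc.LossWeights(10.0, 0.0)), log=log)
        assert all(rec["prior"] == 0.0 for rec in log)

    def test_misaligned_priors_rejected(self):
        ds, priors = toy_dataset()
        with pytest.raises(ValueError):
            train(ds, priors[:-1], toy_cfg())

    def test_checkpoint_resume_reproduces_direct_run(self):
        ds, priors = toy_dataset()
        cfg = toy_cfg(checkpoint_every=1)
        direct = train(ds, priors, cfg)
        mid = next(ck for ck in direct.checkpoints if ck.epoch == 2)
        resumed = train(ds, priors, cfg, resume_from=mid)
        a = direct.last().net_weights
        b = resumed.last().net_weights
        assert direct.last().epoch == resumed.last().epoch
        for net in a:
            for k in a[net]:
                np.testing.assert_array_equal(a[net][k], b[net][k])


class TestUnpairedSampling:
    def test_pairing_frequency_is_chance_level(self):
        # matched-index pairings should occur at ~1/n rate
        rng = np.random.default_rng(0)
        n, epochs = 16, 400
        matches = sum(int(np.sum(epoch_pairings(rng, n, n)[0]
                                 == epoch_pairings(rng, n, n)[1]))
                      for _ in range(epochs))
        total = n * epochs
        expected = total / n
        obs = np.array([matches, total - matches])
        exp = np.array([expected, total - expected])
        assert chisquare(obs, exp).pvalue > 0.01

    def test_unequal_sizes_supported(self):
        rng = np.random.default_rng(1)
        xi, yi = epoch_pairings(rng, 10, 7)
        assert len(xi) == len(yi) == 10
        assert yi.max() < 7


class TestDenoise:
    def _trained_gen(self):
        ds, priors = toy_dataset()
        series = train(ds, priors, toy_cfg(total_epochs=1, decay_start_epoch=1))
        return series.generator_state("G_N")

    def test_full_mode_shape_and_determinism(self):
        gen = self._trained_gen()
        s = cc.CTSlice(pixels=np.random.default_rng(0).random((32, 32)) * 2000,
                       id=5)
        a = denoise(s, gen, mode="full")
        b = denoise(s, gen, mode="full")
        assert a.pixels.shape == (32, 32) and a.id == 5
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_indivisible_size_rejected(self):
        gen = self._trained_gen()
        s = cc.CTSlice(pixels=np.zeros((30, 30)))
        with pytest.raises(ValueError):
            denoise(s, gen, mode="full")

    def test_patched_mode_tiles_and_reassembles(self):
        gen = self._trained_gen()
        s = cc.CTSlice(pixels=np.random.default_rng(1).random((64, 64)) * 2000)
        full = denoise(s, gen, mode="full")
        patched = denoise(s, gen, mode="patched", patch_size=32)
        assert patched.pixels.shape == (64, 64)
        # interior pixels away from seams agree closely for a conv generator
        inner = (slice(8, 24), slice(8, 24))
        assert np.median(np.abs(patched.pixels[inner] - full.pixels[inner])) < 50


class TestScaledDownRecovery:
    def test_one_parameter_generator_recovers_inverse_scale(self):
        # F fixed to the true corruption (x -> x/2); G = a*x with a learned by
        # Adam on the cycle loss alone: a should approach 2 within 10%
        rng = np.random.default_rng(0)
        recovered = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            a = 0.5 + rng.random()
            m, v, lr = 0.0, 0.0, 0.05
            for t in range(1, 301):
                x = rng.random((8,)) + 0.5
                # cycle: |F(G(x)) - x| with F(z) = z/2
                g = np.sign(a * x / 2 - x) @ (x / 2) / x.size
                m = 0.5 * m + 0.5 * g
                v = 0.999 * v + 0.001 * g * g
                a -= lr * (m / (1 - 0.5 ** t)) / (np.sqrt(v / (1 - 0.999 ** t)) + 1e-8)
            recovered.append(a)
        assert all(abs(a - 2.0) / 2.0 < 0.1 for a in recovered)
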
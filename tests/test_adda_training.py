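import numpy as np
import pytest

from rbpadda.adda_training import (
    Mode,
    TrainingConfig,
    _BatchStream,
    adapt_target,
    finetune_predictor,
    loss_discriminator,
    loss_finetune,
    loss_pretrain,
    loss_target,
    pretrain_source,
    train_full,
)
from rbpadda.model_core import (
    Adam,
    backward_discriminator,
    forward_discriminator,
    forward_encoder,
    init_bundle,
    predict,
)
from rbpadda.seq_encoding import encode_dataset


def params_equal(a, b):
    return all(np.array_equal(a[k], b[k]) for k in a)


class TestLosses:
    def test_pretrain_examples(self):
        assert loss_pretrain([0.2, -0.5], [0.2, -0.5]) == 0.0
        assert loss_pretrain([1.0, 0.0], [0.0, 0.0]) == pytest.approx(0.5)

    def test_pretrain_quadratic_homogeneity(self):
        base = loss_pretrain([1.0, -2.0], [0.0, 0.0])
        assert loss_pretrain([3.0, -6.0], [0.0, 0.0]) == pytest.approx(9 * base)

    def test_discriminator_examples(self):
        assert loss_discriminator([1.0, 1.0], [0.0, 0.0]) == 0.0
        assert loss_discriminator([0.5], [0.5]) == pytest.approx(0.25)

    def test_discriminator_mean_semantics(self):
        a = loss_discriminator([0.3, 0.9], [0.1, 0.4])
        b = loss_discriminator([0.3, 0.9] * 3, [0.1, 0.4] * 3)
        assert a == pytest.approx(b)

    def test_target_examples(self):
        assert loss_target([1.0], [0.3], [0.3]) == 0.0
        assert loss_target([0.0], [0.3], [0.3]) == pytest.approx(1.0)

    def test_target_monotone_in_fit(self):
        worse = loss_target([0.7], [1.0], [0.0])
        better = loss_target([0.7], [0.5], [0.0])
        assert better < worse

    def test_finetune_examples(self):
        assert loss_finetune([0.1], [0.1], [-0.2], [-0.2]) == 0.0
        assert loss_finetune([1.0], [0.0], [1.0], [0.0]) == pytest.approx(2.0)

    def test_finetune_symmetric_in_domains(self):
        a = loss_finetune([0.5], [0.1], [-0.3], [0.2])
        b = loss_finetune([-0.3], [0.2], [0.5], [0.1])
        assert a == pytest.approx(b)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            loss_pretrain([], [])


class TestConfig:
    def test_defaults_match_stated_hyperparameters(self):
        cfg = TrainingConfig()
        assert cfg.batch_size == 256
        assert cfg.lr_pretrain == 0.001
        assert cfg.lr_target == 0.001
        assert cfg.lr_discriminator == 0.00005
        assert cfg.lr_finetune == 0.00005
        assert cfg.max_epochs == 1000
        assert cfg.mode is Mode.FULL_ADDA
        assert cfg.early_stop_patience is None

    def test_budget_derived_from_epoch_cap(self):
        cfg = TrainingConfig(max_epochs=10, batch_size=100)
        assert cfg.budget("n1", 250) == 10 * 3  # ceil(250/100) batches/epoch
        assert TrainingConfig(n1=5).budget("n1", 1000) == 5

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(lr_pretrain=0.0)
        with pytest.raises(ValueError):
            TrainingConfig(batch_size=0)


class TestBatchStream:
    def test_epoch_covers_all_without_replacement(self):
        stream = _BatchStream(10, 5, np.random.default_rng(0))
        seen = np.concatenate([stream.next(), stream.next()])
        assert sorted(seen) == list(range(10))


class TestPretrain:
    def test_learns_motif_signal(self, small_pair):
        source, _, _ = small_pair
        cfg = TrainingConfig(n1=200, batch_size=64, seed=0)
        bundle = init_bundle(0)
        X, y, _ = encode_dataset(source)
        initial = loss_pretrain(predict(bundle, X), y)
        trained, trace = pretrain_source(bundle, source, cfg)
        final = loss_pretrain(predict(trained, X), y)
        assert final < 0.5 * initial
        assert len(trace.losses("pretrain", "mse_source")) == 200

    def test_updates_only_ms_and_t(self, small_pair):
        source, _, _ = small_pair
        bundle = init_bundle(0)
        trained, _ = pretrain_source(bundle, source, TrainingConfig(n1=5, batch_size=32, seed=0))
        assert not params_equal(trained.params_ms, bundle.params_ms)
        assert not params_equal(trained.params_t, bundle.params_t)
        assert params_equal(trained.params_mt, bundle.params_mt)
        assert params_equal(trained.params_d, bundle.params_d)

    def test_zero_budget_is_identity(self, small_pair):
        source, _, _ = small_pair
        bundle = init_bundle(0)
        trained, _ = pretrain_source(bundle, source, TrainingConfig(n1=0, seed=0))
        assert params_equal(trained.params_ms, bundle.params_ms)
        assert params_equal(trained.params_t, bundle.params_t)

    def test_seeded_determinism(self, small_pair):
        source, _, _ = small_pair
        cfg = TrainingConfig(n1=30, batch_size=32, seed=5)
        a, _ = pretrain_source(init_bundle(5), source, cfg)
        b, _ = pretrain_source(init_bundle(5), source, cfg)
        assert params_equal(a.params_ms, b.params_ms)
        assert params_equal(a.params_t, b.params_t)


@pytest.fixture(scope="module")
def pretrained(small_pair):
    source, _, _ = small_pair
    bundle, _ = pretrain_source(init_bundle(3), source, TrainingConfig(n1=120, batch_size=64, seed=3))
    return bundle


class TestAdaptTarget:
    def test_freezes_ms_and_t(self, small_pair, pretrained):
        source, target, _ = small_pair
        adapted, _ = adapt_target(pretrained, source, target, TrainingConfig(n2=20, batch_size=32, seed=3))
        assert params_equal(adapted.params_ms, pretrained.params_ms)
        assert params_equal(adapted.params_t, pretrained.params_t)
        assert not params_equal(adapted.params_mt, pretrained.params_ms)
        assert not params_equal(adapted.params_d, pretrained.params_d)

    def test_zero_budget_leaves_mt_cloned_from_ms(self, small_pair, pretrained):
        source, target, _ = small_pair
        adapted, _ = adapt_target(pretrained, source, target, TrainingConfig(n2=0, seed=3))
        assert params_equal(adapted.params_mt, adapted.params_ms)

    def test_target_network_confuses_a_warmed_discriminator(self, small_pair):
        """A discriminator warmed on the clone-point features scores the
        target domain below the source side; adversarial Mt updates then
        move the target score toward the source label (confusion
        increases), in the median over 5 seeds."""
        source, target, _ = small_pair
        Xs, _, _ = encode_dataset(source)
        Xt, _, _ = encode_dataset(target)
        movements = []
        for seed in range(5):
            bundle, _ = pretrain_source(
                init_bundle(seed), source, TrainingConfig(n1=60, batch_size=64, seed=seed)
            )
            # discriminator-only warm-up on the clone-point features, at a
            # rate high enough to find the (real) domain difference
            opt = Adam(bundle.params_d, lr=0.005)
            for it in range(150):
                fs = forward_encoder(bundle.params_ms, Xs[(it * 64) % 192 : (it * 64) % 192 + 64])
                ft = forward_encoder(bundle.params_ms, Xt[(it * 32) % 96 : (it * 32) % 96 + 32])
                ds_, cs = forward_discriminator(bundle.params_d, fs, want_cache=True)
                dt_, ct = forward_discriminator(bundle.params_d, ft, want_cache=True)
                gs, _ = backward_discriminator(bundle.params_d, cs, (ds_ - 1) / len(ds_))
                gt, _ = backward_discriminator(bundle.params_d, ct, dt_ / len(dt_))
                opt.step(bundle.params_d, {k: gs[k] + gt[k] for k in gs})
            d_warm = forward_discriminator(
                bundle.params_d, forward_encoder(bundle.params_ms, Xt)
            ).mean()
            adapted, _ = adapt_target(
                bundle, source, target, TrainingConfig(n2=150, batch_size=64, seed=seed)
            )
            d_adapted = forward_discriminator(
                adapted.params_d, forward_encoder(adapted.params_mt, Xt)
            ).mean()
            movements.append(d_adapted - d_warm)
        assert np.median(movements) > 0


class TestFinetune:
    def test_freezes_both_encoders(self, small_pair, pretrained):
        source, target, _ = small_pair
        from rbpadda.model_core import clone_source_to_target

        bundle = clone_source_to_target(pretrained)
        tuned, trace = finetune_predictor(bundle, source, target, TrainingConfig(n3=20, batch_size=32, seed=3))
        assert params_equal(tuned.params_ms, bundle.params_ms)
        assert params_equal(tuned.params_mt, bundle.params_mt)
        assert not params_equal(tuned.params_t, bundle.params_t)
        assert len(trace.losses("finetune", "finetune")) == 20

    def test_zero_budget_leaves_t_unchanged(self, small_pair, pretrained):
        source, target, _ = small_pair
        tuned, _ = finetune_predictor(pretrained, source, target, TrainingConfig(n3=0, seed=3))
        assert params_equal(tuned.params_t, pretrained.params_t)


TINY = dict(n1=40, n2=20, n3=10, batch_size=32)


class TestTrainFull:
    def test_without_adda_keeps_mt_equal_to_ms(self, small_pair):
        source, target, _ = small_pair
        bundle, _ = train_full(source, target, TrainingConfig(**TINY, seed=0, mode=Mode.WITHOUT_ADDA))
        assert params_equal(bundle.params_mt, bundle.params_ms)

    def test_reversed_mode_equals_swapped_inputs(self, small_pair):
        source, target, _ = small_pair
        rev, _ = train_full(source, target, TrainingConfig(**TINY, seed=0, mode=Mode.REVERSED))
        swp, _ = train_full(target, source, TrainingConfig(**TINY, seed=0, mode=Mode.FULL_ADDA))
        for part in ("params_ms", "params_mt", "params_t", "params_d"):
            assert params_equal(getattr(rev, part), getattr(swp, part))

    def test_end_to_end_determinism(self, small_pair):
        source, target, _ = small_pair
        cfg = TrainingConfig(**TINY, seed=9)
        a, ta = train_full(source, target, cfg)
        b, tb = train_full(source, target, cfg)
        for part in ("params_ms", "params_mt", "params_t", "params_d"):
            assert params_equal(getattr(a, part), getattr(b, part))
        assert ta.records == tb.records

    def test_trace_losses_are_finite_and_ordered(self, small_pair):
        source, target, _ = small_pair
        _, trace = train_full(source, target, TrainingConfig(**TINY, seed=0))
        steps = [r[0] for r in trace.records]
        assert steps == sorted(steps, key=lambda s: ["pretrain", "adapt", "finetune"].index(s))
        assert all(np.isfinite(r[3]) for r in trace.records)
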
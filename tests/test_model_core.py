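import numpy as np
import pytest

from rbpadda.model_core import (
    Adam,
    EncoderSpec,
    backward_discriminator,
    backward_encoder,
    backward_predictor,
    clone_source_to_target,
    forward_discriminator,
    forward_encoder,
    forward_predictor,
    init_bundle,
    load_checkpoint,
    predict,
    save_checkpoint,
)


@pytest.fixture(scope="module")
def bundle():
    return init_bundle(7)


@pytest.fixture(scope="module")
def batch(rng2=np.random.default_rng(42)):
    return rng2.random((6, 41, 4))


class TestArchitecture:
    def test_encoder_parameter_inventory(self, bundle):
        shapes = {k: v.shape for k, v in bundle.params_ms.items()}
        assert shapes == {
            "conv1_W": (32, 4, 4),
            "conv1_b": (32,),
            "conv2_W": (32, 4, 32),
            "conv2_b": (32,),
            "fc1_W": (256, 128),
            "fc1_b": (128,),
            "fc2_W": (128, 64),
            "fc2_b": (64,),
        }

    def test_predictor_and_discriminator_inventory(self, bundle):
        assert {k: v.shape for k, v in bundle.params_t.items()} == {
            "fc1_W": (64, 64),
            "fc1_b": (64,),
            "fc2_W": (64, 32),
            "fc2_b": (32,),
            "out_W": (32, 1),
            "out_b": (1,),
        }
        assert {k: v.shape for k, v in bundle.params_d.items()} == {
            "fc1_W": (64, 64),
            "fc1_b": (64,),
            "out_W": (64, 1),
            "out_b": (1,),
        }

    def test_source_and_target_encoders_share_shape_inventory(self, bundle):
        assert {k: v.shape for k, v in bundle.params_ms.items()} == {
            k: v.shape for k, v in bundle.params_mt.items()
        }

    def test_grid_spec_changes_geometry(self):
        spec = EncoderSpec(n_filters=16, filter_width=6)
        b = init_bundle(0, spec)
        assert b.params_ms["conv1_W"].shape == (16, 6, 4)
        # 41 -> 36 -> 18 -> 13 -> 6 positions, 16 maps
        assert b.params_ms["fc1_W"].shape == (6 * 16, 128)


class TestForwardContracts:
    def test_zero_input_gives_constant_feature(self, bundle):
        feat = forward_encoder(bundle.params_ms, np.zeros((3, 41, 4)))
        assert np.array_equal(feat[0], feat[1]) and np.array_equal(feat[1], feat[2])

    def test_batch_permutation_permutes_outputs(self, bundle, batch):
        feat = forward_encoder(bundle.params_ms, batch)
        perm = np.array([3, 0, 5, 1, 4, 2])
        assert np.array_equal(forward_encoder(bundle.params_ms, batch[perm]), feat[perm])

    def test_forward_is_deterministic(self, bundle, batch):
        a = predict(bundle, batch)
        b = predict(bundle, batch)
        assert np.array_equal(a, b)

    def test_nonfinite_input_rejected(self, bundle):
        bad = np.full((1, 41, 4), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            forward_encoder(bundle.params_ms, bad)

    def test_fresh_discriminator_scores_half(self, bundle, batch):
        feat = forward_encoder(bundle.params_ms, batch)
        assert np.array_equal(forward_discriminator(bundle.params_d, feat), np.full(6, 0.5))

    def test_discriminator_scores_bounded(self, bundle, rng):
        params = dict(bundle.params_d)
        params["out_W"] = rng.normal(size=params["out_W"].shape)
        scores = forward_discriminator(params, rng.normal(scale=5, size=(20, 64)))
        assert np.all((scores > 0) & (scores < 1))

    def test_predictor_zero_feature_constant(self, bundle):
        out = forward_predictor(bundle.params_t, np.zeros((4, 64)))
        assert np.all(out == out[0])


def _fd_check(f, x, analytic, rng, n_probes=25, eps=1e-6, tol=1e-4):
    """Central finite differences on random coordinates of x."""
    for _ in range(n_probes):
        idx = tuple(rng.integers(s) for s in x.shape)
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        fd = (f(xp) - f(xm)) / (2 * eps)
        denom = max(abs(fd), abs(analytic[idx]), 1e-6)
        assert abs(fd - analytic[idx]) / denom < tol, (idx, fd, analytic[idx])


class TestGradients:
    def test_encoder_input_gradient_matches_finite_differences(self, bundle, rng):
        x = rng.random((2, 41, 4))
        probe = rng.normal(size=(2, 64))
        feat, cache = forward_encoder(bundle.params_ms, x, want_cache=True)
        _, dx = backward_encoder(bundle.params_ms, cache, probe)
        _fd_check(lambda xx: (forward_encoder(bundle.params_ms, xx) * probe).sum(), x, dx, rng)

    def test_encoder_parameter_gradients(self, bundle, rng):
        x = rng.random((2, 41, 4))
        probe = rng.normal(size=(2, 64))
        feat, cache = forward_encoder(bundle.params_ms, x, want_cache=True)
        grads, _ = backward_encoder(bundle.params_ms, cache, probe)
        for key in ("conv1_W", "conv2_W", "fc1_W", "fc2_W", "conv1_b", "fc2_b"):

            def f(val, key=key):
                saved = bundle.params_ms[key]
                bundle.params_ms[key] = val
                out = (forward_encoder(bundle.params_ms, x) * probe).sum()
                bundle.params_ms[key] = saved
                return out

            _fd_check(f, bundle.params_ms[key].copy(), grads[key], rng, n_probes=8)

    def test_predictor_gradients(self, bundle, rng):
        feat = rng.random((3, 64))
        probe = rng.normal(size=3)
        _, cache = forward_predictor(bundle.params_t, feat, want_cache=True)
        grads, dfeat = backward_predictor(bundle.params_t, cache, probe)
        _fd_check(lambda ff: (forward_predictor(bundle.params_t, ff) * probe).sum(), feat, dfeat, rng)

    def test_discriminator_gradients(self, bundle, rng):
        params = {k: v.copy() for k, v in bundle.params_d.items()}
        params["out_W"] = rng.normal(scale=0.2, size=params["out_W"].shape)
        feat = rng.random((3, 64))
        probe = rng.normal(size=3)
        _, cache = forward_discriminator(params, feat, want_cache=True)
        grads, dfeat = backward_discriminator(params, cache, probe)
        _fd_check(lambda ff: (forward_discriminator(params, ff) * probe).sum(), feat, dfeat, rng)


class TestCloneAndCheckpoint:
    def test_clone_makes_encoders_identical(self, bundle, batch):
        cloned = clone_source_to_target(bundle)
        a = forward_encoder(cloned.params_ms, batch)
        b = forward_encoder(cloned.params_mt, batch)
        assert np.abs(a - b).max() == 0

    def test_updating_mt_leaves_ms_unchanged(self, bundle, batch):
        cloned = clone_source_to_target(bundle)
        before = forward_encoder(cloned.params_ms, batch)
        cloned.params_mt["fc2_W"] += 1.0
        assert np.array_equal(forward_encoder(cloned.params_ms, batch), before)

    def test_clone_shape_mismatch_rejected(self, bundle):
        broken = bundle.copy()
        broken.params_mt["fc2_W"] = np.zeros((3, 3))
        with pytest.raises(ValueError, match="shape mismatch"):
            clone_source_to_target(broken)

    def test_checkpoint_round_trip_bit_identical(self, bundle, batch, tmp_path):
        b = bundle.copy()
        b.scale_params_source = (0.0, 2.5)
        b.config_hash = "abc123"
        path = tmp_path / "ckpt.npz"
        save_checkpoint(b, path)
        loaded = load_checkpoint(path)
        for part in ("params_ms", "params_mt", "params_t", "params_d"):
            for key, val in getattr(b, part).items():
                assert np.array_equal(getattr(loaded, part)[key], val)
        assert loaded.scale_params_source == (0.0, 2.5)
        assert loaded.config_hash == "abc123"
        assert np.array_equal(predict(loaded, batch), predict(b, batch))

    def test_same_seed_same_init(self, batch):
        a, b = init_bundle(11), init_bundle(11)
        assert np.array_equal(predict(a, batch), predict(b, batch))
        c = init_bundle(12)
        assert not np.array_equal(predict(a, batch), predict(c, batch))


class TestAdam:
    def test_descends_a_quadratic(self):
        params = {"w": np.array([5.0])}
        opt = Adam(params, lr=0.1)
        for _ in range(200):
            opt.step(params, {"w": 2 * params["w"]})
        assert abs(params["w"][0]) < 1e-2
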
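"""Network definitions: source/target encoders, task predictor, discriminator.

The four parameterized functions are small enough that they are
implemented directly on numpy arrays with hand-written forward and
backward passes (gradient-checked against central finite differences in
the test suite).  All parameters live in plain ``dict[str, ndarray]``
collections so cloning, freezing and checkpointing are trivial.

Default architecture:

* encoder (identical for source ``Ms`` and target ``Mt``):
  conv(32 filters, 4 wide x 4 channels, valid) -> ReLU -> maxpool(2,2)
  -> conv(32 filters, 4 wide x 32 maps, valid) -> ReLU -> maxpool(2,2)
  -> flatten -> fc 128 -> ReLU -> fc 64 -> ReLU; a 41x4 input yields a
  64-dimensional feature vector (41 -> 38 -> 19 -> 16 -> 8 positions).
* task predictor ``T``: fc 64 -> ReLU -> fc 32 -> ReLU -> linear scalar.
  The head is linear because scaled labels live in [-1, 1] under a plain
  squared loss.
* discriminator ``D``: fc 64 -> ReLU -> linear scalar -> sigmoid, so its
  score lies in (0, 1) with 1 = source, 0 = target; the bounded score
  keeps the least-squares adversarial objective in [0, 1].

Filter count and width are configurable for grid search; everything else
is fixed.  Weights are Glorot-uniform from a caller-supplied seed;
biases start at zero, which is why a freshly initialized discriminator
scores 0.5 everywhere (sigmoid of 0).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .seq_encoding import MAX_LEN

CHECKPOINT_SCHEMA_VERSION = 1
INPUT_LEN = MAX_LEN  # 41

Params = dict[str, np.ndarray]


@dataclass(frozen=True)
class EncoderSpec:
    n_filters: int = 32
    filter_width: int = 4
    fc1_units: int = 128
    fc2_units: int = 64  # = feature dimension

    @property
    def flat_dim(self) -> int:
        l1 = INPUT_LEN - self.filter_width + 1
        p1 = l1 // 2
        l2 = p1 - self.filter_width + 1
        p2 = l2 // 2
        if l2 < 1:
            raise ValueError(f"filter_width={self.filter_width} too large for input {INPUT_LEN}")
        return p2 * self.n_filters


@dataclass(frozen=True)
class PredictorSpec:
    fc1_units: int = 64
    fc2_units: int = 32


@dataclass(frozen=True)
class DiscriminatorSpec:
    fc1_units: int = 64


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_encoder_params(rng: np.random.Generator, spec: EncoderSpec = EncoderSpec()) -> Params:
    F, W = spec.n_filters, spec.filter_width
    return {
        "conv1_W": _glorot(rng, (F, W, 4), W * 4, F),
        "conv1_b": np.zeros(F),
        "conv2_W": _glorot(rng, (F, W, F), W * F, F),
        "conv2_b": np.zeros(F),
        "fc1_W": _glorot(rng, (spec.flat_dim, spec.fc1_units), spec.flat_dim, spec.fc1_units),
        "fc1_b": np.zeros(spec.fc1_units),
        "fc2_W": _glorot(rng, (spec.fc1_units, spec.fc2_units), spec.fc1_units, spec.fc2_units),
        "fc2_b": np.zeros(spec.fc2_units),
    }


def init_predictor_params(
    rng: np.random.Generator, spec: PredictorSpec = PredictorSpec(), feature_dim: int = 64
) -> Params:
    return {
        "fc1_W": _glorot(rng, (feature_dim, spec.fc1_units), feature_dim, spec.fc1_units),
        "fc1_b": np.zeros(spec.fc1_units),
        "fc2_W": _glorot(rng, (spec.fc1_units, spec.fc2_units), spec.fc1_units, spec.fc2_units),
        "fc2_b": np.zeros(spec.fc2_units),
        "out_W": _glorot(rng, (spec.fc2_units, 1), spec.fc2_units, 1),
        "out_b": np.zeros(1),
    }


def init_discriminator_params(
    rng: np.random.Generator, spec: DiscriminatorSpec = DiscriminatorSpec(), feature_dim: int = 64
) -> Params:
    # zero-initialized head: a fresh discriminator is neutral (sigmoid(0)=0.5)
    return {
        "fc1_W": _glorot(rng, (feature_dim, spec.fc1_units), feature_dim, spec.fc1_units),
        "fc1_b": np.zeros(spec.fc1_units),
        "out_W": np.zeros((spec.fc1_units, 1)),
        "out_b": np.zeros(1),
    }


# ---------------------------------------------------------------------------
# layer primitives (forward returns a cache consumed by the paired backward)


def _conv1d(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    # x: (B, L, C); W: (F, width, C) -> z: (B, L-width+1, F)
    # implemented as one BLAS matmul over flattened windows
    F, width, C = W.shape
    B = x.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(x, width, axis=1)
    # win: (B, P, C, width) -> contiguous (B*P, C*width)
    P = win.shape[1]
    win_flat = np.ascontiguousarray(win).reshape(B * P, C * width)
    Wm = W.transpose(2, 1, 0).reshape(C * width, F)
    z = (win_flat @ Wm).reshape(B, P, F) + b
    return z, (win_flat, (B, P))


def _conv1d_backward(dz: np.ndarray, conv_cache, W: np.ndarray, in_shape):
    win_flat, (B, P) = conv_cache
    F, width, C = W.shape
    dz_flat = dz.reshape(B * P, F)
    dW = (win_flat.T @ dz_flat).reshape(C, width, F).transpose(2, 1, 0)
    db = dz_flat.sum(axis=0)
    dx = np.zeros(in_shape)
    for w_off in range(width):
        dx[:, w_off : w_off + P, :] += dz @ W[:, w_off, :]
    return dW, db, dx


def _maxpool2(x: np.ndarray):
    # window 2, stride 2 along the sequence axis; an odd trailing element
    # is dropped (floor semantics); ties route to the earlier position
    L2 = x.shape[1] // 2
    left = x[:, 0 : L2 * 2 : 2, :]
    right = x[:, 1 : L2 * 2 : 2, :]
    mask = left >= right
    out = np.where(mask, left, right)
    return out, (mask, x.shape)


def _maxpool2_backward(dout: np.ndarray, cache):
    mask, shape = cache
    L2 = shape[1] // 2
    dx = np.zeros(shape)
    dx[:, 0 : L2 * 2 : 2, :] = np.where(mask, dout, 0.0)
    dx[:, 1 : L2 * 2 : 2, :] = np.where(mask, 0.0, dout)
    return dx


def _relu(x):
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# encoder


def forward_encoder(params: Params, x: np.ndarray, want_cache: bool = False):
    """Map a batch of encoded sequences ``(B, 41, 4)`` to feature vectors."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.shape[1:] != (INPUT_LEN, 4):
        raise ValueError(f"expected batch shaped (B, {INPUT_LEN}, 4), got {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in encoder input")

    z1, win1 = _conv1d(x, params["conv1_W"], params["conv1_b"])
    a1 = _relu(z1)
    p1, pc1 = _maxpool2(a1)
    z2, win2 = _conv1d(p1, params["conv2_W"], params["conv2_b"])
    a2 = _relu(z2)
    p2, pc2 = _maxpool2(a2)
    flat = p2.reshape(x.shape[0], -1)
    z3 = flat @ params["fc1_W"] + params["fc1_b"]
    a3 = _relu(z3)
    z4 = a3 @ params["fc2_W"] + params["fc2_b"]
    feat = _relu(z4)
    if want_cache:
        cache = (x, z1, win1, pc1, p1, z2, win2, pc2, flat, z3, a3, z4)
        return feat, cache
    return feat


def backward_encoder(params: Params, cache, dfeat: np.ndarray):
    """Backprop through the encoder; returns (param grads, input grad)."""
    x, z1, win1, pc1, p1, z2, win2, pc2, flat, z3, a3, z4 = cache
    grads: Params = {}

    dz4 = dfeat * (z4 > 0)
    grads["fc2_W"] = a3.T @ dz4
    grads["fc2_b"] = dz4.sum(axis=0)
    da3 = dz4 @ params["fc2_W"].T
    dz3 = da3 * (z3 > 0)
    grads["fc1_W"] = flat.T @ dz3
    grads["fc1_b"] = dz3.sum(axis=0)
    dflat = dz3 @ params["fc1_W"].T
    n_filters = params["conv2_W"].shape[0]
    dp2 = dflat.reshape(x.shape[0], -1, n_filters)
    da2 = _maxpool2_backward(dp2, pc2)
    dz2 = da2 * (z2 > 0)
    grads["conv2_W"], grads["conv2_b"], dp1 = _conv1d_backward(
        dz2, win2, params["conv2_W"], p1.shape
    )
    da1 = _maxpool2_backward(dp1, pc1)
    dz1 = da1 * (z1 > 0)
    grads["conv1_W"], grads["conv1_b"], dx = _conv1d_backward(
        dz1, win1, params["conv1_W"], x.shape
    )
    return grads, dx


# ---------------------------------------------------------------------------
# task predictor


def forward_predictor(params: Params, feat: np.ndarray, want_cache: bool = False):
    """Map feature vectors to a scalar affinity prediction per item
    (linear head, unbounded reals)."""
    feat = np.atleast_2d(np.asarray(feat, dtype=float))
    if not np.isfinite(feat).all():
        raise ValueError("non-finite values in predictor input")
    z1 = feat @ params["fc1_W"] + params["fc1_b"]
    a1 = _relu(z1)
    z2 = a1 @ params["fc2_W"] + params["fc2_b"]
    a2 = _relu(z2)
    out = (a2 @ params["out_W"] + params["out_b"])[:, 0]
    if want_cache:
        return out, (feat, z1, a1, z2, a2)
    return out


def backward_predictor(params: Params, cache, dout: np.ndarray):
    feat, z1, a1, z2, a2 = cache
    grads: Params = {}
    d = np.asarray(dout, dtype=float)[:, None]
    grads["out_W"] = a2.T @ d
    grads["out_b"] = d.sum(axis=0)
    da2 = d @ params["out_W"].T
    dz2 = da2 * (z2 > 0)
    grads["fc2_W"] = a1.T @ dz2
    grads["fc2_b"] = dz2.sum(axis=0)
    da1 = dz2 @ params["fc2_W"].T
    dz1 = da1 * (z1 > 0)
    grads["fc1_W"] = feat.T @ dz1
    grads["fc1_b"] = dz1.sum(axis=0)
    dfeat = dz1 @ params["fc1_W"].T
    return grads, dfeat


# ---------------------------------------------------------------------------
# discriminator


def forward_discriminator(params: Params, feat: np.ndarray, want_cache: bool = False):
    """Score feature vectors as source-like (-> 1) or target-like (-> 0)."""
    feat = np.atleast_2d(np.asarray(feat, dtype=float))
    if not np.isfinite(feat).all():
        raise ValueError("non-finite values in discriminator input")
    z1 = feat @ params["fc1_W"] + params["fc1_b"]
    a1 = _relu(z1)
    logit = (a1 @ params["out_W"] + params["out_b"])[:, 0]
    score = 1.0 / (1.0 + np.exp(-logit))
    if want_cache:
        return score, (feat, z1, a1, score)
    return score


def backward_discriminator(params: Params, cache, dscore: np.ndarray):
    feat, z1, a1, score = cache
    grads: Params = {}
    dlogit = (np.asarray(dscore, dtype=float) * score * (1.0 - score))[:, None]
    grads["out_W"] = a1.T @ dlogit
    grads["out_b"] = dlogit.sum(axis=0)
    da1 = dlogit @ params["out_W"].T
    dz1 = da1 * (z1 > 0)
    grads["fc1_W"] = feat.T @ dz1
    grads["fc1_b"] = dz1.sum(axis=0)
    dfeat = dz1 @ params["fc1_W"].T
    return grads, dfeat


# ---------------------------------------------------------------------------
# bundle, cloning, checkpointing


def _copy_params(p: Params) -> Params:
    return {k: v.copy() for k, v in p.items()}


@dataclass
class ModelBundle:
    """The four parameter collections of one trained (or training) model."""

    params_ms: Params
    params_mt: Params
    params_t: Params
    params_d: Params
    rng_seed: int
    encoder_spec: EncoderSpec = EncoderSpec()
    predictor_spec: PredictorSpec = PredictorSpec()
    discriminator_spec: DiscriminatorSpec = DiscriminatorSpec()
    scale_params_source: tuple[float, float] | None = None
    scale_params_target: tuple[float, float] | None = None
    config_hash: str | None = None

    def copy(self) -> "ModelBundle":
        return replace(
            self,
            params_ms=_copy_params(self.params_ms),
            params_mt=_copy_params(self.params_mt),
            params_t=_copy_params(self.params_t),
            params_d=_copy_params(self.params_d),
        )


def init_bundle(seed: int, encoder_spec: EncoderSpec = EncoderSpec()) -> ModelBundle:
    """Fresh Glorot-initialized bundle; Mt starts as an independent draw
    and is overwritten by :func:`clone_source_to_target` before step 2."""
    rng = np.random.default_rng(seed)
    feature_dim = encoder_spec.fc2_units
    pspec, dspec = PredictorSpec(), DiscriminatorSpec()
    return ModelBundle(
        params_ms=init_encoder_params(rng, encoder_spec),
        params_mt=init_encoder_params(rng, encoder_spec),
        params_t=init_predictor_params(rng, pspec, feature_dim),
        params_d=init_discriminator_params(rng, dspec, feature_dim),
        rng_seed=seed,
        encoder_spec=encoder_spec,
        predictor_spec=pspec,
        discriminator_spec=dspec,
    )


def clone_source_to_target(bundle: ModelBundle) -> ModelBundle:
    """Initialize the target encoder from the source encoder (deep copy,
    so later Mt updates never touch Ms)."""
    for key, val in bundle.params_ms.items():
        if key not in bundle.params_mt or bundle.params_mt[key].shape != val.shape:
            raise ValueError(f"encoder shape mismatch on {key!r}")
    out = bundle.copy()
    out.params_mt = _copy_params(bundle.params_ms)
    return out


_PARTS = ("ms", "mt", "t", "d")


def save_checkpoint(bundle: ModelBundle, path: str | Path) -> None:
    """Write the bundle to a single ``.npz`` archive (versioned schema)."""
    arrays: dict[str, np.ndarray] = {}
    for part in _PARTS:
        for key, val in getattr(bundle, f"params_{part}").items():
            arrays[f"{part}/{key}"] = val
    meta = {
        "schema_version": CHECKPOINT_SCHEMA_VERSION,
        "rng_seed": bundle.rng_seed,
        "encoder_spec": asdict(bundle.encoder_spec),
        "predictor_spec": asdict(bundle.predictor_spec),
        "discriminator_spec": asdict(bundle.discriminator_spec),
        "scale_params_source": bundle.scale_params_source,
        "scale_params_target": bundle.scale_params_target,
        "config_hash": bundle.config_hash,
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> ModelBundle:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        if meta["schema_version"] != CHECKPOINT_SCHEMA_VERSION:
            raise ValueError(f"unsupported checkpoint schema {meta['schema_version']}")
        parts: dict[str, Params] = {p: {} for p in _PARTS}
        for name in npz.files:
            if name == "__meta__":
                continue
            part, key = name.split("/", 1)
            parts[part][key] = npz[name]
    return ModelBundle(
        params_ms=parts["ms"],
        params_mt=parts["mt"],
        params_t=parts["t"],
        params_d=parts["d"],
        rng_seed=meta["rng_seed"],
        encoder_spec=EncoderSpec(**meta["encoder_spec"]),
        predictor_spec=PredictorSpec(**meta["predictor_spec"]),
        discriminator_spec=DiscriminatorSpec(**meta["discriminator_spec"]),
        scale_params_source=None
        if meta["scale_params_source"] is None
        else tuple(meta["scale_params_source"]),
        scale_params_target=None
        if meta["scale_params_target"] is None
        else tuple(meta["scale_params_target"]),
        config_hash=meta["config_hash"],
    )


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with the usual default moments (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params: Params, lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2, self.eps = b1, b2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# convenience forwards used by attribution and evaluation


def predict(bundle: ModelBundle, x: np.ndarray, encoder: str = "source") -> np.ndarray:
    """T(M(x)) with the requested encoder ('source' -> Ms, 'target' -> Mt)."""
    enc = bundle.params_ms if encoder == "source" else bundle.params_mt
    return forward_predictor(bundle.params_t, forward_encoder(enc, x))


def prediction_input_gradient(bundle: ModelBundle, x: np.ndarray, encoder: str = "source") -> np.ndarray:
    """d prediction / d input, per item — the primitive behind integrated
    gradients."""
    enc_params = bundle.params_ms if encoder == "source" else bundle.params_mt
    feat, enc_cache = forward_encoder(enc_params, x, want_cache=True)
    _, pred_cache = forward_predictor(bundle.params_t, feat, want_cache=True)
    _, dfeat = backward_predictor(bundle.params_t, pred_cache, np.ones(feat.shape[0]))
    _, dx = backward_encoder(enc_params, enc_cache, dfeat)
    return dx
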
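"""The three-step adversarial domain-adaptation training strategy.

Step 1 (pre-training) fits the source encoder Ms and the task predictor
T on labeled source data under a plain squared-error loss.  Step 2
(domain adaptation) initializes the target encoder Mt from Ms and then
alternates, once each per iteration, a least-squares discriminator
update (source features -> 1, target features -> 0) with a target-network
update whose loss combines fooling the discriminator (target features
-> 1) with supervised squared error on target labels; Ms and T stay
frozen.  Step 3 (fine-tuning) freezes both encoders and nudges only T,
at a much smaller learning rate, on source and target batches
simultaneously.

Predictions route by domain: target-domain sequences go through T(Mt(x)),
source-domain sequences through T(Ms(x)).

Two reduced modes exist: ``without_adda`` skips step 2 entirely (the
ablation; Mt remains an exact copy of Ms), and ``reversed`` swaps the
roles of the two datasets before training.

All squared terms are batch means, so learning rates are independent of
batch size.  The optimizer is Adam with default moments throughout; only
the learning rates differ per step.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .augmentation import AugmentationConfig, apply_augmentation_array
from .model_core import (
    Adam,
    EncoderSpec,
    ModelBundle,
    backward_discriminator,
    backward_encoder,
    backward_predictor,
    clone_source_to_target,
    forward_discriminator,
    forward_encoder,
    forward_predictor,
    init_bundle,
)
from .seq_encoding import DomainDataset, encode_dataset


class Mode(str, enum.Enum):
    FULL_ADDA = "full_adda"
    WITHOUT_ADDA = "without_adda"
    REVERSED = "reversed"


@dataclass
class TrainingConfig:
    """Iteration budgets, learning rates and mode for one training run.

    ``n1``/``n2``/``n3`` left as None are derived from ``max_epochs``
    (one epoch = ceil(n_samples / batch_size) minibatches).
    """

    n1: int | None = None
    n2: int | None = None
    n3: int | None = None
    batch_size: int = 256
    lr_pretrain: float = 0.001
    lr_target: float = 0.001
    lr_discriminator: float = 0.00005
    lr_finetune: float = 0.00005
    max_epochs: int = 1000
    seed: int = 0
    mode: Mode = Mode.FULL_ADDA
    augmentation: AugmentationConfig | None = None
    early_stop_patience: int | None = None  # off by default
    n_filters: int = 32       # grid-search knobs; defaults are the tuned values
    filter_width: int = 4

    def __post_init__(self) -> None:
        self.mode = Mode(self.mode)
        for name in ("lr_pretrain", "lr_target", "lr_discriminator", "lr_finetune"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def budget(self, which: str, n_samples: int) -> int:
        explicit = getattr(self, which)
        if explicit is not None:
            return explicit
        return self.max_epochs * math.ceil(n_samples / self.batch_size)


@dataclass
class TrainingTrace:
    """Append-only per-iteration loss log plus final evaluation slots."""

    records: list[tuple[str, int, str, float]] = field(default_factory=list)
    final_pearson: dict[str, float] = field(default_factory=dict)

    def add(self, step: str, iteration: int, loss_name: str, value: float) -> None:
        if not np.isfinite(value):
            raise RuntimeError(
                f"non-finite {loss_name} at {step} iteration {iteration} "
                "(training diverged)"
            )
        self.records.append((step, iteration, loss_name, float(value)))

    def losses(self, step: str, loss_name: str) -> list[float]:
        return [v for s, _, n, v in self.records if s == step and n == loss_name]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("step\titeration\tloss\tvalue\n")
            for rec in self.records:
                fh.write("\t".join(str(x) for x in rec) + "\n")


# ---------------------------------------------------------------------------
# the four losses (Algorithm steps reference these directly)


def loss_pretrain(preds: np.ndarray, labels: np.ndarray) -> float:
    """Mean squared error of source predictions (step-1 objective)."""
    preds, labels = np.asarray(preds, float), np.asarray(labels, float)
    if preds.size == 0 or preds.shape != labels.shape:
        raise ValueError("preds and labels must be equal-length and non-empty")
    return float(np.mean((preds - labels) ** 2))


def loss_discriminator(d_source: np.ndarray, d_target: np.ndarray) -> float:
    """Least-squares discriminator loss: source scores toward 1, target
    scores toward 0, halved sum of the two batch means."""
    d_source, d_target = np.asarray(d_source, float), np.asarray(d_target, float)
    return float(0.5 * (np.mean((d_source - 1.0) ** 2) + np.mean(d_target**2)))


def loss_target(d_target: np.ndarray, preds_target: np.ndarray, labels_target: np.ndarray) -> float:
    """Target-network loss: fool the discriminator (scores toward 1) plus
    supervised squared error on target labels."""
    d_target = np.asarray(d_target, float)
    adv = float(np.mean((d_target - 1.0) ** 2))
    return adv + loss_pretrain(preds_target, labels_target)


def loss_finetune(
    preds_source: np.ndarray,
    labels_source: np.ndarray,
    preds_target: np.ndarray,
    labels_target: np.ndarray,
) -> float:
    """Fine-tuning loss: squared error summed over both domains."""
    return loss_pretrain(preds_source, labels_source) + loss_pretrain(
        preds_target, labels_target
    )


# ---------------------------------------------------------------------------
# minibatch stream


class _BatchStream:
    """Uniform sampling without replacement per epoch, reshuffled each
    epoch; one independent stream per domain."""

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator):
        self.n = n
        self.m = min(batch_size, n)
        self.rng = rng
        self._order = rng.permutation(n)
        self._pos = 0

    def next(self) -> np.ndarray:
        if self._pos + self.m > self.n:
            self._order = self.rng.permutation(self.n)
            self._pos = 0
        idx = self._order[self._pos : self._pos + self.m]
        self._pos += self.m
        return idx


def _maybe_augment(Xb, lengths_b, cfg: TrainingConfig, rng) -> np.ndarray:
    if cfg.augmentation is None:
        return Xb
    return apply_augmentation_array(Xb, lengths_b, cfg.augmentation, rng)


# ---------------------------------------------------------------------------
# step 1: source pre-training


def pretrain_source(
    bundle: ModelBundle, source: DomainDataset, cfg: TrainingConfig
) -> tuple[ModelBundle, TrainingTrace]:
    """Train Ms and T on labeled source data (only those two collections
    are updated)."""
    if len(source) == 0:
        raise ValueError("empty source dataset")
    X, y, lengths = encode_dataset(source)
    bundle = bundle.copy()
    trace = TrainingTrace()
    n_iters = cfg.budget("n1", len(source))

    ss = np.random.SeedSequence([cfg.seed, 1])
    rng_batch, rng_aug = (np.random.default_rng(s) for s in ss.spawn(2))
    stream = _BatchStream(len(source), cfg.batch_size, rng_batch)
    opt_ms = Adam(bundle.params_ms, cfg.lr_pretrain)
    opt_t = Adam(bundle.params_t, cfg.lr_pretrain)

    for it in range(n_iters):
        idx = stream.next()
        Xb = _maybe_augment(X[idx], lengths[idx], cfg, rng_aug)
        yb = y[idx]
        feat, enc_cache = forward_encoder(bundle.params_ms, Xb, want_cache=True)
        preds, pred_cache = forward_predictor(bundle.params_t, feat, want_cache=True)
        loss = loss_pretrain(preds, yb)
        trace.add("pretrain", it, "mse_source", loss)
        dpred = 2.0 * (preds - yb) / len(yb)
        grads_t, dfeat = backward_predictor(bundle.params_t, pred_cache, dpred)
        grads_ms, _ = backward_encoder(bundle.params_ms, enc_cache, dfeat)
        opt_t.step(bundle.params_t, grads_t)
        opt_ms.step(bundle.params_ms, grads_ms)
    return bundle, trace


# ---------------------------------------------------------------------------
# step 2: adversarial domain adaptation


def adapt_target(
    bundle: ModelBundle,
    source: DomainDataset,
    target: DomainDataset,
    cfg: TrainingConfig,
) -> tuple[ModelBundle, TrainingTrace]:
    """Initialize Mt from Ms, then alternate one discriminator update and
    one target-network update per iteration.  Ms and T are frozen; only
    Mt and D change.

    With ``early_stop_patience`` set, 20% of the target training data is
    held out and split in half into a selection fold and a confirmation
    fold.  Every few iterations the Pearson correlation of target
    predictions on the selection fold is evaluated (the metric of record
    — squared error can improve through recalibration while the ranking
    degrades), the best Mt snapshot is kept, and training stops after
    ``patience`` evaluations without improvement.  The adapted encoder
    is finally retained only if, on the untouched confirmation fold, its
    correlation beats the clone point's by more than one bootstrap
    standard error; otherwise Mt reverts to the clone of Ms.  The
    two-fold design is a do-no-harm rule: the best-of-many-snapshots
    selection estimate is upward-biased, so acceptance is decided on
    data that played no part in the selection.
    """
    Xs, _, len_s = encode_dataset(source)
    Xt, yt, len_t = encode_dataset(target)
    bundle = clone_source_to_target(bundle)
    trace = TrainingTrace()
    n_iters = cfg.budget("n2", len(target))

    ss = np.random.SeedSequence([cfg.seed, 2])
    rng_s, rng_t, rng_aug, rng_val = (np.random.default_rng(s) for s in ss.spawn(4))

    fit_idx = np.arange(len(target))
    val_idx = np.array([], dtype=int)
    if cfg.early_stop_patience is not None and len(target) >= 10:
        perm = rng_val.permutation(len(target))
        n_val = max(1, len(target) // 5)
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
    X_fit, y_fit, len_fit = Xt[fit_idx], yt[fit_idx], len_t[fit_idx]
    eval_every = 10

    n_sel = len(val_idx) // 2  # first half selects, second half confirms

    def _val_preds() -> np.ndarray:
        feats = forward_encoder(bundle.params_mt, Xt[val_idx])
        return forward_predictor(bundle.params_t, feats)

    def _corr(preds: np.ndarray, obs: np.ndarray) -> float:
        if np.ptp(preds) == 0 or np.ptp(obs) == 0:
            return -np.inf
        return float(np.corrcoef(preds, obs)[0, 1])

    y_val = yt[val_idx]
    clone_preds = _val_preds() if val_idx.size else None
    best_r = _corr(clone_preds[:n_sel], y_val[:n_sel]) if val_idx.size else -np.inf
    best_preds = clone_preds
    best_mt = {k: v.copy() for k, v in bundle.params_mt.items()}
    clone_mt = best_mt
    stale = 0

    stream_s = _BatchStream(len(source), cfg.batch_size, rng_s)
    stream_t = _BatchStream(len(fit_idx), cfg.batch_size, rng_t)
    opt_d = Adam(bundle.params_d, cfg.lr_discriminator)
    opt_mt = Adam(bundle.params_mt, cfg.lr_target)

    for it in range(n_iters):
        idx_s, idx_t = stream_s.next(), stream_t.next()
        Xs_b = _maybe_augment(Xs[idx_s], len_s[idx_s], cfg, rng_aug)
        Xt_b = _maybe_augment(X_fit[idx_t], len_fit[idx_t], cfg, rng_aug)
        yt_b = y_fit[idx_t]

        # --- discriminator update (source -> 1, target -> 0)
        feat_s = forward_encoder(bundle.params_ms, Xs_b)
        feat_t = forward_encoder(bundle.params_mt, Xt_b)
        d_s, cache_ds = forward_discriminator(bundle.params_d, feat_s, want_cache=True)
        d_t, cache_dt = forward_discriminator(bundle.params_d, feat_t, want_cache=True)
        trace.add("adapt", it, "disc", loss_discriminator(d_s, d_t))
        grads_s, _ = backward_discriminator(bundle.params_d, cache_ds, (d_s - 1.0) / len(d_s))
        grads_t, _ = backward_discriminator(bundle.params_d, cache_dt, d_t / len(d_t))
        opt_d.step(bundle.params_d, {k: grads_s[k] + grads_t[k] for k in grads_s})

        # --- target-network update (fool D toward 1, fit target labels)
        feat_t, enc_cache = forward_encoder(bundle.params_mt, Xt_b, want_cache=True)
        d_t, cache_d = forward_discriminator(bundle.params_d, feat_t, want_cache=True)
        preds_t, cache_p = forward_predictor(bundle.params_t, feat_t, want_cache=True)
        trace.add("adapt", it, "target", loss_target(d_t, preds_t, yt_b))
        _, dfeat_adv = backward_discriminator(
            bundle.params_d, cache_d, 2.0 * (d_t - 1.0) / len(d_t)
        )
        _, dfeat_sup = backward_predictor(
            bundle.params_t, cache_p, 2.0 * (preds_t - yt_b) / len(yt_b)
        )
        grads_mt, _ = backward_encoder(bundle.params_mt, enc_cache, dfeat_adv + dfeat_sup)
        opt_mt.step(bundle.params_mt, grads_mt)

        if val_idx.size and (it + 1) % eval_every == 0:
            preds = _val_preds()
            r = _corr(preds[:n_sel], y_val[:n_sel])
            trace.add("adapt", it, "val_pearson", r if np.isfinite(r) else -1.0)
            if r > best_r + 1e-6:
                best_r, stale = r, 0
                best_preds = preds
                best_mt = {k: v.copy() for k, v in bundle.params_mt.items()}
            else:
                stale += 1
                if stale > cfg.early_stop_patience:
                    break
    if val_idx.size:
        # accept/reject on the confirmation fold only, with a paired
        # bootstrap margin for the correlation difference
        y_conf = y_val[n_sel:]
        best_conf, clone_conf = best_preds[n_sel:], clone_preds[n_sel:]
        n_conf = len(y_conf)
        boot_idx = rng_val.integers(0, n_conf, size=(200, n_conf))
        deltas = np.array(
            [_corr(best_conf[b], y_conf[b]) - _corr(clone_conf[b], y_conf[b]) for b in boot_idx]
        )
        deltas = deltas[np.isfinite(deltas)]
        margin = float(deltas.std(ddof=1)) if deltas.size > 1 else np.inf
        delta = _corr(best_conf, y_conf) - _corr(clone_conf, y_conf)
        keep_adapted = np.isfinite(delta) and delta > margin
        bundle.params_mt = best_mt if keep_adapted else {k: v.copy() for k, v in clone_mt.items()}
    return bundle, trace


# ---------------------------------------------------------------------------
# step 3: predictor fine-tuning


def finetune_predictor(
    bundle: ModelBundle,
    source: DomainDataset,
    target: DomainDataset,
    cfg: TrainingConfig,
) -> tuple[ModelBundle, TrainingTrace]:
    """Update only T, at the fine-tuning learning rate, on source and
    target minibatches simultaneously (both encoders frozen)."""
    Xs, ys, len_s = encode_dataset(source)
    Xt, yt, len_t = encode_dataset(target)
    bundle = bundle.copy()
    trace = TrainingTrace()
    n_iters = cfg.budget("n3", max(len(source), len(target)))

    ss = np.random.SeedSequence([cfg.seed, 3])
    rng_s, rng_t, rng_aug = (np.random.default_rng(s) for s in ss.spawn(3))
    stream_s = _BatchStream(len(source), cfg.batch_size, rng_s)
    stream_t = _BatchStream(len(target), cfg.batch_size, rng_t)
    opt_t = Adam(bundle.params_t, cfg.lr_finetune)

    for it in range(n_iters):
        idx_s, idx_t = stream_s.next(), stream_t.next()
        Xs_b = _maybe_augment(Xs[idx_s], len_s[idx_s], cfg, rng_aug)
        Xt_b = _maybe_augment(Xt[idx_t], len_t[idx_t], cfg, rng_aug)
        ys_b, yt_b = ys[idx_s], yt[idx_t]

        feat_s = forward_encoder(bundle.params_ms, Xs_b)
        feat_t = forward_encoder(bundle.params_mt, Xt_b)
        preds_s, cache_s = forward_predictor(bundle.params_t, feat_s, want_cache=True)
        preds_t, cache_t = forward_predictor(bundle.params_t, feat_t, want_cache=True)
        trace.add("finetune", it, "finetune", loss_finetune(preds_s, ys_b, preds_t, yt_b))
        grads_a, _ = backward_predictor(bundle.params_t, cache_s, 2.0 * (preds_s - ys_b) / len(ys_b))
        grads_b, _ = backward_predictor(bundle.params_t, cache_t, 2.0 * (preds_t - yt_b) / len(yt_b))
        opt_t.step(bundle.params_t, {k: grads_a[k] + grads_b[k] for k in grads_a})
    return bundle, trace


# ---------------------------------------------------------------------------
# full pipeline


def train_full(
    source: DomainDataset,
    target: DomainDataset,
    cfg: TrainingConfig,
    callback=None,
) -> tuple[ModelBundle, TrainingTrace]:
    """Run steps 1 -> 2 -> 3 from a fresh seeded initialization.

    ``without_adda`` skips step 2 (Mt stays a clone of Ms); ``reversed``
    swaps the roles of the two datasets first.  ``callback(step, bundle)``
    if given is invoked after each step, e.g. for per-step evaluation.
    """
    if cfg.mode is Mode.REVERSED:
        source, target = target, source
        cfg = replace(cfg, mode=Mode.FULL_ADDA)

    bundle = init_bundle(
        cfg.seed, EncoderSpec(n_filters=cfg.n_filters, filter_width=cfg.filter_width)
    )
    bundle, trace1 = pretrain_source(bundle, source, cfg)
    if callback:
        callback("pretrain", bundle)

    if cfg.mode is Mode.WITHOUT_ADDA:
        bundle = clone_source_to_target(bundle)
        trace2 = TrainingTrace()
    else:
        bundle, trace2 = adapt_target(bundle, source, target, cfg)
    if callback:
        callback("adapt", bundle)

    bundle, trace3 = finetune_predictor(bundle, source, target, cfg)
    if callback:
        callback("finetune", bundle)

    trace = TrainingTrace(trace1.records + trace2.records + trace3.records)
    return bundle, trace
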
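"""Training-time sequence augmentation: Replacement, Swap, Gap.

All three operators act on the encoded representation and only ever
touch non-pad rows (positions below ``active_length``).  They are
applied per epoch to fresh copies of training batches, so the stored
dataset is never mutated and labels are untouched — the perturbation is
temporary by construction.  Validation and test data are never
augmented.

* Replacement: a randomly chosen position's row becomes a copy of an
  adjacent position's row (left or right by coin flip; sequence ends use
  the only available neighbor).  "Neighboring nucleotide" is read
  positionally, not as a chemically similar base.
* Swap: two distinct positions exchange rows, conserving per-channel
  column sums.
* Gap: a chosen position's row is overwritten with ``[0.3, 0.2, 0.2,
  0.3]`` — a soft removal that keeps the row sum at 1 and the sequence
  length unchanged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .seq_encoding import GAP_ROW, EncodedSequence


class Operator(str, enum.Enum):
    REPLACEMENT = "replacement"
    SWAP = "swap"
    GAP = "gap"
    NONE = "none"


@dataclass
class AugmentationConfig:
    """Defaults are the best-performing setting: one nucleotide per
    sequence, every training sequence augmented."""

    operator: Operator = Operator.NONE
    positions_per_seq: int = 1
    fraction_augmented: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.operator = Operator(self.operator)
        if not 0 <= self.positions_per_seq <= 5:
            raise ValueError("positions_per_seq must be in 0..5")
        if not 0.0 <= self.fraction_augmented <= 1.0:
            raise ValueError("fraction_augmented must be in [0, 1]")


def _check_n(n: int, active_length: int) -> None:
    if n < 0:
        raise ValueError("n must be non-negative")
    if n > active_length:
        raise ValueError(f"n={n} exceeds active_length={active_length}")


def augment_replacement(enc: EncodedSequence, n: int, rng: np.random.Generator) -> EncodedSequence:
    """Copy an adjacent position's row onto each of ``n`` chosen positions."""
    _check_n(n, enc.active_length)
    out = enc.copy()
    if n == 0:
        return out
    positions = rng.choice(enc.active_length, size=n, replace=False)
    original = enc.values  # read neighbors from the unmodified input
    for pos in positions:
        if pos == 0:
            neighbor = 1
        elif pos == enc.active_length - 1:
            neighbor = pos - 1
        else:
            neighbor = pos + (1 if rng.random() < 0.5 else -1)
        out.values[pos] = original[neighbor]
    return out


def augment_swap(enc: EncodedSequence, n: int, rng: np.random.Generator) -> EncodedSequence:
    """Apply ``n`` swap events, each exchanging two distinct non-pad rows."""
    if enc.active_length < 2:
        raise ValueError("swap needs active_length >= 2")
    if n < 0:
        raise ValueError("n must be non-negative")
    out = enc.copy()
    for _ in range(n):
        i, j = rng.choice(enc.active_length, size=2, replace=False)
        out.values[[i, j]] = out.values[[j, i]]
    return out


def augment_gap(enc: EncodedSequence, n: int, rng: np.random.Generator) -> EncodedSequence:
    """Overwrite ``n`` chosen non-pad rows with the gap vector."""
    _check_n(n, enc.active_length)
    out = enc.copy()
    if n == 0:
        return out
    positions = rng.choice(enc.active_length, size=n, replace=False)
    out.values[positions] = GAP_ROW
    return out


_OPERATORS = {
    Operator.REPLACEMENT: augment_replacement,
    Operator.SWAP: augment_swap,
    Operator.GAP: augment_gap,
}


def apply_augmentation(
    batch: list[EncodedSequence],
    cfg: AugmentationConfig,
    rng: np.random.Generator,
) -> list[EncodedSequence]:
    """Augment a ``fraction_augmented`` Bernoulli share of the batch.

    Returns fresh :class:`EncodedSequence` objects; the input batch is
    never modified.
    """
    if cfg.operator is Operator.NONE or cfg.positions_per_seq == 0:
        return [enc.copy() for enc in batch]
    op = _OPERATORS[cfg.operator]
    out = []
    for enc in batch:
        if rng.random() < cfg.fraction_augmented:
            out.append(op(enc, cfg.positions_per_seq, rng))
        else:
            out.append(enc.copy())
    return out


def apply_augmentation_array(
    X: np.ndarray,
    active_lengths: np.ndarray,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Array form used inside training loops: ``X`` is ``(B, 41, 4)``.

    Always returns a copy; the caller's arrays are left untouched.
    """
    if cfg.operator is Operator.NONE or cfg.positions_per_seq == 0:
        return X.copy()
    op = _OPERATORS[cfg.operator]
    out = X.copy()
    for i in range(X.shape[0]):
        if rng.random() < cfg.fraction_augmented:
            enc = EncodedSequence(out[i].copy(), int(active_lengths[i]))
            out[i] = op(enc, cfg.positions_per_seq, rng).values
    return out
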
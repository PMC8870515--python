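"""Sequence I/O, length normalization, one-hot encoding and label scaling.

Two labeled-sequence domains are handled throughout the package: a
high-signal *source* domain (RNAcompete-style probe intensities) and a
noisier *target* domain (eCLIP-style peak signal).  Both arrive as RNA
fragments paired with real-valued binding intensities; this module turns
them into the fixed-shape numeric arrays the networks consume.

Conventions
-----------
* Alphabet ``{A, C, G, U, N}``; ``T`` is transliterated to ``U`` on read
  (eCLIP-derived sequences are commonly DNA-alphabet).
* Channel order is alphabetical: A, C, G, U.
* Network input length is 41 (the maximum RNAcompete probe length);
  shorter fragments are right-padded with all-zero rows, ``N`` is the
  all-zero row as well.
* Peaks longer than 41 nt are tiled into equal-length windows that
  overlap by 10 nt; peaks shorter than 26 nt are symmetrically extended
  to 26 with ``N``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

ALPHABET = "ACGUN"
CHANNELS = "ACGU"
#: row used by the Gap augmentation operator and the attribution baseline
GAP_ROW = np.array([0.3, 0.2, 0.2, 0.3])

MIN_LEN = 26
MAX_LEN = 41
WINDOW_OVERLAP = 10

_BASE_TO_CHANNEL = {b: i for i, b in enumerate(CHANNELS)}


class Domain(str, enum.Enum):
    """Which measurement platform a record came from."""

    SOURCE = "source"  # in vitro style (high signal-to-noise)
    TARGET = "target"  # in vivo style (low signal-to-noise)


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA fragment with provenance."""

    bases: str
    source_id: str
    domain: Domain

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("empty sequence")
        bad = set(self.bases) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"invalid characters {sorted(bad)!r} in sequence {self.source_id!r}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class EncodedSequence:
    """One network input: a ``pad_to x 4`` array plus its non-pad length.

    Rows are one-hot (A,C,G,U), all-zero (``N`` or padding), or the gap
    row ``[0.3, 0.2, 0.2, 0.3]`` introduced by augmentation.
    """

    values: np.ndarray
    active_length: int

    def copy(self) -> "EncodedSequence":
        return EncodedSequence(self.values.copy(), self.active_length)


@dataclass
class DomainDataset:
    """Index-aligned fragments and intensities for one domain."""

    sequences: list[RnaSequence]
    raw_labels: np.ndarray
    domain: Domain
    scaled_labels: np.ndarray | None = None
    scale_params: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.raw_labels = np.asarray(self.raw_labels, dtype=float)
        if len(self.sequences) != len(self.raw_labels):
            raise ValueError("sequences and labels differ in length")
        for seq in self.sequences:
            if seq.domain is not self.domain:
                raise ValueError("sequence domain tag does not match dataset")

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, indices: Sequence[int]) -> "DomainDataset":
        idx = np.asarray(indices, dtype=int)
        return DomainDataset(
            sequences=[self.sequences[i] for i in idx],
            raw_labels=self.raw_labels[idx],
            domain=self.domain,
            scaled_labels=None if self.scaled_labels is None else self.scaled_labels[idx],
            scale_params=self.scale_params,
        )


# ---------------------------------------------------------------------------
# reading


def _clean_bases(raw: str, where: str) -> str:
    bases = raw.strip().upper().replace("T", "U")
    bad = set(bases) - set(ALPHABET)
    if bad:
        raise ValueError(f"{where}: invalid characters {sorted(bad)!r}")
    if not bases:
        raise ValueError(f"{where}: empty sequence")
    return bases


def read_affinity_table(
    path: str | Path,
    domain: Domain | str,
    score_key: str = "score",
) -> DomainDataset:
    """Read a labeled sequence table into a :class:`DomainDataset`.

    Two formats are accepted:

    * two-column TSV ``sequence<TAB>intensity`` (no header, ``#`` comments)
    * FASTA with the intensity in the header as ``<score_key>=<float>``

    Labels are returned raw; scaling and length normalization are separate
    steps so they can be fit on training splits only.
    """
    path = Path(path)
    domain = Domain(domain)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")

    if text.lstrip().startswith(">"):
        return _read_fasta_scores(path, domain, score_key)

    sequences: list[RnaSequence] = []
    labels: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields")
        bases = _clean_bases(parts[0], f"{path}: line {lineno}")
        try:
            score = float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric score {parts[1]!r}") from exc
        sequences.append(RnaSequence(bases, f"{path.stem}:{lineno}", domain))
        labels.append(score)
    if not sequences:
        raise ValueError(f"{path}: no records")
    return DomainDataset(sequences, np.array(labels), domain)


def _read_fasta_scores(path: Path, domain: Domain, score_key: str) -> DomainDataset:
    from Bio import SeqIO

    sequences: list[RnaSequence] = []
    labels: list[float] = []
    marker = f"{score_key}="
    for i, record in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        header = record.description
        token = next((t for t in header.split() if t.startswith(marker)), None)
        if token is None:
            raise ValueError(f"{path}: record {i} ({record.id}): no '{marker}' token in header")
        try:
            score = float(token[len(marker):])
        except ValueError as exc:
            raise ValueError(f"{path}: record {i}: non-numeric score {token!r}") from exc
        bases = _clean_bases(str(record.seq), f"{path}: record {i}")
        sequences.append(RnaSequence(bases, record.id, domain))
        labels.append(score)
    if not sequences:
        raise ValueError(f"{path}: no FASTA records")
    return DomainDataset(sequences, np.array(labels), domain)


# ---------------------------------------------------------------------------
# peak-length normalization


def normalize_peak_length(
    seq: RnaSequence,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    overlap: int = WINDOW_OVERLAP,
) -> list[RnaSequence]:
    """Bring one fragment into the [min_len, max_len] length band.

    * already in band: returned unchanged;
    * shorter: symmetrically extended to ``min_len`` with ``N`` (the odd
      leftover base goes to the right end);
    * longer: split into ``k`` equal-length windows overlapping by
      ``overlap`` nt, with ``k`` the smallest count whose window length
      ``w = ceil((L + overlap*(k-1)) / k)`` fits under ``max_len``.
      Windows tile left to right at stride ``w - overlap``; the last
      window is right-anchored at the fragment end, so the final pair may
      overlap by slightly more than ``overlap`` when the arithmetic is
      not exact.

    Emitted window ids carry 1-based inclusive coordinates, e.g.
    ``peak7:1-30``.
    """
    if overlap >= max_len:
        raise ValueError("overlap must be smaller than max_len")
    L = len(seq)
    if min_len <= L <= max_len:
        return [seq]
    if L < min_len:
        deficit = min_len - L
        left = deficit // 2
        right = deficit - left
        bases = "N" * left + seq.bases + "N" * right
        return [RnaSequence(bases, f"{seq.source_id}|padded", seq.domain)]

    # k smallest with w <= max_len  <=>  k >= (L - overlap) / (max_len - overlap)
    k = math.ceil((L - overlap) / (max_len - overlap))
    w = math.ceil((L + overlap * (k - 1)) / k)
    starts = [i * (w - overlap) for i in range(k)]
    starts[-1] = L - w  # right-anchor the final window
    out = []
    for start in starts:
        bases = seq.bases[start : start + w]
        ident = f"{seq.source_id}:{start + 1}-{start + w}"
        out.append(RnaSequence(bases, ident, seq.domain))
    return out


def normalize_dataset(ds: DomainDataset) -> DomainDataset:
    """Apply :func:`normalize_peak_length` to every record; windows split
    from one peak inherit its label."""
    sequences: list[RnaSequence] = []
    labels: list[float] = []
    for seq, y in zip(ds.sequences, ds.raw_labels):
        for win in normalize_peak_length(seq):
            sequences.append(win)
            labels.append(y)
    return DomainDataset(sequences, np.array(labels), ds.domain)


# ---------------------------------------------------------------------------
# encoding


def encode_one_hot(seq: RnaSequence, pad_to: int = MAX_LEN) -> EncodedSequence:
    """One-hot encode with channel order A, C, G, U; ``N`` and padding are
    all-zero rows."""
    L = len(seq)
    if L > pad_to:
        raise ValueError(
            f"sequence {seq.source_id!r} has length {L} > {pad_to}; "
            "run normalize_peak_length first"
        )
    values = np.zeros((pad_to, 4))
    for i, base in enumerate(seq.bases):
        if base != "N":
            values[i, _BASE_TO_CHANNEL[base]] = 1.0
    return EncodedSequence(values, L)


def decode_one_hot(enc: EncodedSequence) -> str:
    """Inverse of :func:`encode_one_hot` on non-augmented rows."""
    out = []
    for i in range(enc.active_length):
        row = enc.values[i]
        if not row.any():
            out.append("N")
            continue
        hot = np.flatnonzero(row == 1.0)
        if len(hot) != 1 or row.sum() != 1.0:
            raise ValueError(f"row {i} is not one-hot: {row}")
        out.append(CHANNELS[hot[0]])
    return "".join(out)


def encode_dataset(ds: DomainDataset, pad_to: int = MAX_LEN):
    """Stack a dataset into network arrays.

    Returns ``(X, y, active_lengths)`` with ``X`` shaped
    ``(n, pad_to, 4)`` and ``y`` the scaled labels (falls back to raw
    labels when scaling has not been applied).
    """
    X = np.stack([encode_one_hot(s, pad_to).values for s in ds.sequences])
    y = ds.scaled_labels if ds.scaled_labels is not None else ds.raw_labels
    lengths = np.array([len(s) for s in ds.sequences], dtype=int)
    return X, np.asarray(y, dtype=float), lengths


# ---------------------------------------------------------------------------
# label scaling


def scale_labels(raw: Sequence[float]) -> tuple[np.ndarray, tuple[float, float]]:
    """Affine min-max map of intensities onto [-1, 1].

    Returns the scaled values and ``(min, max)`` so the map can be
    inverted and applied to held-out labels.  Fit this on the training
    split only.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least 2 label values to fit a scale")
    lo, hi = float(raw.min()), float(raw.max())
    if hi <= lo:
        raise ValueError("constant labels: scaling is undefined (uninformative dataset)")
    return apply_scale(raw, (lo, hi)), (lo, hi)


def apply_scale(raw: Sequence[float], scale_params: tuple[float, float]) -> np.ndarray:
    lo, hi = scale_params
    return 2.0 * (np.asarray(raw, dtype=float) - lo) / (hi - lo) - 1.0


def inverse_scale(scaled: Sequence[float], scale_params: tuple[float, float]) -> np.ndarray:
    lo, hi = scale_params
    return (np.asarray(scaled, dtype=float) + 1.0) / 2.0 * (hi - lo) + lo


def scale_dataset(ds: DomainDataset, scale_params: tuple[float, float] | None = None) -> DomainDataset:
    """Return a copy with scaled labels; fits the scale on this dataset's
    own labels unless ``scale_params`` (from a training split) is given."""
    if scale_params is None:
        scaled, scale_params = scale_labels(ds.raw_labels)
    else:
        scaled = apply_scale(ds.raw_labels, scale_params)
    return DomainDataset(
        sequences=list(ds.sequences),
        raw_labels=ds.raw_labels.copy(),
        domain=ds.domain,
        scaled_labels=scaled,
        scale_params=scale_params,
    )
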
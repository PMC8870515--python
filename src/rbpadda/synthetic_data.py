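"""Synthetic domain-shifted affinity data with a planted motif.

The generator emulates the structure of paired in vitro / in vivo RBP
binding data: both domains share one true sequence preference (a planted
motif whose best ungapped match score drives a continuous affinity), but
the target domain has fewer sequences, a lower signal-to-noise ratio,
and optionally a confounder motif that perturbs its labels.  Every other
module is testable against the retained ground truth without any
downloads.

Affinity model:  raw = motif_strength * match(seq, motif) + noise, with
``match`` the best fraction of matching positions over all ungapped
offsets (1.0 when the motif is present verbatim) and noise Gaussian at
the domain's standard deviation.  Target labels additionally receive
half-strength credit for the confounder motif when one is configured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seq_encoding import (
    CHANNELS,
    Domain,
    DomainDataset,
    RnaSequence,
    read_affinity_table,
    scale_dataset,
)


@dataclass
class SimulationConfig:
    """Defaults define the package's reference scenario: a UGUGU-driven
    affinity, 2000 source vs 800 target sequences, and 3x target noise."""

    motif: str = "UGUGU"
    n_source: int = 2000
    n_target: int = 800
    seq_len_range: tuple[int, int] = (26, 41)
    source_noise_sd: float = 0.1
    target_noise_sd: float = 0.3
    confounder_motif: str | None = "CCACC"
    confounder_strength: float = 0.5
    motif_strength: float = 1.0
    motif_fraction: float = 0.7
    background_base_probs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.motif) - set("ACGU"):
            raise ValueError("motif must be over {A,C,G,U}")
        if self.confounder_motif and set(self.confounder_motif) - set("ACGU"):
            raise ValueError("confounder motif must be over {A,C,G,U}")
        if self.source_noise_sd < 0 or self.target_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if abs(sum(self.background_base_probs) - 1.0) > 1e-9:
            raise ValueError("background_base_probs must sum to 1")
        if len(self.motif) > self.seq_len_range[0]:
            raise ValueError("motif longer than the minimum sequence length")
        if not 0.0 <= self.motif_fraction <= 1.0:
            raise ValueError("motif_fraction must be in [0, 1]")


def best_match_score(seq: str, motif: str) -> float:
    """Best ungapped match fraction of ``motif`` against ``seq``."""
    k = len(motif)
    if len(seq) < k:
        return 0.0
    best = 0
    for off in range(len(seq) - k + 1):
        hits = sum(a == b for a, b in zip(seq[off : off + k], motif))
        if hits > best:
            best = hits
    return best / k


def _simulate_domain(
    cfg: SimulationConfig,
    domain: Domain,
    n: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> tuple[DomainDataset, list[dict]]:
    lo, hi = cfg.seq_len_range
    probs = np.asarray(cfg.background_base_probs)
    sequences: list[RnaSequence] = []
    raw: list[float] = []
    truth: list[dict] = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        bases = list(rng.choice(list(CHANNELS), size=L, p=probs))
        planted_at = None
        if rng.random() < cfg.motif_fraction:
            planted_at = int(rng.integers(0, L - len(cfg.motif) + 1))
            bases[planted_at : planted_at + len(cfg.motif)] = list(cfg.motif)
        if domain is Domain.TARGET and cfg.confounder_motif is not None:
            if rng.random() < cfg.motif_fraction:
                c = cfg.confounder_motif
                off = int(rng.integers(0, L - len(c) + 1))
                bases[off : off + len(c)] = list(c)
        seq = "".join(bases)
        score = cfg.motif_strength * best_match_score(seq, cfg.motif)
        if domain is Domain.TARGET and cfg.confounder_motif is not None:
            score += cfg.confounder_strength * cfg.motif_strength * best_match_score(
                seq, cfg.confounder_motif
            )
        label = score + rng.normal(0.0, noise_sd)
        ident = f"{domain.value}{i}"
        sequences.append(RnaSequence(seq, ident, domain))
        raw.append(label)
        truth.append(
            {"id": ident, "motif_offset": planted_at, "match_score": best_match_score(seq, cfg.motif)}
        )
    ds = DomainDataset(sequences, np.array(raw), domain)
    try:
        ds = scale_dataset(ds)
    except ValueError:
        pass  # degenerate config (constant labels): leave labels unscaled
    return ds, truth


def generate_domain_pair(cfg: SimulationConfig):
    """Generate ``(source, target, truth)``; truth retains the planted
    motif and per-sequence plant offsets / true match scores."""
    ss = np.random.SeedSequence([cfg.seed, 0x5EED])
    rng_s, rng_t = (np.random.default_rng(s) for s in ss.spawn(2))
    source, truth_s = _simulate_domain(cfg, Domain.SOURCE, cfg.n_source, cfg.source_noise_sd, rng_s)
    target, truth_t = _simulate_domain(cfg, Domain.TARGET, cfg.n_target, cfg.target_noise_sd, rng_t)
    truth = {
        "motif": cfg.motif,
        "confounder_motif": cfg.confounder_motif,
        "source": truth_s,
        "target": truth_t,
    }
    return source, target, truth


def write_fixture(pair, out_dir: str | Path) -> dict[str, Path]:
    """Write ``source.tsv``, ``target.tsv`` and ``truth.json`` so that
    :func:`read_affinity_table` round-trips them exactly."""
    source, target, truth = pair
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, ds in (("source", source), ("target", target)):
        path = out_dir / f"{name}.tsv"
        with open(path, "w") as fh:
            for seq, y in zip(ds.sequences, ds.raw_labels):
                fh.write(f"{seq.bases}\t{float(y)!r}\n")
        paths[name] = path
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    paths["truth"] = truth_path
    return paths


def read_fixture(fixture_dir: str | Path):
    fixture_dir = Path(fixture_dir)
    source = read_affinity_table(fixture_dir / "source.tsv", Domain.SOURCE)
    target = read_affinity_table(fixture_dir / "target.tsv", Domain.TARGET)
    truth = json.loads((fixture_dir / "truth.json").read_text())
    return source, target, truth
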
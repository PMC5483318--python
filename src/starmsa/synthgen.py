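"""Synthetic datasets of highly similar sequences.

All sequences derive independently from one random ancestor (star
topology, matching the model assumption behind center-star alignment):
per ancestor site a substitution with probability ``sub_rate`` (uniform
over the 3 alternatives), an inserted run with probability ``ins_rate``,
and a deleted run with probability ``del_rate``; indel run lengths are
geometric with the configured mean.  Identical config + seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from starmsa.seqio import ALPHABET, Dataset, Sequence

_RESIDUES = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    n: int
    length: int
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    indel_len_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")
        if self.indel_len_mean < 1.0:
            raise ValueError("indel_len_mean must be >= 1")


def _substitute_only(
    anc: np.ndarray, sub_rate: float, rng: np.random.Generator
) -> np.ndarray:
    out = anc.copy()
    if sub_rate > 0:
        mask = rng.random(anc.size) < sub_rate
        hits = int(mask.sum())
        if hits:
            # shift by 1..3 in code space: uniform over the 3 alternatives
            out[mask] = (out[mask] + rng.integers(1, 4, size=hits)) % 4
    return out


def _mutate_with_indels(
    anc: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    p_len = 1.0 / cfg.indel_len_mean
    out: list[int] = []
    i = 0
    while i < anc.size:
        if cfg.ins_rate and rng.random() < cfg.ins_rate:
            run = int(rng.geometric(p_len))
            out.extend(rng.integers(0, 4, size=run).tolist())
        if cfg.del_rate and rng.random() < cfg.del_rate:
            run = int(rng.geometric(p_len))
            i += run
            continue
        code = int(anc[i])
        if cfg.sub_rate and rng.random() < cfg.sub_rate:
            code = (code + int(rng.integers(1, 4))) % 4
        out.append(code)
        i += 1
    if not out:  # deletions may erase everything; keep records non-empty
        out.append(int(rng.integers(0, 4)))
    return np.asarray(out, dtype=np.uint8)


def _to_text(codes: np.ndarray) -> str:
    return _RESIDUES[codes].tobytes().decode("ascii")


def generate(cfg: SimulationConfig) -> tuple[Dataset, Sequence]:
    """Generate (dataset of n derived sequences, ancestor record)."""
    rng = np.random.default_rng(cfg.seed)
    anc = rng.integers(0, 4, size=cfg.length).astype(np.uint8)
    ancestor = Sequence(id="ancestor", residues=_to_text(anc))
    width = len(str(cfg.n - 1)) if cfg.n > 1 else 1
    records: list[Sequence] = []
    indels = cfg.ins_rate > 0 or cfg.del_rate > 0
    for i in range(cfg.n):
        if indels:
            derived = _mutate_with_indels(anc, cfg, rng)
        else:
            derived = _substitute_only(anc, cfg.sub_rate, rng)
        records.append(Sequence(id=f"seq{i:0{width}d}", residues=_to_text(derived)))
    return Dataset(records), ancestor
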
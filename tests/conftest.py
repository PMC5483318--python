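from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from starmsa.seqio import Dataset, Sequence

ALPHABET = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def random_dataset(
    rng: np.random.Generator, n: int, max_len: int, min_len: int = 1
) -> Dataset:
    records = [
        Sequence(
            id=f"s{i}",
            residues=random_seq(rng, int(rng.integers(min_len, max_len + 1))),
        )
        for i in range(n)
    ]
    return Dataset(records)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_dataset() -> Dataset:
    return Dataset(
        [
            Sequence(id="a", residues="ACGT"),
            Sequence(id="b", residues="AACGT"),
            Sequence(id="c", residues="ACGTT"),
        ]
    )
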
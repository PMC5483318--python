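"""Sum-of-pairs (SP) scoring of an MSA.

Each unordered row pair contributes per-column: match/mismatch for
residue-residue, the gap penalty for residue-gap, and 0 for gap-gap.
The average SP divides the total by n (the number of rows, not the number
of pairs).  The implementation counts per-column residue frequencies, so
it runs in O(width x n) rather than O(width x n^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence as TypingSequence

import numpy as np

from starmsa.seqio import GAP
from starmsa.pairwise import DEFAULT_SCORING, ScoringScheme
from starmsa.star_merge import MSAResult


@dataclass(frozen=True)
class SPScore:
    sp_total: int
    sp_average: float


def _rows_of(msa: MSAResult | TypingSequence[str]) -> list[str]:
    if isinstance(msa, MSAResult):
        return [row for _, row in msa.rows]
    return list(msa)


def sp_score(
    msa: MSAResult | TypingSequence[str], s: ScoringScheme = DEFAULT_SCORING
) -> SPScore:
    """SP total and average (total / n) of an equal-width MSA."""
    rows = _rows_of(msa)
    n = len(rows)
    if n < 2:
        raise ValueError("SP score needs at least 2 rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"ragged MSA rows: widths {sorted(widths)}")

    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(n, widths.pop())
    residue_cols = np.stack([(arr == ord(ch)).sum(axis=0) for ch in "ACGT"])
    n_res = residue_cols.sum(axis=0)
    n_gap = n - n_res

    def pairs(c: np.ndarray) -> np.ndarray:
        return c * (c - 1) // 2

    matches = pairs(residue_cols).sum()
    res_res = pairs(n_res).sum()
    mismatches = res_res - matches
    res_gap = (n_res * n_gap).sum()

    total = int(s.match * matches + s.mismatch * mismatches + s.gap * res_gap)
    return SPScore(sp_total=total, sp_average=total / n)
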
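"""Global pairwise alignment: full Needleman-Wunsch and a K-band variant.

Scoring is match/mismatch plus a linear gap penalty.  The backtrace breaks
ties in the fixed order diagonal > up > left, so outputs are
bit-reproducible.  The banded variant restricts the DP to a diagonal band
of half-width k and doubles k whenever the optimal in-band path touches
the band boundary, falling back to the full table in the limit, so its
result always equals the full DP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from starmsa.seqio import GAP

_NEG = -(1 << 40)  # out-of-band sentinel; far below any reachable score


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scores and linear gap penalty."""

    match: int = 1
    mismatch: int = -1
    gap: int = -2

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap >= self.match:
            raise ValueError("gap penalty must be below the match score")


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length gapped rows (center first) and the alignment score."""

    center_row: str
    other_row: str
    score: int

    def __post_init__(self) -> None:
        if len(self.center_row) != len(self.other_row):
            raise ValueError("alignment rows must have equal length")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _fill_full(av: np.ndarray, bv: np.ndarray, s: ScoringScheme) -> np.ndarray:
    """Full DP matrix, rows vectorized.

    The within-row dependency H[i,j] = max(V[j], H[i,j-1] + gap) with a
    linear gap is a running maximum of V[j] - gap*j, so each row is a few
    numpy operations.
    """
    n, m = av.size, bv.size
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    gj = s.gap * np.arange(m + 1, dtype=np.int64)
    H[0] = gj
    V = np.empty(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], s.match, s.mismatch)
        np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + s.gap, out=V[1:])
        V[0] = s.gap * i
        H[i] = np.maximum.accumulate(V - gj) + gj
    return H


def _fill_banded(
    av: np.ndarray, bv: np.ndarray, s: ScoringScheme, lo: int, hi: int
) -> np.ndarray:
    """DP matrix with cells outside lo <= j - i <= hi pinned to a sentinel."""
    n, m = av.size, bv.size
    H = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    j_hi0 = min(m, hi)
    H[0, : j_hi0 + 1] = s.gap * np.arange(j_hi0 + 1, dtype=np.int64)
    for i in range(1, n + 1):
        j0 = max(0, i + lo)
        j1 = min(m, i + hi)
        if j0 > j1:
            continue
        width = j1 - j0 + 1
        V = np.full(width, _NEG, dtype=np.int64)
        np.maximum(V, H[i - 1, j0 : j1 + 1] + s.gap, out=V)
        jd = max(j0, 1)  # diagonal defined for j >= 1
        if jd <= j1:
            sub = np.where(bv[jd - 1 : j1] == av[i - 1], s.match, s.mismatch)
            off = jd - j0
            np.maximum(V[off:], H[i - 1, jd - 1 : j1] + sub, out=V[off:])
        gj = s.gap * np.arange(j0, j1 + 1, dtype=np.int64)
        H[i, j0 : j1 + 1] = np.maximum.accumulate(V - gj) + gj
    return H


def _traceback(
    H: np.ndarray, a: str, b: str, s: ScoringScheme
) -> tuple[str, str, list[tuple[int, int]]]:
    """Deterministic backtrace (diagonal > up > left) from (len a, len b)."""
    i, j = len(a), len(b)
    row_a: list[str] = []
    row_b: list[str] = []
    path = [(i, j)]
    while i > 0 or j > 0:
        h = H[i, j]
        if (
            i > 0
            and j > 0
            and H[i - 1, j - 1] > _NEG // 2
            and h == H[i - 1, j - 1] + (s.match if a[i - 1] == b[j - 1] else s.mismatch)
        ):
            row_a.append(a[i - 1])
            row_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and H[i - 1, j] > _NEG // 2 and h == H[i - 1, j] + s.gap:
            row_a.append(a[i - 1])
            row_b.append(GAP)
            i -= 1
        elif j > 0 and H[i, j - 1] > _NEG // 2 and h == H[i, j - 1] + s.gap:
            row_a.append(GAP)
            row_b.append(b[j - 1])
            j -= 1
        else:  # pragma: no cover - DP consistency violation
            raise RuntimeError("backtrace failed: inconsistent DP matrix")
        path.append((i, j))
    return "".join(reversed(row_a)), "".join(reversed(row_b)), path


def nw_align(a: str, b: str, s: ScoringScheme = DEFAULT_SCORING) -> PairwiseAlignment:
    """Optimal global alignment of *a* (center row) and *b* (other row).

    Ties are resolved diagonal > up > left reading from the start of the
    sequences; implemented as a standard backtrace over the reversed
    inputs, whose rows are then flipped back.
    """
    if not a and not b:
        return PairwiseAlignment("", "", 0)
    ra, rb = a[::-1], b[::-1]
    H = _fill_full(_encode(ra), _encode(rb), s)
    row_a, row_b, _ = _traceback(H, ra, rb, s)
    return PairwiseAlignment(row_a[::-1], row_b[::-1], int(H[len(a), len(b)]))


def initial_band_width(len_a: int, len_b: int) -> int:
    """Default starting half-band: max(|length difference| + 1, 8)."""
    return max(abs(len_a - len_b) + 1, 8)


def kband_align(
    a: str,
    b: str,
    s: ScoringScheme = DEFAULT_SCORING,
    k: int | None = None,
) -> PairwiseAlignment:
    """Banded global alignment, doubling k until the result is exact.

    The band holds cells with -(k + max(0, la-lb)) <= j - i <= k +
    max(0, lb-la), which always contains both corners.  If the optimal
    in-band path touches the band boundary, k is doubled and the DP redone;
    once the path is interior or the band covers the table, the output
    equals :func:`nw_align`.
    """
    la, lb = len(a), len(b)
    if k is None:
        k = initial_band_width(la, lb)
    if k < 1:
        raise ValueError("band half-width k must be >= 1")
    if la == 0 or lb == 0:
        return nw_align(a, b, s)
    ra, rb = a[::-1], b[::-1]
    av, bv = _encode(ra), _encode(rb)
    while True:
        lo = -(k + max(0, la - lb))
        hi = k + max(0, lb - la)
        full_cover = hi >= lb and -lo >= la
        if full_cover:
            H = _fill_full(av, bv, s)
        else:
            H = _fill_banded(av, bv, s, lo, hi)
        if H[la, lb] > _NEG // 2:
            row_a, row_b, path = _traceback(H, ra, rb, s)
            if full_cover:
                return PairwiseAlignment(row_a[::-1], row_b[::-1], int(H[la, lb]))
            touches = any(j - i == lo or j - i == hi for i, j in path)
            if not touches:
                return PairwiseAlignment(row_a[::-1], row_b[::-1], int(H[la, lb]))
        k *= 2


def gap_insertions(aln: PairwiseAlignment) -> list[tuple[int, int]]:
    """Maximal gap runs in the center row as (insertion point, run length).

    The insertion point is the 0-based index of the center residue the run
    precedes; a trailing run maps to point len(center).
    """
    runs: list[tuple[int, int]] = []
    residue_idx = 0
    run_len = 0
    for ch in aln.center_row:
        if ch == GAP:
            run_len += 1
        else:
            if run_len:
                runs.append((residue_idx, run_len))
                run_len = 0
            residue_idx += 1
    if run_len:
        runs.append((residue_idx, run_len))
    return runs
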
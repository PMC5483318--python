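"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own data paths: plain dictionaries,
recursive enumeration, and O(n^2 L) pair loops.
"""

from __future__ import annotations

from collections import defaultdict


def dict_occurrences(seqs: list[str]) -> dict[str, int]:
    """Map 8-char segment *text* -> number of sequences containing it.

    Disjoint windows from position 0; remainder < 8 dropped; a sequence
    counts once per distinct segment.
    """
    occ: dict[str, int] = defaultdict(int)
    for s in seqs:
        segs = {s[i : i + 8] for i in range(0, (len(s) // 8) * 8, 8)}
        for seg in segs:
            occ[seg] += 1
    return dict(occ)


def dict_similarity_scores(seqs: list[str]) -> list[int]:
    """SS per sequence via the dictionary table (duplicates included)."""
    occ = dict_occurrences(seqs)
    scores = []
    for s in seqs:
        segs = [s[i : i + 8] for i in range(0, (len(s) // 8) * 8, 8)]
        scores.append(sum(occ[seg] for seg in segs))
    return scores


def enumerate_global_score(a: str, b: str, match: int, mismatch: int, gap: int) -> int:
    """Maximum global alignment score by exhaustive recursion (no memo)."""
    if not a and not b:
        return 0
    best = None
    if a and b:
        sub = match if a[0] == b[0] else mismatch
        best = enumerate_global_score(a[1:], b[1:], match, mismatch, gap) + sub
    if a:
        cand = enumerate_global_score(a[1:], b, match, mismatch, gap) + gap
        best = cand if best is None else max(best, cand)
    if b:
        cand = enumerate_global_score(a, b[1:], match, mismatch, gap) + gap
        best = cand if best is None else max(best, cand)
    return best


def brute_force_sp(rows: list[str], match: int, mismatch: int, gap: int) -> int:
    """SP total via an explicit O(n^2 L) loop over row pairs and columns."""
    total = 0
    n = len(rows)
    for i in range(n):
        for j in range(i + 1, n):
            for x, y in zip(rows[i], rows[j]):
                if x == "-" and y == "-":
                    continue
                if x == "-" or y == "-":
                    total += gap
                elif x == y:
                    total += match
                else:
                    total += mismatch
    return total
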
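"""Merge pairwise gap insertions into a gap profile and emit the final MSA.

The merged profile keeps, per insertion point on the center sequence, the
maximum gap run length demanded by any pairwise alignment ("aggregating"
the inserted spaces; literal addition would misalign identical pairs).
Within an expanded gap block the other row's residues are left-justified.
Insertion points are keyed to 0-based center residue indexes, with point
len(center) for trailing runs, so they are immune to earlier insertions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence as TypingSequence

from starmsa.seqio import GAP, Dataset
from starmsa.pairwise import (
    DEFAULT_SCORING,
    PairwiseAlignment,
    ScoringScheme,
    gap_insertions,
    kband_align,
    nw_align,
)
from starmsa.center_select import select_center


@dataclass(frozen=True)
class GapProfile:
    """Per-insertion-point maximum gap run lengths; len(center)+1 entries."""

    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.lengths):
            raise ValueError("gap lengths must be non-negative")

    def __getitem__(self, point: int) -> int:
        return self.lengths[point]

    @property
    def total(self) -> int:
        return sum(self.lengths)


@dataclass
class MSAResult:
    """Equal-length gapped rows in input order; the center row is flagged."""

    rows: list[tuple[str, str]]
    center_index: int

    @property
    def width(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def __iter__(self):
        return iter(self.rows)


def merge_gap_profiles(
    per_pair: Iterable[TypingSequence[tuple[int, int]]], center_len: int
) -> GapProfile:
    """Pointwise maximum of the pairwise gap-insertion lists."""
    merged = [0] * (center_len + 1)
    for insertions in per_pair:
        for point, run in insertions:
            if not 0 <= point <= center_len:
                raise ValueError(
                    f"insertion point {point} out of range 0..{center_len}"
                )
            if run > merged[point]:
                merged[point] = run
    return GapProfile(tuple(merged))


def _split_other_row(aln: PairwiseAlignment) -> tuple[list[str], list[str]]:
    """Split the other row by the center's residues.

    Returns (blocks, aligned): ``blocks[p]`` holds the other-row characters
    sitting in the center's gap run before center residue p (empty string
    if none); ``aligned[p]`` is the other-row character paired with center
    residue p.
    """
    center_len = sum(1 for ch in aln.center_row if ch != GAP)
    blocks = [""] * (center_len + 1)
    aligned = [""] * center_len
    p = 0
    for c_ch, o_ch in zip(aln.center_row, aln.other_row):
        if c_ch == GAP:
            blocks[p] += o_ch
        else:
            aligned[p] = o_ch
            p += 1
    return blocks, aligned


def apply_profile(aln: PairwiseAlignment, profile: GapProfile) -> str:
    """Re-pad the other row of *aln* onto the merged profile's columns.

    At every insertion point p exactly ``profile[p]`` gap columns precede
    center residue p; the pair's own gap-block characters are
    left-justified inside the block.  Degapping the result reproduces the
    original other sequence.
    """
    blocks, aligned = _split_other_row(aln)
    if len(blocks) != len(profile.lengths):
        raise ValueError(
            f"profile has {len(profile.lengths)} points, alignment needs {len(blocks)}"
        )
    parts: list[str] = []
    for p, block in enumerate(blocks):
        if len(block) > profile[p]:
            raise ValueError(
                f"profile entry {profile[p]} at point {p} smaller than the "
                f"pair's own gap run of {len(block)}"
            )
        parts.append(block.ljust(profile[p], GAP))
        if p < len(aligned):
            parts.append(aligned[p])
    return "".join(parts)


def expand_center(center: str, profile: GapProfile) -> str:
    """The center sequence with the merged gap columns inserted."""
    if len(profile.lengths) != len(center) + 1:
        raise ValueError("profile length must be len(center) + 1")
    parts: list[str] = []
    for p, ch in enumerate(center):
        parts.append(GAP * profile[p])
        parts.append(ch)
    parts.append(GAP * profile[len(center)])
    return "".join(parts)


def assemble(
    data: Dataset,
    center_index: int,
    alignments: TypingSequence[PairwiseAlignment],
) -> MSAResult:
    """Build the final MSA from the center and its pairwise alignments.

    *alignments* holds one alignment per non-center sequence, in dataset
    order.  All output rows share width len(center) + total merged gaps.
    """
    if not 0 <= center_index < data.n:
        raise ValueError(f"center index {center_index} out of range")
    if len(alignments) != data.n - 1:
        raise ValueError(
            f"expected {data.n - 1} pairwise alignments, got {len(alignments)}"
        )
    center = data[center_index].residues
    profile = merge_gap_profiles(
        [gap_insertions(aln) for aln in alignments], len(center)
    )
    center_row = expand_center(center, profile)
    rows: list[tuple[str, str]] = []
    aln_iter = iter(alignments)
    for i, rec in enumerate(data):
        if i == center_index:
            rows.append((rec.id, center_row))
            continue
        row = apply_profile(next(aln_iter), profile)
        if len(row) != len(center_row):
            raise RuntimeError(
                f"internal consistency failure: row {rec.id!r} has width "
                f"{len(row)}, center has {len(center_row)}"
            )
        if row.replace(GAP, "") != rec.residues:
            raise RuntimeError(
                f"internal consistency failure: row {rec.id!r} does not "
                "degap to its input sequence"
            )
        rows.append((rec.id, row))
    return MSAResult(rows=rows, center_index=center_index)


def align_star(
    data: Dataset,
    s: ScoringScheme = DEFAULT_SCORING,
    center_index: int | None = None,
    k: int | None = None,
    banded: bool = False,
) -> MSAResult:
    """Serial end-to-end star alignment (select, pairwise, merge)."""
    if data.n < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if center_index is None:
        center_index = select_center(data)
    center = data[center_index].residues
    alignments = []
    for i, rec in enumerate(data):
        if i == center_index:
            continue
        if banded:
            alignments.append(kband_align(center, rec.residues, s, k))
        else:
            alignments.append(nw_align(center, rec.residues, s))
    return assemble(data, center_index, alignments)
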
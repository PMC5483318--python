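"""FASTA input/output and normalization to the 4-letter DNA alphabet.

All coordinates are 0-based.  The gap character is ``-``.  RNA input is
accepted by mapping U to T.  Characters outside {A,C,G,T,U} are handled by
a configurable ambiguity policy:

``map-to-a`` (default)
    replace with ``A`` (keeps the 2-bit segment encoding total), count and
    log the replacements;
``strict``
    raise on the first offending character, naming its 0-based position;
``skip-segment``
    replace with ``A`` like the default, but record the offending
    positions on the record so downstream segment encoding can drop any
    segment that overlaps them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

GAP = "-"
ALPHABET = "ACGT"
AMBIGUITY_POLICIES = ("map-to-a", "strict", "skip-segment")

_CLEAN = set("ACGTU")


class FastaError(ValueError):
    """Raised for malformed or inconsistent FASTA input."""


def find_ambiguous_positions(raw: str) -> tuple[int, ...]:
    """0-based positions of characters outside {A,C,G,T,U} (case-insensitive)."""
    upper = raw.upper()
    return tuple(i for i, ch in enumerate(upper) if ch not in _CLEAN)


def normalize_residues(raw: str, policy: str = "map-to-a") -> str:
    """Normalize raw residue text to a string over {A,C,G,T}.

    Uppercases, maps U->T, and resolves other characters per *policy*.
    Idempotent: applying it twice equals applying it once.
    """
    if policy not in AMBIGUITY_POLICIES:
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    if not raw:
        raise ValueError("empty residue text")
    upper = raw.upper().replace("U", "T")
    bad = [i for i, ch in enumerate(upper) if ch not in ALPHABET]
    if not bad:
        return upper
    if policy == "strict":
        i = bad[0]
        raise ValueError(
            f"non-ACGTU character {raw[i]!r} at position {i} (strict policy)"
        )
    logger.warning("replaced %d ambiguous character(s) with 'A'", len(bad))
    chars = list(upper)
    for i in bad:
        chars[i] = "A"
    return "".join(chars)


@dataclass(frozen=True)
class Sequence:
    """One named sequence with residues over {A,C,G,T}."""

    id: str
    residues: str
    description: str = ""
    ambiguous_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has empty residue text")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGT characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Dataset:
    """Ordered collection of sequences; record order is preserved end-to-end."""

    records: list[Sequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise FastaError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def m_avg(self) -> float:
        if not self.records:
            return 0.0
        return sum(len(r) for r in self.records) / len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> Sequence:
        return self.records[i]


def read_fasta(path: str | Path, policy: str = "map-to-a") -> Dataset:
    """Read a FASTA file into a normalized :class:`Dataset`.

    Raises :class:`FastaError` on a missing/empty file, an empty record, or
    a duplicate id; the message names the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"no such file: {path}")
    records: list[Sequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if not raw:
            raise FastaError(f"record {rec.id!r} has empty residue text")
        ambiguous: tuple[int, ...] = ()
        if policy == "skip-segment":
            ambiguous = find_ambiguous_positions(raw)
        try:
            residues = normalize_residues(raw, policy)
        except ValueError as exc:
            raise FastaError(f"record {rec.id!r}: {exc}") from exc
        records.append(
            Sequence(
                id=rec.id,
                residues=residues,
                description=rec.description,
                ambiguous_positions=ambiguous,
            )
        )
    if not records:
        raise FastaError(f"no sequences in {path}")
    return Dataset(records)


def write_fasta(
    rows: Iterable[tuple[str, str]] | TypingSequence[Sequence],
    path: str | Path,
    line_width: int = 60,
    uniform_length: bool = True,
) -> None:
    """Write (id, residue/gapped-row) pairs as FASTA, wrapped at *line_width*.

    With ``uniform_length=True`` (MSA mode) all rows must have equal length.
    """
    pairs: list[tuple[str, str]] = []
    for item in rows:
        if isinstance(item, Sequence):
            pairs.append((item.id, item.residues))
        else:
            name, text = item
            pairs.append((name, text))
    if uniform_length and pairs:
        widths = {len(text) for _, text in pairs}
        if len(widths) > 1:
            raise ValueError(f"MSA rows have unequal lengths: {sorted(widths)}")
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    path = Path(path)
    with path.open("w") as fh:
        for name, text in pairs:
            fh.write(f">{name}\n")
            for start in range(0, len(text), line_width):
                fh.write(text[start : start + line_width] + "\n")
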
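"""FASTA input/output for protein and DNA sequences.

Records carry the coordinates of previously excised or masked domains on the
name line, using the dialect ``#FILTERED start-end id[,start-end id...]#``
appended to the description (1-based inclusive coordinates on the ORIGINAL,
unfiltered sequence).  The reader and writer are exact inverses for that
dialect.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

__all__ = [
    "Alphabet",
    "DomainInterval",
    "SequenceRecord",
    "PROTEIN",
    "DNA",
    "read_fasta",
    "write_fasta",
    "detect_alphabet",
]

_LINE_WIDTH = 60


@dataclass(frozen=True)
class Alphabet:
    """A residue alphabet with a distinguished 'unknown' letter."""

    kind: str  # "protein" | "dna"
    letters: str
    unknown: str

    def __post_init__(self) -> None:
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("alphabet letters must be distinct")
        if self.unknown in self.letters:
            raise ValueError("unknown letter must not be an ordinary letter")

    @property
    def valid(self) -> frozenset[str]:
        return frozenset(self.letters) | {self.unknown}


PROTEIN = Alphabet("protein", "ACDEFGHIKLMNPQRSTVWY", "X")
DNA = Alphabet("dna", "ACGT", "N")

#: Ambiguity codes mapped to the unknown letter on input (with a logged count).
_AMBIGUITY = {"protein": frozenset("BZJUO"), "dna": frozenset("RYSWKMBDHV")}


@dataclass(frozen=True)
class DomainInterval:
    """An excised/masked span, 1-based inclusive, in original coordinates."""

    seq_id: str
    start: int
    end: int
    domain_id: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"bad interval {self.start}-{self.end} for {self.seq_id!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SequenceRecord:
    """One FASTA entry after normalisation."""

    id: str
    description: str
    residues: str
    alphabet: Alphabet
    filtered_intervals: tuple[DomainInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - self.alphabet.valid
        if bad:
            pos = next(
                i + 1 for i, c in enumerate(self.residues) if c in bad
            )
            raise ValueError(
                f"record {self.id!r}: illegal character "
                f"{self.residues[pos - 1]!r} at position {pos}"
            )
        ivs = tuple(self.filtered_intervals)
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"record {self.id!r}: filtered intervals overlap or are unsorted"
                )
        self.filtered_intervals = ivs

    def __len__(self) -> int:
        return len(self.residues)


_FILTER_TAG = re.compile(r"\s*#FILTERED\s+([^#]*)#\s*$")
_FILTER_ITEM = re.compile(r"^\s*(\d+)-(\d+)(?:\s+(.+?))?\s*$")


def _parse_filter_tag(seq_id: str, description: str):
    """Split the ``#FILTERED ...#`` annotation out of a description."""
    m = _FILTER_TAG.search(description)
    if m is None:
        return description, ()
    items = []
    for chunk in m.group(1).split(","):
        im = _FILTER_ITEM.match(chunk)
        if im is None:
            raise ValueError(
                f"record {seq_id!r}: malformed #FILTERED entry {chunk!r}"
            )
        start, end, dom = int(im.group(1)), int(im.group(2)), im.group(3) or ""
        items.append(DomainInterval(seq_id, start, end, dom))
    return description[: m.start()].rstrip(), tuple(items)


def _format_filter_tag(intervals) -> str:
    parts = []
    for iv in intervals:
        item = f"{iv.start}-{iv.end}"
        if iv.domain_id:
            item += f" {iv.domain_id}"
        parts.append(item)
    return "#FILTERED " + ",".join(parts) + "#"


def _normalise(seq_id: str, raw: str, alphabet: Alphabet) -> str:
    seq = raw.upper()
    ambiguous = _AMBIGUITY[alphabet.kind]
    n_mapped = 0
    out = []
    for i, c in enumerate(seq):
        if c in alphabet.valid:
            out.append(c)
        elif c in ambiguous:
            out.append(alphabet.unknown)
            n_mapped += 1
        else:
            raise ValueError(
                f"record {seq_id!r}: illegal character {c!r} at position {i + 1}"
            )
    if n_mapped:
        logger.info(
            "record %r: mapped %d ambiguity code(s) to %r",
            seq_id, n_mapped, alphabet.unknown,
        )
    return "".join(out)


def read_fasta(path, alphabet: Alphabet) -> list[SequenceRecord]:
    """Read a FASTA file into normalised records.

    Lowercase is folded to uppercase, ambiguity codes are mapped to the
    alphabet's unknown letter, and any ``#FILTERED`` name-line annotation is
    parsed into ``filtered_intervals``.

    Raises
    ------
    ValueError
        If the file contains no records, a record has an empty sequence, or a
        sequence contains a character outside the alphabet.
    """
    records: list[SequenceRecord] = []
    with open(path) as fh:
        for header, raw in SimpleFastaParser(fh):
            header = header.strip()
            seq_id, _, desc = header.partition(" ")
            if not seq_id:
                raise ValueError(f"{path}: record with empty header")
            if not raw:
                raise ValueError(f"record {seq_id!r} has an empty sequence")
            desc, intervals = _parse_filter_tag(seq_id, desc.strip())
            residues = _normalise(seq_id, raw, alphabet)
            records.append(
                SequenceRecord(seq_id, desc, residues, alphabet, intervals)
            )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path) -> None:
    """Write records to ``path``; inverse of :func:`read_fasta`."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(format_record(rec))


def format_record(rec: SequenceRecord) -> str:
    header = ">" + rec.id
    if rec.description:
        header += " " + rec.description
    if rec.filtered_intervals:
        header += " " + _format_filter_tag(rec.filtered_intervals)
    lines = [header]
    for i in range(0, len(rec.residues), _LINE_WIDTH):
        lines.append(rec.residues[i : i + _LINE_WIDTH])
    return "\n".join(lines) + "\n"


def detect_alphabet(residues: str) -> str:
    """Advisory alphabet guess: ``"dna"`` iff only A/C/G/T/N occur.

    A sequence valid under both alphabets is reported as DNA, with a logged
    caution; an explicit user flag always takes precedence over this guess.
    """
    if not residues:
        raise ValueError("empty sequence")
    chars = set(residues.upper())
    if chars <= DNA.valid:
        if chars <= (DNA.valid & PROTEIN.valid):
            logger.warning(
                "sequence is valid in both alphabets; guessing DNA "
                "(pass an explicit alphabet flag to override)"
            )
        return "dna"
    return "protein"


def with_intervals(rec: SequenceRecord, intervals) -> SequenceRecord:
    """Copy of ``rec`` carrying ``intervals`` as its filtered-domain list."""
    return replace(rec, filtered_intervals=tuple(intervals))
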
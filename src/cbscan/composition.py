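"""Background residue compositions: the binomial null model.

A composition table maps each ordinary letter of an alphabet to a background
frequency.  Unknown letters (X/N) are never listed: by default they dilute the
denominator when counting, which makes biased-residue frequencies
conservative; with ``ignore_unknown`` they are dropped entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

from .seqio import DNA, PROTEIN, Alphabet, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CompositionTable",
    "compute_composition",
    "default_composition",
    "read_composition_file",
    "write_composition_file",
]


@dataclass
class CompositionTable:
    alphabet: Alphabet
    freq: dict[str, float]
    n_residues: int
    source: str = ""

    def __post_init__(self) -> None:
        missing = set(self.alphabet.letters) - set(self.freq)
        if missing:
            raise ValueError(f"composition missing letters: {sorted(missing)}")
        if any(v < 0 for v in self.freq.values()):
            raise ValueError("negative frequency in composition")
        total = sum(self.freq.values())
        # Σ may fall below 1 when unknown residues diluted the denominator,
        # but can never meaningfully exceed 1.
        if not (0 < total <= 1 + 1e-9):
            raise ValueError(f"composition frequencies sum to {total!r}")


def compute_composition(
    records: list[SequenceRecord], ignore_unknown: bool = False
) -> CompositionTable:
    """Tally residue frequencies over ``records``.

    Unknown letters are excluded from the numerator always; they are excluded
    from the denominator only when ``ignore_unknown`` is set.
    """
    if not records:
        raise ValueError("no records to tally")
    alphabet = records[0].alphabet
    if any(r.alphabet != alphabet for r in records):
        raise ValueError("records mix alphabets")
    counts = dict.fromkeys(alphabet.letters, 0)
    n_unknown = 0
    for rec in records:
        for c in rec.residues:
            if c == alphabet.unknown:
                n_unknown += 1
            else:
                counts[c] += 1
    n_known = sum(counts.values())
    if n_known == 0:
        raise ValueError("zero countable residues")
    denom = n_known if ignore_unknown else n_known + n_unknown
    freq = {r: counts[r] / denom for r in alphabet.letters}
    return CompositionTable(
        alphabet, freq, denom, source=f"computed from {len(records)} record(s)"
    )


def default_composition(alphabet: Alphabet) -> CompositionTable:
    """The packaged default background.

    DNA: uniform 0.25 per base.  Protein: a fixed database-wide amino-acid
    frequency table shipped in the package data (normalised on load and
    overridable with a user composition file).
    """
    if alphabet.kind == "dna":
        return CompositionTable(
            alphabet, {b: 0.25 for b in DNA.letters}, 0, source="uniform default"
        )
    text = (
        resources.files("cbscan.data")
        .joinpath("protein_composition.txt")
        .read_text()
    )
    freq = _parse_composition_text(text, alphabet)
    total = sum(freq.values())
    freq = {r: v / total for r, v in freq.items()}
    return CompositionTable(alphabet, freq, 0, source="packaged protein default")


def _parse_composition_text(text: str, alphabet: Alphabet) -> dict[str, float]:
    freq: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'LETTER FREQ', got {line!r}")
        letter, value = parts[0].upper(), float(parts[1])
        if letter == alphabet.unknown:
            logger.warning("ignoring unknown letter %r in composition file", letter)
            continue
        if letter not in alphabet.letters:
            raise ValueError(f"line {lineno}: letter {letter!r} not in alphabet")
        if value < 0:
            raise ValueError(f"line {lineno}: negative frequency {value!r}")
        if letter in freq:
            raise ValueError(f"line {lineno}: duplicate letter {letter!r}")
        freq[letter] = value
    return freq


def read_composition_file(path, alphabet: Alphabet) -> CompositionTable:
    """Read a whitespace-separated ``LETTER FREQ`` file ('#' comments allowed).

    Frequencies off unity by more than 1e-6 are renormalised with a logged
    warning; a deviation above 1% is an error, as is any missing letter.
    """
    with open(path) as fh:
        freq = _parse_composition_text(fh.read(), alphabet)
    missing = set(alphabet.letters) - set(freq)
    if missing:
        raise ValueError(f"{path}: missing letters {sorted(missing)}")
    total = sum(freq.values())
    if abs(total - 1.0) > 0.01:
        raise ValueError(f"{path}: frequencies sum to {total:.6f}, not 1")
    if abs(total - 1.0) > 1e-6:
        logger.warning("%s: frequencies sum to %.8f; renormalising", path, total)
    freq = {r: v / total for r, v in freq.items()}
    return CompositionTable(alphabet, freq, 0, source=str(path))


def write_composition_file(table: CompositionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# background residue composition ({table.alphabet.kind})\n")
        if table.source:
            fh.write(f"# source: {table.source}\n")
        for letter in table.alphabet.letters:
            fh.write(f"{letter} {table.freq[letter]!r}\n")
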
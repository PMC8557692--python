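"""Synthetic sequences with implanted biased tracts, and overlap scoring.

The generator draws background positions i.i.d. from a composition table and
overwrites implant windows with residues drawn from a chosen set at a chosen
concentration, returning the ground-truth intervals for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import CompositionTable
from .seqio import SequenceRecord

__all__ = ["ImplantSpec", "generate", "coincides", "read_features"]


@dataclass(frozen=True)
class ImplantSpec:
    """A biased tract to implant (1-based start)."""

    position: int
    length: int
    residue_set: str
    concentration: float
    seed: int | None = None  # optional per-implant stream; derived if None

    def __post_init__(self) -> None:
        if not 0 < self.concentration <= 1:
            raise ValueError("concentration must be in (0, 1]")
        if self.length < 1 or self.position < 1:
            raise ValueError("implant must have positive position and length")

    @property
    def start(self) -> int:
        return self.position

    @property
    def end(self) -> int:
        return self.position + self.length - 1


def generate(
    length: int,
    background: CompositionTable,
    implants: list[ImplantSpec] | tuple[ImplantSpec, ...] = (),
    seed: int = 0,
    seq_id: str = "synthetic",
) -> tuple[SequenceRecord, list[tuple[int, int, str]]]:
    """Draw one synthetic record; returns (record, truth intervals).

    Background positions are i.i.d. from ``background``; each implant position
    is drawn uniformly from the implant's residue set with probability equal
    to its concentration, otherwise from the background.  Identical seeds give
    identical sequences.
    """
    implants = sorted(implants, key=lambda s: s.position)
    for a, b in zip(implants, implants[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"implants overlap: {a.start}-{a.end} and {b.start}-{b.end}"
            )
    if implants and implants[-1].end > length:
        raise ValueError("implant extends beyond the sequence")
    alphabet = background.alphabet
    letters = list(alphabet.letters)
    probs = np.array([background.freq[r] for r in letters], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    chars = rng.choice(np.array(letters), size=length, p=probs)
    truth = []
    for spec in implants:
        sub = rng if spec.seed is None else np.random.default_rng(spec.seed)
        members = np.array(list(spec.residue_set))
        for i in range(spec.start - 1, spec.end):
            if sub.random() < spec.concentration:
                chars[i] = members[sub.integers(len(members))]
        truth.append((spec.start, spec.end, spec.residue_set))
    record = SequenceRecord(seq_id, "", "".join(chars), alphabet)
    return record, truth


def coincides(feature: tuple[int, int], regions) -> bool:
    """Reciprocal-overlap test between a feature interval and scan regions.

    True iff some region shares at least 50% of the feature's residues AND
    that shared span covers at least 50% of the region's residues.  Exact
    residue counts are compared (a tie at exactly 50% satisfies the rule).
    """
    fs, fe = feature
    if fs > fe:
        raise ValueError(f"bad feature interval {feature!r}")
    flen = fe - fs + 1
    for reg in regions:
        ov = min(fe, reg.end) - max(fs, reg.start) + 1
        if ov <= 0:
            continue
        rlen = reg.end - reg.start + 1
        if 2 * ov >= flen and 2 * ov >= rlen:
            return True
    return False


def read_features(path) -> list[tuple[str, int, int]]:
    """Read a 3-column tab-separated feature file: seq_id, start, end."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected seq_id, start, end")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out
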
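"""Bias signatures, physico-chemical bias classes, and enrichment ratios."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .composition import CompositionTable

__all__ = [
    "ClassTable",
    "load_protein_classes",
    "signature",
    "protein_class",
    "dna_class",
    "enrichment",
    "DNA_CLASS_LABELS",
]

MIXED = "mixed"


@dataclass(frozen=True)
class ClassTable:
    """Ordered (label, residue-set) classes for one alphabet kind."""

    kind: str
    classes: tuple[tuple[str, frozenset], ...]
    fallback: str = MIXED

    def smallest_containing(self, residue_set) -> str:
        """Label of the smallest class containing every residue in the set.

        Ties in membership size are broken by table order; with no container
        the fallback label is returned.
        """
        rs = frozenset(residue_set)
        best = None
        for i, (label, members) in enumerate(self.classes):
            if rs <= members and (best is None or len(members) < len(best[0])):
                best = (members, i, label)
        return self.fallback if best is None else best[2]


def _parse_class_text(text: str, kind: str) -> ClassTable:
    classes = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        label, members = line.split()
        classes.append((label, frozenset(members)))
    return ClassTable(kind, tuple(classes))


@lru_cache(maxsize=8)
def load_protein_classes(path: str | None = None) -> ClassTable:
    """The packaged protein class table, or a user replacement from ``path``."""
    if path is None:
        text = (
            resources.files("cbscan.data")
            .joinpath("protein_classes.txt")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    return _parse_class_text(text, "protein")


def signature(residue_set) -> str:
    """Curly-bracket signature of the biasing residues, in precedence order."""
    return "{" + "".join(residue_set) + "}"


def protein_class(residue_set, table: ClassTable | None = None) -> str:
    if table is None:
        table = load_protein_classes()
    return table.smallest_containing(residue_set)


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: The eight strand-paired DNA bias classes.
DNA_CLASS_LABELS = (
    "{A}-{T}",
    "{G}-{C}",
    "{AT}",
    "{GC}",
    "{AC}-{GT}",
    "{AG}-{CT}",
    "{ATC}-{ATG}",
    "{ACG}-{CGT}",
)

_DNA_CANONICAL = {
    frozenset("A"): "{A}-{T}",
    frozenset("T"): "{A}-{T}",
    frozenset("G"): "{G}-{C}",
    frozenset("C"): "{G}-{C}",
    frozenset("AT"): "{AT}",
    frozenset("GC"): "{GC}",
    frozenset("AC"): "{AC}-{GT}",
    frozenset("GT"): "{AC}-{GT}",
    frozenset("AG"): "{AG}-{CT}",
    frozenset("CT"): "{AG}-{CT}",
    frozenset("ATC"): "{ATC}-{ATG}",
    frozenset("ATG"): "{ATC}-{ATG}",
    frozenset("ACG"): "{ACG}-{CGT}",
    frozenset("CGT"): "{ACG}-{CGT}",
}


def dna_class(residue_set) -> str:
    """Canonical label among the eight DNA bias classes.

    A base set and its complementary-strand image (base-wise complement) map
    to the same class; a bias for all four bases is impossible.
    """
    rs = frozenset(residue_set)
    if not rs:
        raise ValueError("empty residue set")
    if not rs <= frozenset("ACGT"):
        raise ValueError(f"not a DNA residue set: {sorted(rs)}")
    if len(rs) == 4:
        raise ValueError("a bias for all four bases is not possible")
    return _DNA_CANONICAL[rs]


def enrichment(region, comp: CompositionTable) -> float:
    """(biasing fraction of the region) / (background frequency of the set)."""
    length = region.end - region.start + 1
    if length < 1:
        raise ValueError("empty region")
    k = sum(region.counts.get(r, 0) for r in region.residue_set)
    p = sum(comp.freq[r] for r in region.residue_set)
    if p == 0:
        raise ValueError(
            f"residues {''.join(region.residue_set)} absent from the background"
        )
    return (k / length) / p
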
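"""Excise or mask annotated domains, and remap scan coordinates back.

Excision deletes the domain spans (the output sequence is shorter); masking
replaces them with the alphabet's unknown letter (length preserved).  Either
way the original-coordinate spans are recorded on the record and carried on
the FASTA name line, so regions found on a filtered sequence can be remapped
to original coordinates.
"""

from __future__ import annotations

from dataclasses import replace

from .scanner import BiasedRegion
from .seqio import DomainInterval, SequenceRecord

__all__ = [
    "DomainInterval",
    "read_domain_table",
    "apply_filter",
    "remap",
    "looks_masked",
    "to_original",
]


def read_domain_table(path) -> list[DomainInterval]:
    """Read a tab-separated ``seq_id  start  end  domain_id`` table.

    Coordinates are 1-based inclusive; the domain id column is optional.
    Lines starting with '#' are skipped.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected seq_id, start, end[, domain_id]"
                )
            seq_id, start, end = parts[0], int(parts[1]), int(parts[2])
            dom = parts[3] if len(parts) > 3 else ""
            out.append(DomainInterval(seq_id, start, end, dom))
    return out


def _merge_spans(record_id: str, domains, length: int):
    spans = sorted((d.start, d.end, d.domain_id) for d in domains)
    for s, e, _ in spans:
        if not (1 <= s <= e <= length):
            raise ValueError(
                f"domain {s}-{e} outside sequence {record_id!r} (length {length})"
            )
    merged: list[list] = []
    for s, e, dom in spans:
        # contiguous spans behave identically to one span; merge them too
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
            if dom and dom not in merged[-1][2]:
                merged[-1][2].append(dom)
        else:
            merged.append([s, e, [dom] if dom else []])
    return [
        DomainInterval(record_id, s, e, ",".join(doms)) for s, e, doms in merged
    ]


def apply_filter(
    record: SequenceRecord, domains, mode: str
) -> SequenceRecord:
    """Return a copy of ``record`` with domain spans excised or masked."""
    if mode not in ("excised", "masked"):
        raise ValueError(f"mode must be 'excised' or 'masked', got {mode!r}")
    relevant = [d for d in domains if d.seq_id == record.id]
    if not relevant:
        return record
    merged = _merge_spans(record.id, relevant, len(record.residues))
    seq = record.residues
    if mode == "masked":
        chars = list(seq)
        for iv in merged:
            chars[iv.start - 1 : iv.end] = record.alphabet.unknown * iv.length
        new_seq = "".join(chars)
    else:
        keep = []
        pos = 0
        for iv in merged:
            keep.append(seq[pos : iv.start - 1])
            pos = iv.end
        keep.append(seq[pos:])
        new_seq = "".join(keep)
        if not new_seq:
            raise ValueError(
                f"record {record.id!r}: excising all domains leaves no sequence"
            )
    return replace(
        record, residues=new_seq, filtered_intervals=tuple(merged)
    )


def looks_masked(record: SequenceRecord) -> bool:
    """Heuristic: filtered spans lie inside the sequence and are all unknown.

    Distinguishes masked from excised records when only the name-line
    annotation is available (the dialect does not store the mode).
    """
    if not record.filtered_intervals:
        return False
    unk = record.alphabet.unknown
    for iv in record.filtered_intervals:
        if iv.end > len(record.residues):
            return False
        if set(record.residues[iv.start - 1 : iv.end]) != {unk}:
            return False
    return True


def to_original(pos: int, spans) -> int:
    """Map a 1-based position on the excised sequence to original coordinates."""
    orig = pos
    for s, e in spans:
        if orig >= s:
            orig += e - s + 1
        else:
            break
    return orig


def remap(region: BiasedRegion, filtered: SequenceRecord) -> BiasedRegion:
    """Shift a region found on an excised sequence to original coordinates.

    A region spanning one or more excisions is reported with its
    original-coordinate outer extent plus the list of excluded spans
    (a discontinuous region); counts and the tail probability refer to the
    filtered residues only and are unchanged.
    """
    spans = [(iv.start, iv.end) for iv in filtered.filtered_intervals]
    if not spans:
        return region
    start = to_original(region.start, spans)
    end = to_original(region.end, spans)
    excluded = tuple((s, e) for s, e in spans if start < s and e < end)
    return replace(region, start=start, end=end, excluded_spans=excluded)
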
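"""Core compositional-bias scan: quick scan, minimise, merge, trim.

The pipeline, per sequence and per residue type:

1. QUICK SCAN — slide fixed-length windows (length ``m``, step per precision
   mode, plus one window flush with the sequence end) and keep those whose
   binomial tail probability under the background falls below the mode's
   baseline; overlapping/adjacent kept windows are unioned into candidate
   contigs.
2. MINIMIZE — within each contig, exhaustively find the subinterval with
   length in ``[m, M]`` whose tail probability is smallest.
3. TRIM — shear non-biasing residues off both ends of minimum-length
   regions (counts unchanged; the tail can only shrink).
4. MERGE — transitively overlapping single-residue regions are re-minimised
   jointly over their union extent with pooled counts and pooled background
   probability, yielding multiple-residue regions.

Regions are emitted when their log10 tail probability is at or below the
output threshold ``t``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import bias_typing
from .binom import tail_row, tails_at
from .composition import CompositionTable
from .seqio import Alphabet, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ScanParams",
    "CandidateContig",
    "BiasedRegion",
    "PRECISION_MODES",
    "quick_scan",
    "minimize",
    "minimize_interval",
    "merge",
    "trim",
    "annotate",
]

#: precision mode -> (baseline window P-value, window step in residues)
PRECISION_MODES = {
    "fast": (1e-3, 3),
    "medium": (1e-2, 2),
    "thorough": (1e-1, 1),
}


@dataclass(frozen=True)
class ScanParams:
    """All scan knobs; ``t`` is the output threshold in log10."""

    alphabet: Alphabet
    t: float = math.log10(1e-3)
    m: int = 15
    M: int = 500
    precision: str = "fast"
    restriction: frozenset | None = None
    ignore_unknown: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.m <= self.M:
            raise ValueError(f"need 1 <= m <= M, got m={self.m}, M={self.M}")
        if self.t > 0:
            raise ValueError(f"t must be a log10 probability (<= 0), got {self.t}")
        if self.precision not in PRECISION_MODES:
            raise ValueError(f"unknown precision mode {self.precision!r}")
        if self.restriction is not None:
            rs = frozenset(self.restriction)
            bad = rs - frozenset(self.alphabet.letters)
            if bad:
                raise ValueError(
                    f"restriction letters {sorted(bad)} outside the alphabet"
                )
            object.__setattr__(self, "restriction", rs)

    @property
    def baseline_p0(self) -> float:
        return PRECISION_MODES[self.precision][0]

    @property
    def step(self) -> int:
        return PRECISION_MODES[self.precision][1]

    @property
    def scan_residues(self) -> str:
        letters = self.alphabet.letters
        if self.restriction is None:
            return letters
        return "".join(r for r in letters if r in self.restriction)


@dataclass(frozen=True)
class CandidateContig:
    """Union of overlapping kept windows for one residue (1-based inclusive)."""

    residue: str
    start: int
    end: int
    member_windows: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class BiasedRegion:
    """An annotated biased interval (1-based inclusive coordinates)."""

    seq_id: str
    start: int
    end: int
    residue_set: tuple[str, ...]  # precedence order
    counts: dict[str, int]
    logp: float  # log10 binomial tail
    kind: str  # "single" | "multiple"
    signature: str = ""
    bias_class: str = ""
    enrichment: float = float("nan")
    excluded_spans: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _window_starts(L: int, m: int, step: int) -> np.ndarray:
    """0-based window start offsets: every ``step`` plus one flush with the end."""
    last = L - m
    starts = list(range(0, last + 1, step))
    if starts[-1] != last:
        starts.append(last)  # step > 1 must not skip a terminal bias
    return np.asarray(starts, dtype=np.intp)


def _prefix_counts(seq_bytes: np.ndarray, letter: str) -> np.ndarray:
    pc = np.zeros(len(seq_bytes) + 1, dtype=np.intp)
    np.cumsum(seq_bytes == ord(letter), out=pc[1:])
    return pc


def quick_scan(
    record: SequenceRecord, comp: CompositionTable, params: ScanParams
) -> dict[str, list[CandidateContig]]:
    """Stage one: per residue, contigs of windows beating the baseline P-value."""
    L = len(record.residues)
    out: dict[str, list[CandidateContig]] = {}
    if L < params.m:
        return out
    seq = np.frombuffer(record.residues.encode("ascii"), dtype=np.uint8)
    starts = _window_starts(L, params.m, params.step)
    baseline = math.log10(params.baseline_p0)
    if params.ignore_unknown:
        pc_unknown = _prefix_counts(seq, record.alphabet.unknown)
        w_eff = params.m - (pc_unknown[starts + params.m] - pc_unknown[starts])
    else:
        w_eff = params.m
    for r in params.scan_residues:
        p = comp.freq.get(r, 0.0)
        if not 0 < p < 1:
            logger.debug("residue %r has background %r; cannot seed bias", r, p)
            continue
        pc = _prefix_counts(seq, r)
        k = pc[starts + params.m] - pc[starts]
        if np.ndim(w_eff):
            ok = w_eff > 0
            lp = np.zeros(len(starts))
            lp[ok] = tails_at(np.minimum(k[ok], w_eff[ok]), w_eff[ok], p)
        else:
            lp = tails_at(k, w_eff, p)
        kept = starts[lp < baseline]
        if not len(kept):
            continue
        contigs = []
        cs = ce = None
        n_win = 0
        for s in kept:
            lo, hi = int(s) + 1, int(s) + params.m  # 1-based inclusive
            if cs is None:
                cs, ce, n_win = lo, hi, 1
            elif lo <= ce + 1:
                ce, n_win = max(ce, hi), n_win + 1
            else:
                contigs.append(CandidateContig(r, cs, ce, n_win))
                cs, ce, n_win = lo, hi, 1
        contigs.append(CandidateContig(r, cs, ce, n_win))
        out[r] = contigs
    return out


def _best_subinterval(
    record: SequenceRecord,
    lo: int,
    hi: int,
    members: str,
    p: float,
    params: ScanParams,
    max_len: int,
):
    """Exhaustive minimum-tail subinterval of [lo, hi] (1-based inclusive).

    Counts positions whose residue is in ``members``; window length is reduced
    by contained unknowns when ``ignore_unknown`` is set.  Ties prefer the
    longer interval, then the leftmost.  Returns (logp, start, end) or None.
    """
    sub = np.frombuffer(
        record.residues[lo - 1 : hi].encode("ascii"), dtype=np.uint8
    )
    L = len(sub)
    if L < params.m:
        return None
    in_set = np.zeros(L, dtype=bool)
    for r in members:
        in_set |= sub == ord(r)
    pk = np.zeros(L + 1, dtype=np.intp)
    np.cumsum(in_set, out=pk[1:])
    if params.ignore_unknown:
        pu = np.zeros(L + 1, dtype=np.intp)
        np.cumsum(sub == ord(record.alphabet.unknown), out=pu[1:])
    best = None  # (logp, w, start_offset)
    for w in range(params.m, min(max_len, L) + 1):
        k = pk[w:] - pk[: L - w + 1]
        if params.ignore_unknown:
            weff = w - (pu[w:] - pu[: L - w + 1])
            valid = weff > 0
            lp = np.full(len(k), np.inf)
            if valid.any():
                lp[valid] = tails_at(k[valid], weff[valid], p)
        else:
            lp = tail_row(w, p)[k]
        i = int(np.argmin(lp))  # leftmost minimum
        v = float(lp[i])
        if best is None or v < best[0] or (v == best[0] and w > best[1]):
            best = (v, w, i)
    if best is None:
        return None
    v, w, i = best
    return v, lo + i, lo + i + w - 1


def _region_logp(record, start, end, residue_set, p, params) -> tuple[float, dict]:
    """Tail log10-P and per-residue counts for a fixed interval."""
    piece = record.residues[start - 1 : end]
    counts = {r: piece.count(r) for r in residue_set}
    k = sum(counts.values())
    w = end - start + 1
    if params.ignore_unknown:
        w -= piece.count(record.alphabet.unknown)
    return float(tail_row(w, p)[k]), counts


def minimize_interval(
    record: SequenceRecord,
    contig: CandidateContig,
    comp: CompositionTable,
    params: ScanParams,
):
    """The raw minimum-tail subinterval of a contig: (log10 tail, start, end).

    This is the exhaustive search underlying :func:`minimize`, before the
    output threshold is applied and before trimming.
    """
    return _best_subinterval(
        record,
        contig.start,
        contig.end,
        contig.residue,
        comp.freq[contig.residue],
        params,
        params.M,
    )


def minimize(
    record: SequenceRecord,
    contig: CandidateContig,
    comp: CompositionTable,
    params: ScanParams,
) -> BiasedRegion | None:
    """Stage two: the minimum-tail subinterval of a contig, trimmed."""
    r = contig.residue
    best = minimize_interval(record, contig, comp, params)
    if best is None or best[0] > params.t:
        return None
    logp, start, end = best
    counts = {r: record.residues[start - 1 : end].count(r)}
    region = BiasedRegion(
        record.id, start, end, (r,), counts, logp, "single"
    )
    return trim(region, record, comp, params)


def trim(
    region: BiasedRegion,
    record: SequenceRecord,
    comp: CompositionTable | None = None,
    params: ScanParams | None = None,
) -> BiasedRegion:
    """Shear non-biasing residues off both ends; recompute the tail.

    Counts are unchanged; the window only shrinks, so the tail probability
    never grows.  Only minimum-length regions can actually change, because
    an exhaustively minimised longer region already ends in biasing residues.
    """
    rs = set(region.residue_set)
    start, end = region.start, region.end
    seq = record.residues
    while start < end and seq[start - 1] not in rs:
        start += 1
    while end > start and seq[end - 1] not in rs:
        end -= 1
    if start == region.start and end == region.end:
        return region
    if comp is not None and params is not None:
        p = sum(comp.freq[r] for r in region.residue_set)
        logp, _ = _region_logp(record, start, end, region.residue_set, p, params)
    else:
        logp = region.logp
    return replace(region, start=start, end=end, logp=logp)


def merge(
    regions: list[BiasedRegion],
    record: SequenceRecord,
    comp: CompositionTable,
    params: ScanParams,
) -> list[BiasedRegion]:
    """Stage three: joint regions from transitively overlapping single biases.

    Each overlap group is re-minimised over its union extent with pooled
    probability (sum of member background frequencies) and pooled counts; the
    joint region may exceed ``M``.  The biasing residues are ordered by bias
    precedence: ascending single-residue tail, ties alphabetical.
    """
    singles = sorted(regions, key=lambda g: (g.start, g.end))
    groups: list[list[BiasedRegion]] = []
    group_end = -1
    for reg in singles:
        if groups and reg.start <= group_end:
            groups[-1].append(reg)
            group_end = max(group_end, reg.end)
        else:
            groups.append([reg])
            group_end = reg.end
    out: list[BiasedRegion] = []
    for group in groups:
        if len(group) < 2:
            continue
        best_logp: dict[str, float] = {}
        for g in group:
            r = g.residue_set[0]
            best_logp[r] = min(g.logp, best_logp.get(r, 0.0))
        residue_set = tuple(
            sorted(best_logp, key=lambda r: (best_logp[r], r))
        )
        p = sum(comp.freq[r] for r in residue_set)
        if not p < 1:
            continue
        lo = min(g.start for g in group)
        hi = max(g.end for g in group)
        best = _best_subinterval(
            record, lo, hi, "".join(residue_set), p, params, max_len=hi - lo + 1
        )
        if best is None or best[0] > params.t:
            continue
        logp, start, end = best
        _, counts = _region_logp(record, start, end, residue_set, p, params)
        region = BiasedRegion(
            record.id, start, end, residue_set, counts, logp, "multiple"
        )
        out.append(trim(region, record, comp, params))
    return out


def annotate(
    record: SequenceRecord,
    comp: CompositionTable,
    params: ScanParams,
    class_table: bias_typing.ClassTable | None = None,
) -> list[BiasedRegion]:
    """Full pipeline on one sequence; regions sorted by start, then tail."""
    contigs = quick_scan(record, comp, params)
    singles = []
    for r in params.scan_residues:
        for contig in contigs.get(r, []):
            reg = minimize(record, contig, comp, params)
            if reg is not None:
                singles.append(reg)
    multiples = merge(singles, record, comp, params)
    regions = singles + multiples
    for reg in regions:
        reg.signature = bias_typing.signature(reg.residue_set)
        if record.alphabet.kind == "dna":
            reg.bias_class = bias_typing.dna_class(reg.residue_set)
        else:
            reg.bias_class = bias_typing.protein_class(reg.residue_set, class_table)
        reg.enrichment = bias_typing.enrichment(reg, comp)
    regions.sort(key=lambda g: (g.start, g.logp, g.end))
    return regions
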
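"""Duplication/insertion notational equivalence between call sets.

A tandem duplication of the segment ``[a, b]`` and an insertion of ``b-a+1``
bases at either boundary of that segment produce the same derivative
chromosome, yet their breakpoint representations are disjoint: the
duplication is a ``(-,+)`` pair spanning the segment, the insertion an
adjacent ``(+,-)`` pair carrying inserted sequence.  Long-read callers
typically report moderate-size duplications as insertions while short-read
callers report duplications, so plain breakpoint matching labels the same
rearrangement discordant.  :func:`find_ins_dup_overlaps` detects these
equivalent calls across two sets.

Equivalence here is positional and length-based only; the inserted sequence
is never compared against the reference (callers often emit placeholder or
N-padded inserts, and notational equivalence does not require sequence
identity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import Breakend, BreakpointSet

__all__ = ["DupInsHit", "find_ins_dup_overlaps"]

# canonical insertion form: breakends 1 bp apart, widened by their intervals
_ADJACENCY_BP = 1


@dataclass(frozen=True)
class DupInsHit:
    """A duplication call equivalent to an insertion call.

    ``boundary`` records where the insertion site sat relative to the
    duplicated segment: ``"left"``, ``"right"`` or ``"both"`` (a single hit
    is reported when both boundaries are within reach of a short
    duplication).
    """

    dup_id: str
    ins_id: str
    dup_in_query: bool
    boundary: str
    dup_len: int
    ins_len: int
    size_ratio: float


def _classify(pair: tuple[Breakend, Breakend]):
    """('dup'|'ins'|None, pair) for a canonically ordered pair."""
    b1, b2 = pair
    if b1.contig != b2.contig:
        return None
    sig = (b1.orientation, b2.orientation)
    if sig == ("-", "+"):
        return "dup"
    if sig == ("+", "-") and b2.lo - b1.hi <= _ADJACENCY_BP and b1.insert_seq:
        return "ins"
    return None


def _boundary_hits(dup, ins, maxgap: int):
    d1, d2 = dup
    i1, i2 = ins
    site_lo = min(i1.lo, i2.lo) - maxgap
    site_hi = max(i1.hi, i2.hi) + maxgap
    left = site_lo <= d1.hi and d1.lo <= site_hi
    right = site_lo <= d2.hi and d2.lo <= site_hi
    if left and right:
        return "both"
    if left:
        return "left"
    if right:
        return "right"
    return None


def find_ins_dup_overlaps(query: BreakpointSet, subject: BreakpointSet,
                          maxgap: int = 16,
                          size_margin: float = 0.25) -> list[DupInsHit]:
    """Match duplication-notation calls in one set to insertion-notation
    calls in the other.

    A dup-like pair (intrachromosomal, ``(-,+)`` by coordinate order,
    duplicated length ``L = nominal2 - nominal1 + 1``) matches an ins-like
    pair (adjacent ``(+,-)`` breakends with insert length ``l > 0``) when

    * the insertion site lies within ``maxgap`` of either duplication
      boundary (intervals widened by breakend uncertainty), and
    * ``|L - l| / max(L, l) <= size_margin``.

    The search is symmetric in the two roles: duplications are taken from
    whichever side reports them.
    """
    hits = []
    qpairs = query.breakpoint_pairs()
    spairs = subject.breakpoint_pairs()
    for dup_in_query, dups, inss in ((True, qpairs, spairs), (False, spairs, qpairs)):
        dup_list = [(p, query.pair_id(p[0]) if dup_in_query else subject.pair_id(p[0]))
                    for p in dups if _classify(p) == "dup"]
        ins_list = [(p, subject.pair_id(p[0]) if dup_in_query else query.pair_id(p[0]))
                    for p in inss if _classify(p) == "ins"]
        for dup, dup_id in dup_list:
            d1, d2 = dup
            if d1.contig != d2.contig:
                continue
            dup_len = d2.nominal - d1.nominal + 1
            for ins, ins_id in ins_list:
                if ins[0].contig != d1.contig:
                    continue
                ins_len = len(ins[0].insert_seq)
                m = max(dup_len, ins_len)
                ratio = abs(dup_len - ins_len) / m if m else 0.0
                if ratio > size_margin:
                    continue
                boundary = _boundary_hits(dup, ins, maxgap)
                if boundary is None:
                    continue
                hits.append(DupInsHit(dup_id, ins_id, dup_in_query, boundary,
                                      dup_len, ins_len, ratio))
    hits.sort(key=lambda h: (h.dup_id, h.ins_id))
    return hits
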
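"""Orientation-aware breakpoint overlap detection between call sets.

Two breakpoints match when their breakends can be aligned so that each
aligned pair shares a contig, agrees in orientation, and has intersecting
location intervals (after widening each interval by ``maxgap``).  An
uncertain position therefore counts as an exact match to any position inside
its interval.  Because matching is purely positional/orientational it is
notation-blind: no deletion/duplication/inversion typing happens first, so
calls match across VCF notations.  Relative event-size criteria only apply
to intrachromosomal breakpoints, where an event span is defined.

:func:`find_breakpoint_overlaps` uses a per-contig interval index;
:func:`find_breakpoint_overlaps_naive` is the brute-force all-pairs
reference implementation the index is contractually equal to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from intervaltree import IntervalTree

from .model import Breakend, BreakpointSet, pair_span

__all__ = [
    "MatchParams",
    "BreakpointHit",
    "find_breakpoint_overlaps",
    "find_breakpoint_overlaps_naive",
    "count_breakpoint_overlaps",
    "find_breakend_overlaps",
    "best_hits",
]


@dataclass(frozen=True)
class MatchParams:
    """Matching tolerances.

    maxgap: bp slack added to each breakend interval (default 0 = exact).
    size_margin: maximum tolerated relative event-size difference
        ``|span_q - span_s| / max(span_q, span_s)`` for intrachromosomal
        pairs; ``None`` disables the test.
    restrict_margin_to_size_multiple: optional cap expressing the effective
        maxgap as a multiple of the (smaller) event size; applied
        conjunctively with ``size_margin``.
    ignore_strand: drop the orientation-equality requirement.
    """

    maxgap: int = 0
    size_margin: Optional[float] = None
    restrict_margin_to_size_multiple: Optional[float] = None
    ignore_strand: bool = False

    def __post_init__(self):
        if self.maxgap < 0:
            raise ValueError("maxgap must be >= 0")
        if self.size_margin is not None and not (0 <= self.size_margin <= 1):
            raise ValueError("size_margin must be in [0, 1]")


@dataclass(frozen=True)
class BreakpointHit:
    """One matching (query pair, subject pair) with per-breakend gaps.

    Gaps are the separations between the *unexpanded* location intervals of
    the aligned breakends (0 when they already intersect).  ``size_ratio``
    is the relative span difference, defined only when both pairs are
    intrachromosomal.
    """

    query_id: str
    subject_id: str
    gap1: int
    gap2: int
    size_ratio: Optional[float] = None


def _interval_gap(a: Breakend, b: Breakend) -> int:
    return max(0, max(a.lo, b.lo) - min(a.hi, b.hi))


def _breakend_match(q: Breakend, s: Breakend, gap: int, ignore_strand: bool) -> bool:
    if q.contig != s.contig:
        return False
    if not ignore_strand and q.orientation != s.orientation:
        return False
    return q.lo - gap <= s.hi + gap and s.lo - gap <= q.hi + gap


def _pair_match(q1, q2, s1, s2, params: MatchParams):
    """Hit fields for two pairs, or None.  Tries both breakend assignments."""
    size_ratio = None
    span_q = pair_span(q1, q2)
    span_s = pair_span(s1, s2)
    gap = params.maxgap
    if span_q is not None and span_s is not None:
        m = max(span_q, span_s)
        size_ratio = abs(span_q - span_s) / m if m else 0.0
        if params.size_margin is not None and size_ratio > params.size_margin:
            return None
        if params.restrict_margin_to_size_multiple is not None:
            gap = min(gap, int(params.restrict_margin_to_size_multiple
                               * min(span_q, span_s)))
    for a1, a2 in (((q1, s1), (q2, s2)), ((q1, s2), (q2, s1))):
        if _breakend_match(*a1, gap, params.ignore_strand) and \
                _breakend_match(*a2, gap, params.ignore_strand):
            return _interval_gap(*a1), _interval_gap(*a2), size_ratio
    return None


def find_breakpoint_overlaps_naive(query: BreakpointSet, subject: BreakpointSet,
                                   params: MatchParams | None = None) -> list[BreakpointHit]:
    """All-pairs reference matcher (quadratic); the oracle for the indexed path."""
    params = params or MatchParams()
    hits = []
    subject_pairs = subject.breakpoint_pairs()
    for q1, q2 in query.breakpoint_pairs():
        for s1, s2 in subject_pairs:
            res = _pair_match(q1, q2, s1, s2, params)
            if res is not None:
                hits.append(BreakpointHit(q1.id, s1.id, res[0], res[1], res[2]))
    return hits


def find_breakpoint_overlaps(query: BreakpointSet, subject: BreakpointSet,
                             params: MatchParams | None = None) -> list[BreakpointHit]:
    """Find all matching breakpoint pairs between two call sets.

    Hit ids are pair ids (canonical-first breakend id of each pair).  Ties —
    one query pair matching several subject pairs — are all reported; use
    :func:`best_hits` for unambiguous one-to-one selection.  Single
    breakends never match pairs (see :func:`find_breakend_overlaps`).
    """
    params = params or MatchParams()
    g = params.maxgap
    trees: dict[str, IntervalTree] = {}
    spairs = subject.breakpoint_pairs()
    for idx, (s1, s2) in enumerate(spairs):
        for s in (s1, s2):
            trees.setdefault(s.contig, IntervalTree()).addi(
                s.lo - g, s.hi + g + 1, idx)
    hits = []
    for q1, q2 in query.breakpoint_pairs():
        tree = trees.get(q1.contig)
        if tree is None:
            continue
        candidates = {iv.data for iv in tree.overlap(q1.lo - g, q1.hi + g + 1)}
        for idx in sorted(candidates):
            s1, s2 = spairs[idx]
            res = _pair_match(q1, q2, s1, s2, params)
            if res is not None:
                hits.append(BreakpointHit(q1.id, s1.id, res[0], res[1], res[2]))
    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits


def count_breakpoint_overlaps(query: BreakpointSet, subject: BreakpointSet,
                              params: MatchParams | None = None) -> dict[str, int]:
    """Number of subject pairs matching each query pair (0 for unmatched).

    Enables truth/caller true-positive flagging:
    ``tp = {q: n > 0 for q, n in count_breakpoint_overlaps(truth, calls).items()}``.
    """
    counts = {q1.id: 0 for q1, _ in query.breakpoint_pairs()}
    for hit in find_breakpoint_overlaps(query, subject, params):
        counts[hit.query_id] += 1
    return counts


def find_breakend_overlaps(query: BreakpointSet, subject: BreakpointSet,
                           params: MatchParams | None = None) -> list[BreakpointHit]:
    """Match single breakends between two sets with the one-breakend rule."""
    params = params or MatchParams()
    hits = []
    subj = subject.singles()
    for q in query.singles():
        for s in subj:
            if _breakend_match(q, s, params.maxgap, params.ignore_strand):
                hits.append(BreakpointHit(q.id, s.id, _interval_gap(q, s), 0, None))
    return hits


def best_hits(hits: list[BreakpointHit]) -> list[BreakpointHit]:
    """One hit per query: smallest total gap, then size difference, then subject id."""
    best: dict[str, BreakpointHit] = {}
    for h in hits:
        key = (h.gap1 + h.gap2,
               h.size_ratio if h.size_ratio is not None else 0.0,
               h.subject_id)
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        ckey = (cur.gap1 + cur.gap2,
                cur.size_ratio if cur.size_ratio is not None else 0.0,
                cur.subject_id)
        if key < ckey:
            best[h.query_id] = h
    return sorted(best.values(), key=lambda h: h.query_id)
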
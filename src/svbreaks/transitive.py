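"""Transitive breakpoint detection.

A *transitive* call is a single reported junction that actually spans a path
through two or more real junctions lying close together on the derivative
chromosome — a read (or read pair) jumped across short intervening segments
and the caller fused the path into one breakpoint.  Transitive calls arise
from imprecise short-read calls and from precise long-read calls whose
intervening derivative sequence surfaces as inserted bases at the fused
junction.  They cause spurious mismatches between call sets and confound
derivative-chromosome reconstruction.

:func:`find_transitive_calls` explains candidate breakpoints as ordered
chains of constituent junctions: starting from a junction whose breakend
matches one side of the candidate, the search repeatedly crosses a junction
and walks along the retained reference sequence (bounded by
``max_segment_bp``) to the next junction facing back toward it, accepting
when the final junction's far breakend matches the candidate's other side.
For precise candidates the total traversed distance (reference segments plus
the constituents' own inserted bases) must agree with the candidate's insert
length within ``insert_tolerance_bp``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import Breakend, BreakpointSet

__all__ = [
    "TransitiveParams",
    "TransitiveChain",
    "traverse_step",
    "find_transitive_calls",
    "find_transitive_calls_bruteforce",
]


@dataclass(frozen=True)
class TransitiveParams:
    """Search bounds.

    max_segment_bp: maximum reference distance walked between consecutive
        junctions (default 1000 bp; intervening segments are typically much
        shorter).
    max_chain: maximum number of constituent junctions (default 3).
    insert_tolerance_bp: allowed |total traversed - insert length| for a
        precise candidate (default 25 bp).
    allow_imprecise: also explain imprecise candidates (no insert-length
        test is possible for them).
    bound_by_interval: optionally require the total traversed distance of an
        imprecise candidate to fit within its own location-interval width.
    """

    max_segment_bp: int = 1000
    max_chain: int = 3
    insert_tolerance_bp: int = 25
    allow_imprecise: bool = True
    bound_by_interval: bool = False


@dataclass(frozen=True)
class TransitiveChain:
    """One explanation of a candidate breakpoint as a junction path."""

    candidate_id: str
    constituent_ids: tuple[str, ...]
    segment_distances: tuple[int, ...]
    total_traversed: int
    classification: str  # 'precise-insert-explained' | 'imprecise-explained'


def _match(a: Breakend, b: Breakend) -> bool:
    """Interval-exact breakend equivalence (same rule as exact matching)."""
    return (a.contig == b.contig and a.orientation == b.orientation
            and a.lo <= b.hi and b.lo <= a.hi)


def traverse_step(bset: BreakpointSet, from_be: Breakend,
                  max_segment_bp: int) -> list[tuple[Breakend, int]]:
    """Junction breakends reachable from ``from_be`` along retained sequence.

    Having just crossed a junction and landed on ``from_be``, traversal
    continues into its retained flank: rightward (increasing coordinates)
    for a ``'-'`` breakend, leftward for ``'+'``.  The next junction must
    present a breakend on the same contig *facing back* toward ``from_be``
    (``'+'`` when walking rightward, ``'-'`` when leftward) within
    ``max_segment_bp``.  Distances are measured between nominal positions
    and widened by both breakends' uncertainty intervals.

    Returns ``(entry breakend of the next junction, segment distance)``
    tuples; cross via the entry breakend's partner to continue.
    """
    rightward = from_be.orientation == "-"
    facing = "+" if rightward else "-"
    out = []
    for be in bset:
        if be.partner_id is None or be.contig != from_be.contig:
            continue
        if be.orientation != facing or be.id == from_be.id:
            continue
        if rightward:
            d_lo, d_hi = be.lo - from_be.hi, be.hi - from_be.lo
            d_nom = be.nominal - from_be.nominal
        else:
            d_lo, d_hi = from_be.lo - be.hi, from_be.hi - be.lo
            d_nom = from_be.nominal - be.nominal
        if d_hi < 0 or d_lo > max_segment_bp:
            continue
        out.append((be, max(0, min(d_nom, max_segment_bp))))
    out.sort(key=lambda t: (t[1], t[0].id))
    return out


def _pair_lookup(bset: BreakpointSet):
    return {bset.pair_id(a): (a, b) for a, b in bset.breakpoint_pairs()}


def find_transitive_calls(bset: BreakpointSet,
                          params: TransitiveParams | None = None,
                          constituents: BreakpointSet | None = None
                          ) -> list[TransitiveChain]:
    """Explain breakpoints in ``bset`` as chains of >= 2 other junctions.

    Every partnered pair of ``bset`` is a candidate.  Constituent junctions
    are drawn from ``constituents`` when given (e.g. candidates from a
    short-read caller, constituents from a long-read caller), else from
    ``bset`` itself; a candidate never explains itself and no junction is
    used twice within a chain.  All minimal accepting chains are reported;
    nothing is filtered out of the input set.
    """
    params = params or TransitiveParams()
    cons = constituents if constituents is not None else bset
    chains: list[TransitiveChain] = []
    for x, y in bset.breakpoint_pairs():
        cand_id = bset.pair_id(x)
        precise = x.precise and y.precise
        if not precise and not params.allow_imprecise:
            continue
        m = len(x.insert_seq)
        seen: set[tuple[str, ...]] = set()

        def accept(total: int) -> bool:
            if precise:
                return abs(total - m) <= params.insert_tolerance_bp
            if params.bound_by_interval and total > x.width + y.width:
                return False
            return True

        def extend(exit_be: Breakend, used: tuple[str, ...],
                   segs: tuple[int, ...], ins_total: int):
            if len(used) >= 2 and _match(exit_be, y):
                total = ins_total + sum(segs)
                if accept(total) and used not in seen:
                    seen.add(used)
                    chains.append(TransitiveChain(
                        cand_id, used, segs, total,
                        "precise-insert-explained" if precise
                        else "imprecise-explained"))
                return  # a path is closed the first time it reaches the far side
            if len(used) >= params.max_chain:
                return
            for entry, d in traverse_step(cons, exit_be, params.max_segment_bp):
                pid = cons.pair_id(entry)
                if pid in used or pid == cand_id:
                    continue
                extend(cons.by_id[entry.partner_id], used + (pid,),
                       segs + (d,), ins_total + len(entry.insert_seq))

        for a, b in cons.breakpoint_pairs():
            for entry, exit_be in ((a, b), (b, a)):
                pid = cons.pair_id(entry)
                if pid == cand_id:
                    continue
                if _match(entry, x):
                    extend(exit_be, (pid,), (), len(entry.insert_seq))
    chains.sort(key=lambda c: (c.candidate_id, c.constituent_ids))
    return chains


# --------------------------------------------------------------------------- #
# exhaustive reference implementation

def find_transitive_calls_bruteforce(bset: BreakpointSet,
                                     params: TransitiveParams | None = None,
                                     constituents: BreakpointSet | None = None
                                     ) -> list[TransitiveChain]:
    """Enumerate every ordered junction sequence of length 2..max_chain and
    keep those forming a valid chain; reference oracle for small sets.

    The link rule is evaluated directly from the geometry: after crossing a
    junction into breakend ``p``, the next junction's entry breakend ``b``
    must lie on ``p``'s retained side (higher coordinates when ``p`` is
    ``'-'``, lower when ``'+'``), face back toward ``p``, and be within
    ``max_segment_bp``.
    """
    params = params or TransitiveParams()
    cons = constituents if constituents is not None else bset
    cpairs = cons.breakpoint_pairs()
    results: list[TransitiveChain] = []

    def link_ok(p: Breakend, b: Breakend):
        """Segment distance from exit breakend ``p`` to entry breakend ``b``,
        or None when the geometry forbids the step."""
        if b.contig != p.contig:
            return None
        if p.orientation == "-":  # walk rightward; next junction faces '+'
            if b.orientation != "+":
                return None
            lo, hi, nom = b.lo - p.hi, b.hi - p.lo, b.nominal - p.nominal
        else:  # walk leftward; next junction faces '-'
            if b.orientation != "-":
                return None
            lo, hi, nom = p.lo - b.hi, p.hi - b.lo, p.nominal - b.nominal
        if hi < 0 or lo > params.max_segment_bp:
            return None
        return max(0, min(nom, params.max_segment_bp))

    def evaluate(seq, x, y, precise, m):
        """(reaches_y, accepted, segs, total) for one ordered, oriented chain."""
        if not _match(seq[0][0][seq[0][1]], x):
            return False, False, (), 0
        segs = []
        total_ins = 0
        for i, (pair, eidx) in enumerate(seq):
            total_ins += len(pair[eidx].insert_seq)
            if i:
                prev_pair, pidx = seq[i - 1]
                d = link_ok(prev_pair[1 - pidx], pair[eidx])
                if d is None:
                    return False, False, (), 0
                segs.append(d)
        last_pair, lidx = seq[-1]
        if not _match(last_pair[1 - lidx], y):
            return False, False, tuple(segs), 0
        total = total_ins + sum(segs)
        if precise:
            ok = abs(total - m) <= params.insert_tolerance_bp
        else:
            ok = not (params.bound_by_interval and total > x.width + y.width)
        return True, ok, tuple(segs), total

    for x, y in bset.breakpoint_pairs():
        cand_id = bset.pair_id(x)
        precise = x.precise and y.precise
        if not precise and not params.allow_imprecise:
            continue
        m = len(x.insert_seq)
        found = set()
        label = "precise-insert-explained" if precise else "imprecise-explained"
        usable = [p for p in cpairs if cons.pair_id(p[0]) != cand_id]
        n = len(usable)

        def emit(seq):
            reaches, ok, segs, total = evaluate(seq, x, y, precise, m)
            if reaches and ok:
                ids = tuple(cons.pair_id(p[0]) for p, _ in seq)
                if ids not in found:
                    found.add(ids)
                    results.append(TransitiveChain(cand_id, ids, segs, total, label))
            return reaches

        for i in range(n):
            for ei in (0, 1):
                if not _match(usable[i][ei], x):
                    continue
                for j in range(n):
                    if j == i:
                        continue
                    for ej in (0, 1):
                        two = [(usable[i], ei), (usable[j], ej)]
                        reaches_two = emit(two)
                        if params.max_chain < 3 or reaches_two:
                            continue  # a path closes when it first reaches the far side
                        for k in range(n):
                            if k in (i, j):
                                continue
                            for ek in (0, 1):
                                emit(two + [(usable[k], ek)])
    results.sort(key=lambda c: (c.candidate_id, c.constituent_ids))
    return results
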
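"""Paired-breakend data model for structural variant junctions.

A structural variant is decomposed into *breakpoints*: novel adjacencies on a
derivative chromosome.  Each breakpoint consists of two *breakends* joined at
a junction; each breakend is a located, oriented position on a reference
contig.  Multi-breakpoint events (inversions) become several breakpoints, and
a junction whose far side could not be placed is a *single breakend* with no
partner.

Orientation convention
----------------------
``'+'``
    the retained (joined) segment extends toward *lower* coordinates: the
    junction occurs immediately to the right of the breakend base when
    reading the reference left-to-right.
``'-'``
    the retained segment extends toward *higher* coordinates.

Under this convention a deletion is a ``(+,-)`` pair ordered by coordinate, a
tandem duplication is ``(-,+)``, and an inversion decomposes into one
``(+,+)`` and one ``(-,-)`` breakpoint.

Positions are 1-based inclusive throughout (VCF convention).  A breakend is
located on an interval ``[lo, hi]`` rather than a point: for an imprecise
call the interval is the caller's confidence interval; for a precise call
with breakpoint microhomology it is the homologous range over which the
junction may equivalently be placed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from .errors import (
    AsymmetricPartner,
    DanglingPartner,
    DuplicateId,
    MismatchedInsert,
    UnknownId,
)

ORIENTATIONS = ("+", "-")

_ALLOWED_SEQ = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence over the ACGTN alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Breakend:
    """One side of a junction.

    Attributes
    ----------
    id : str
        Unique identifier within a :class:`BreakpointSet`.
    contig : str
        Reference sequence name.
    lo, hi : int
        1-based inclusive bounds of the location interval, ``lo <= hi``.
    nominal : int
        Caller-reported position, ``lo <= nominal <= hi``.
    orientation : str
        ``'+'`` or ``'-'`` (see module docstring).
    partner_id : str or None
        Id of the mate breakend; ``None`` for a single breakend.
    insert_seq : str
        Sequence inserted at the junction (possibly empty); for single
        breakends, the unanchored assembled sequence.  Stored identically on
        both mates, read along the derivative in canonical pair order.
    homology_len : int
        Breakpoint microhomology length in bp.
    precise : bool
        True when the junction is base-pair resolved.  A precise breakend
        with ``hi > lo`` is interpreted as homology, so ``homology_len`` must
        cover the interval width.
    qual, filter : optional passthrough of the source record.
    event_id : str or None
        Source record identifier for provenance.
    """

    id: str
    contig: str
    lo: int
    hi: int
    nominal: int
    orientation: str
    partner_id: Optional[str] = None
    insert_seq: str = ""
    homology_len: int = 0
    precise: bool = True
    qual: Optional[float] = None
    filter: Optional[str] = None
    event_id: Optional[str] = None

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"breakend {self.id!r}: orientation must be '+' or '-', "
                f"got {self.orientation!r}"
            )
        if self.lo < 1:
            raise ValueError(f"breakend {self.id!r}: lo must be >= 1, got {self.lo}")
        if not (self.lo <= self.nominal <= self.hi):
            raise ValueError(
                f"breakend {self.id!r}: require lo <= nominal <= hi, "
                f"got {self.lo} <= {self.nominal} <= {self.hi}"
            )
        if self.homology_len < 0:
            raise ValueError(f"breakend {self.id!r}: homology_len must be >= 0")
        if self.precise and self.width > 0 and self.homology_len < self.width:
            raise ValueError(
                f"breakend {self.id!r}: precise interval of width {self.width} "
                f"requires homology_len >= width (got {self.homology_len})"
            )
        bad = set(self.insert_seq.upper()) - _ALLOWED_SEQ
        if bad:
            raise ValueError(
                f"breakend {self.id!r}: insert_seq contains non-ACGTN characters {bad}"
            )

    @property
    def width(self) -> int:
        """Interval width ``hi - lo`` (0 for a point breakend)."""
        return self.hi - self.lo

    @property
    def is_single(self) -> bool:
        return self.partner_id is None


class BreakpointSet:
    """Validated collection of breakends with a partner involution.

    The universal exchange object between all modules: every ingest routine
    produces one, every matcher consumes two.  Construction checks id
    uniqueness, partner reciprocity and insert-sequence agreement between
    mates, raising :class:`~svbreaks.errors.DuplicateId`,
    :class:`~svbreaks.errors.DanglingPartner`,
    :class:`~svbreaks.errors.AsymmetricPartner` or
    :class:`~svbreaks.errors.MismatchedInsert`.

    Parameters
    ----------
    breakends : iterable of Breakend
    contig_order : sequence of str, optional
        Ordering of contigs (typically the source header order) used for
        canonical pair ordering; contigs not listed sort after the listed
        ones, lexicographically.
    """

    def __init__(self, breakends: Iterable[Breakend], contig_order=None):
        self.breakends = list(breakends)
        self.contig_order = list(contig_order) if contig_order else []
        self._rank = {c: i for i, c in enumerate(self.contig_order)}
        self.by_id = {}
        for be in self.breakends:
            if be.id in self.by_id:
                raise DuplicateId(be.id)
            self.by_id[be.id] = be
        for be in self.breakends:
            if be.partner_id is None:
                continue
            mate = self.by_id.get(be.partner_id)
            if mate is None:
                raise DanglingPartner(be.partner_id, be.id)
            if mate.partner_id != be.id:
                raise AsymmetricPartner(mate.id)
            if mate.insert_seq != be.insert_seq:
                raise MismatchedInsert(be.id)

    # -- basic container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.breakends)

    def __iter__(self) -> Iterator[Breakend]:
        return iter(self.breakends)

    def __contains__(self, bnd_id: str) -> bool:
        return bnd_id in self.by_id

    def get(self, bnd_id: str) -> Breakend:
        try:
            return self.by_id[bnd_id]
        except KeyError:
            raise UnknownId(bnd_id) from None

    # -- ordering -----------------------------------------------------------------

    def contig_key(self, contig: str):
        r = self._rank.get(contig)
        return (0, r, "") if r is not None else (1, 0, contig)

    def sort_key(self, be: Breakend):
        """Total order over breakends: contig rank, nominal, orientation, id."""
        return (self.contig_key(be.contig), be.nominal,
                0 if be.orientation == "+" else 1, be.id)

    # -- queries ------------------------------------------------------------------

    def partner_of(self, bnd_id: str) -> Optional[Breakend]:
        """Mate of the given breakend, or None for a single breakend."""
        be = self.get(bnd_id)
        if be.partner_id is None:
            return None
        return self.by_id[be.partner_id]

    def singles(self) -> list[Breakend]:
        """Single (partner-less) breakends, in canonical order."""
        return sorted((b for b in self.breakends if b.is_single), key=self.sort_key)

    def breakpoint_pairs(self) -> list[tuple[Breakend, Breakend]]:
        """Each partnered pair exactly once, canonically ordered.

        The lower breakend under :meth:`sort_key` comes first in each tuple;
        tuples are sorted by that first breakend.  Single breakends are
        excluded.
        """
        pairs = []
        for be in self.breakends:
            if be.partner_id is None:
                continue
            mate = self.by_id[be.partner_id]
            if self.sort_key(be) < self.sort_key(mate):
                pairs.append((be, mate))
        pairs.sort(key=lambda p: self.sort_key(p[0]))
        return pairs

    def pair_id(self, be: Breakend) -> str:
        """Identifier of the pair containing ``be``: the canonical-first mate's id."""
        if be.partner_id is None:
            return be.id
        mate = self.by_id[be.partner_id]
        return be.id if self.sort_key(be) < self.sort_key(mate) else mate.id


def make_breakpoint_set(breakends: Iterable[Breakend], contig_order=None) -> BreakpointSet:
    """Validate a list of breakends into a :class:`BreakpointSet`."""
    return BreakpointSet(breakends, contig_order=contig_order)


def partner_of(bset: BreakpointSet, bnd_id: str) -> Optional[Breakend]:
    """Functional alias for :meth:`BreakpointSet.partner_of`."""
    return bset.partner_of(bnd_id)


def breakpoint_pairs(bset: BreakpointSet) -> list[tuple[Breakend, Breakend]]:
    """Functional alias for :meth:`BreakpointSet.breakpoint_pairs`."""
    return bset.breakpoint_pairs()


def pair_span(b1: Breakend, b2: Breakend) -> Optional[int]:
    """Event span of an intrachromosomal pair, ``|nominal2 - nominal1|``.

    None for interchromosomal pairs.  Mirrors deletion/duplication length up
    to +/-1; used only for relative size comparisons.
    """
    if b1.contig != b2.contig:
        return None
    return abs(b2.nominal - b1.nominal)


def clone_breakend(be: Breakend, **changes) -> Breakend:
    """Return a copy of ``be`` with the given fields replaced."""
    return replace(be, **changes)
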
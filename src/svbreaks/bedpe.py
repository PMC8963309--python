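"""BEDPE reading and writing for breakpoint sets.

BEDPE (bedtools dialect) stores one breakpoint per row as two 0-based
half-open intervals plus strands; the conversion to the model's 1-based
inclusive intervals is ``lo = start + 1``, ``hi = end``.  The strand columns
map directly onto breakend orientation.  Plain 10-column BEDPE cannot carry
nominal positions, inserted sequence, homology or precision; an *extended*
variant appends those after column 10 so round trips are lossless.  Single
breakends cannot be expressed in BEDPE at all and are skipped with a warning
on write.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TextIO, Union

from .errors import MalformedRow
from .model import Breakend, BreakpointSet

log = logging.getLogger("svbreaks")

EXTENDED_MARKER = "#svbreaks-bedpe-extended"
_EXTRA_COLS = ["nominal1", "nominal2", "insert_seq", "homology_len", "precise"]


def _open(source, mode="r"):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def read_bedpe(source) -> BreakpointSet:
    """Read BEDPE (path or text stream) into a :class:`BreakpointSet`.

    Rows need >= 10 tab-separated columns; ``#`` lines are comments.  A file
    written by :func:`write_bedpe` with ``extended=True`` announces itself
    with a marker comment and restores nominal positions, inserts, homology
    and precision; otherwise the nominal position is the interval lower bound
    and precision is inferred from interval width.
    """
    fh, close = _open(source)
    extended = False
    breakends = []
    contig_order: list[str] = []
    try:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith(EXTENDED_MARKER):
                    extended = True
                continue
            cols = line.split("\t")
            if len(cols) < 10:
                raise MalformedRow(line_no, f"expected >= 10 columns, got {len(cols)}")
            c1, c2 = cols[0], cols[3]
            try:
                s1, e1, s2, e2 = int(cols[1]), int(cols[2]), int(cols[4]), int(cols[5])
            except ValueError:
                raise MalformedRow(line_no, "non-integer interval bounds") from None
            if s1 >= e1 or s2 >= e2:
                raise MalformedRow(line_no, "start must be < end (0-based half-open)")
            name = cols[6] if cols[6] not in (".", "") else f"bedpe{line_no}"
            score = cols[7]
            o1, o2 = cols[8], cols[9]
            if o1 not in "+-" or o2 not in "+-":
                raise MalformedRow(line_no, f"bad strand columns {o1!r}/{o2!r}")
            qual = None
            if score not in (".", ""):
                try:
                    qual = float(score)
                except ValueError:
                    raise MalformedRow(line_no, f"non-numeric score {score!r}") from None
            lo1, hi1, lo2, hi2 = s1 + 1, e1, s2 + 1, e2
            nom1, nom2, insert, homlen, precise1, precise2 = (
                lo1, lo2, "", 0, hi1 == lo1, hi2 == lo2)
            if extended and len(cols) >= 15:
                try:
                    nom1, nom2 = int(cols[10]), int(cols[11])
                    insert = "" if cols[12] == "." else cols[12]
                    homlen = int(cols[13])
                    precise1 = precise2 = cols[14] == "1"
                except ValueError:
                    raise MalformedRow(line_no, "bad extended columns") from None
            id1, id2 = f"{name}_1", f"{name}_2"
            breakends.append(Breakend(
                id=id1, contig=c1, lo=lo1, hi=hi1, nominal=nom1, orientation=o1,
                partner_id=id2, insert_seq=insert, homology_len=homlen,
                precise=precise1, qual=qual, event_id=name))
            breakends.append(Breakend(
                id=id2, contig=c2, lo=lo2, hi=hi2, nominal=nom2, orientation=o2,
                partner_id=id1, insert_seq=insert, homology_len=homlen,
                precise=precise2, qual=qual, event_id=name))
            for c in (c1, c2):
                if c not in contig_order:
                    contig_order.append(c)
    finally:
        if close:
            fh.close()
    return BreakpointSet(breakends, contig_order=contig_order)


def write_bedpe(bset: BreakpointSet, dest, extended: bool = False) -> int:
    """Write partnered pairs as BEDPE rows; returns the row count.

    The name column carries the pair id (canonical-first breakend id).
    Interchromosomal rows keep canonical side order.  With ``extended=True``
    five extra columns (nominal1, nominal2, insert_seq, homology_len,
    precise) follow the standard ten, plus a marker comment so
    :func:`read_bedpe` can restore them.  Single breakends are skipped with a
    warning.
    """
    fh, close = _open(dest, "w")
    n = 0
    try:
        if extended:
            fh.write(EXTENDED_MARKER + "\t" + "\t".join(_EXTRA_COLS) + "\n")
        for a, b in bset.breakpoint_pairs():
            cols = [
                a.contig, str(a.lo - 1), str(a.hi),
                b.contig, str(b.lo - 1), str(b.hi),
                bset.pair_id(a),
                "." if a.qual is None else f"{a.qual:g}",
                a.orientation, b.orientation,
            ]
            if extended:
                cols += [str(a.nominal), str(b.nominal),
                         a.insert_seq or ".",
                         str(max(a.homology_len, b.homology_len)),
                         "1" if (a.precise and b.precise) else "0"]
            fh.write("\t".join(cols) + "\n")
            n += 1
        for s in bset.singles():
            log.warning("single breakend %s cannot be expressed in BEDPE; skipped", s.id)
    finally:
        if close:
            fh.close()
    return n
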
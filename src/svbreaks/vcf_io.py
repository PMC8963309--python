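"""VCF ingest and export for every structural-variant notation.

The VCF specifications allow the same junction to be written four ways:
direct REF/ALT sequence, symbolic alleles (``<DEL>``, ``<DUP>``, ``<INS>``,
``<INV>``), paired BND records with bracketed ALT strings linked by MATEID,
and single-breakend ALTs (``.s`` / ``s.``).  Popular callers additionally use
non-compliant dialects (``SVTYPE=TRA``/``CTX`` with ``CHR2``/``END``,
Pindel-style ``RPL``, DELLY ``CT`` connection types, ``INV3``/``INV5``
half-inversions).  :func:`breakpoint_ranges` converts all of them into one
:class:`~svbreaks.model.BreakpointSet`; :func:`write_bnd_vcf` is its inverse,
emitting spec-compliant BND records.

``<DEL>`` and ``<DUP>`` are treated as breakpoint (not copy-number) calls,
and inversions are decomposed into their two constituent breakpoints.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Union

import pysam

from .errors import (
    InvertedInterval,
    MalformedAlt,
    MissingEnd,
    NegativeSpan,
)
from .model import Breakend, BreakpointSet, revcomp

log = logging.getLogger("svbreaks")

__all__ = [
    "SvRecord",
    "BndAltParts",
    "IngestConfig",
    "parse_bnd_alt",
    "render_bnd_alt",
    "symbolic_to_breakends",
    "direct_alt_to_breakends",
    "apply_uncertainty",
    "normalize_dialect",
    "breakpoint_ranges",
    "breakend_ranges",
    "write_bnd_vcf",
]


# --------------------------------------------------------------------------- #
# record model

@dataclass
class SvRecord:
    """One VCF record reduced to the fields breakpoint conversion needs."""

    contig: str
    pos: int  # 1-based
    vcf_id: str
    ref: str
    alt: str
    info: dict = field(default_factory=dict)
    qual: Optional[float] = None
    filter: Optional[str] = None
    line: int = 0

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"record {self.vcf_id!r}: pos must be >= 1")
        ci = self.info.get("CIPOS")
        if ci is not None and ci[0] > ci[1]:
            raise InvertedInterval(f"record {self.vcf_id!r}: CIPOS {ci}")


@dataclass
class BndAltParts:
    """Decomposition of a bracketed or single-breakend ALT string."""

    mate_contig: Optional[str]
    mate_pos: Optional[int]
    local_orientation: str
    mate_orientation: Optional[str]
    insert_seq: str
    is_single: bool = False


@dataclass
class IngestConfig:
    """Knobs for :func:`breakpoint_ranges`.

    min_sv_size: direct-sequence records with a smaller REF/ALT length
    difference are skipped (customary 50 bp SV floor).
    unmated_policy: what to do with a BND record whose mate line is missing —
    ``"downgrade"`` keeps it as a single breakend, ``"drop"`` discards it.
    """

    min_sv_size: int = 50
    unmated_policy: str = "downgrade"  # or "drop"


# --------------------------------------------------------------------------- #
# BND ALT algebra

_BND_RE = re.compile(
    r"^(?P<t1>[ACGTNacgtn]*)(?P<b1>[\[\]])(?P<mate>[^\[\]:]+):(?P<pos>\d+)"
    r"(?P<b2>[\[\]])(?P<t2>[ACGTNacgtn]*)$"
)
_SINGLE_LEFT_RE = re.compile(r"^\.(?P<s>[ACGTNacgtn]+)$")   # .s  -> '-'
_SINGLE_RIGHT_RE = re.compile(r"^(?P<s>[ACGTNacgtn]+)\.$")  # s.  -> '+'


def parse_bnd_alt(alt: str, ref: str) -> BndAltParts:
    """Parse a breakend ALT string into its junction components.

    Orientation mapping for the four bracketed forms (``t`` = REF anchor plus
    inserted bases, ``p`` = mate position)::

        t[p[   local '+'  mate '-'
        t]p]   local '+'  mate '+'
        ]p]t   local '-'  mate '+'
        [p[t   local '-'  mate '-'

    Single-breakend forms: ``.s`` is a ``'-'`` breakend, ``s.`` a ``'+'``
    breakend; the unanchored bases of ``s`` (beyond the REF anchor) become
    ``insert_seq``.

    Raises :class:`~svbreaks.errors.MalformedAlt` for anything else
    (including symbolic alleles).
    """
    m = _SINGLE_LEFT_RE.match(alt)
    if m:
        s = m.group("s").upper()
        if not s.endswith(ref.upper()):
            raise MalformedAlt(f"single-breakend ALT {alt!r} does not end with REF {ref!r}")
        return BndAltParts(None, None, "-", None, s[: len(s) - len(ref)], is_single=True)
    m = _SINGLE_RIGHT_RE.match(alt)
    if m:
        s = m.group("s").upper()
        if not s.startswith(ref.upper()):
            raise MalformedAlt(f"single-breakend ALT {alt!r} does not start with REF {ref!r}")
        return BndAltParts(None, None, "+", None, s[len(ref):], is_single=True)
    m = _BND_RE.match(alt)
    if not m:
        raise MalformedAlt(f"unparseable breakend ALT {alt!r}")
    t1, b1, b2, t2 = m.group("t1"), m.group("b1"), m.group("b2"), m.group("t2")
    if b1 != b2 or bool(t1) == bool(t2):
        raise MalformedAlt(f"unparseable breakend ALT {alt!r}")
    mate_contig = m.group("mate")
    mate_pos = int(m.group("pos"))
    if t1:  # t[p[ or t]p]
        t = t1.upper()
        if not t.startswith(ref.upper()):
            raise MalformedAlt(f"ALT {alt!r} does not start with REF {ref!r}")
        insert = t[len(ref):]
        local = "+"
        mate = "-" if b1 == "[" else "+"
    else:  # ]p]t or [p[t
        t = t2.upper()
        if not t.endswith(ref.upper()):
            raise MalformedAlt(f"ALT {alt!r} does not end with REF {ref!r}")
        insert = t[: len(t) - len(ref)]
        local = "-"
        mate = "+" if b1 == "]" else "-"
    return BndAltParts(mate_contig, mate_pos, local, mate, insert)


def render_bnd_alt(parts: BndAltParts, ref: str) -> str:
    """Inverse of :func:`parse_bnd_alt`; byte-exact on the four bracketed forms."""
    if parts.is_single:
        if parts.local_orientation == "+":
            return f"{ref}{parts.insert_seq}."
        return f".{parts.insert_seq}{ref}"
    p = f"{parts.mate_contig}:{parts.mate_pos}"
    if parts.local_orientation == "+":
        t = ref + parts.insert_seq
        return f"{t}[{p}[" if parts.mate_orientation == "-" else f"{t}]{p}]"
    t = parts.insert_seq + ref
    return f"]{p}]{t}" if parts.mate_orientation == "+" else f"[{p}[{t}"


# --------------------------------------------------------------------------- #
# symbolic and direct notations

def _scalar(v):
    if isinstance(v, (tuple, list)):
        return v[0] if v else None
    return v


def _resolve_end(rec: SvRecord) -> Optional[int]:
    end = rec.info.get("END")
    if end is not None:
        return int(_scalar(end))
    svlen = rec.info.get("SVLEN")
    if svlen is not None:
        return rec.pos + abs(int(_scalar(svlen)))
    return None


def symbolic_to_breakends(rec: SvRecord) -> list[Breakend]:
    """Decompose a symbolic-allele record into breakends.

    With ``p`` = POS and ``e`` = END (1-based, END from INFO/END or
    POS+|SVLEN|)::

        <DEL>  ->  (p,'+') <-> (e+1,'-')      junction joins p to e+1
        <DUP>  ->  (p+1,'-') <-> (e,'+')      tandem copy joins e back to p+1
        <INS>  ->  (p,'+') <-> (p+1,'-')      with the inserted sequence
        <INV>  ->  (p,'+')<->(e,'+')  and  (p+1,'-')<->(e+1,'-')

    Subtype suffixes (``<DUP:TANDEM>``, ``<DEL:ME:ALU>``) are handled by
    their top-level token.  An ``INV_SINGLE`` info marker (set by
    :func:`normalize_dialect` for INV3/INV5 flags) restricts an inversion to
    the corresponding single breakpoint.
    """
    token = rec.alt.strip("<>").split(":")[0].upper()
    p = rec.pos
    rid = rec.vcf_id
    ev = rec.info.get("EVENT", rid)

    def be(k, i, contig, pos, orient, partner, insert=""):
        return Breakend(
            id=f"{rid}_bp{k}_{i}", contig=contig, lo=pos, hi=pos, nominal=pos,
            orientation=orient, partner_id=partner, insert_seq=insert,
            qual=rec.qual, filter=rec.filter, event_id=ev,
        )

    if token == "INS":
        svlen = rec.info.get("SVLEN")
        seq = rec.info.get("SVINSSEQ")
        if seq is not None:
            seq = str(_scalar(seq)).upper()
        elif svlen is not None:
            seq = "N" * abs(int(_scalar(svlen)))
        else:
            seq = ""
        a = be(1, 1, rec.contig, p, "+", f"{rid}_bp1_2", seq)
        b = be(1, 2, rec.contig, p + 1, "-", f"{rid}_bp1_1", seq)
        return [a, b]

    e = _resolve_end(rec)
    if e is None:
        raise MissingEnd(f"record {rid!r}: {token} without END or SVLEN")
    if e < p:
        raise NegativeSpan(f"record {rid!r}: END {e} < POS {p}")

    if token == "DEL":
        ins = rec.info.get("_RPL_INSERT", "")
        return [be(1, 1, rec.contig, p, "+", f"{rid}_bp1_2", ins),
                be(1, 2, rec.contig, e + 1, "-", f"{rid}_bp1_1", ins)]
    if token == "DUP":
        return [be(1, 1, rec.contig, p + 1, "-", f"{rid}_bp1_2"),
                be(1, 2, rec.contig, e, "+", f"{rid}_bp1_1")]
    if token == "INV":
        which = rec.info.get("INV_SINGLE")
        pairs = []
        if which in (None, "3"):
            pairs += [be(1, 1, rec.contig, p, "+", f"{rid}_bp1_2"),
                      be(1, 2, rec.contig, e, "+", f"{rid}_bp1_1")]
        if which in (None, "5"):
            pairs += [be(2, 1, rec.contig, p + 1, "-", f"{rid}_bp2_2"),
                      be(2, 2, rec.contig, e + 1, "-", f"{rid}_bp2_1")]
        return pairs
    raise MalformedAlt(f"record {rid!r}: unsupported symbolic allele {rec.alt!r}")


def direct_alt_to_breakends(rec: SvRecord, config: IngestConfig | None = None) -> list[Breakend]:
    """Convert a direct REF/ALT sequence record into breakends.

    Left-aligns the changed span by trimming the common prefix (which always
    includes the anchor base) and suffix.  Net deletions become DEL-style
    pairs, net insertions INS-style pairs carrying the inserted bases, and
    replacements DEL-style pairs with an insert.  Records whose length
    difference is below ``min_sv_size`` return ``[]`` (not structural).
    """
    config = config or IngestConfig()
    ref = rec.ref.upper()
    alt = rec.alt.upper()
    if not re.fullmatch(r"[ACGTN]+", alt):
        raise MalformedAlt(f"record {rec.vcf_id!r}: ALT {rec.alt!r} is not a plain sequence")
    if abs(len(ref) - len(alt)) < config.min_sv_size:
        return []
    k = 0
    while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
        k += 1
    k = max(k, 1)  # the anchor base is always shared
    ref_mid, alt_mid = ref[k:], alt[k:]
    s = 0
    while s < min(len(ref_mid), len(alt_mid)) and ref_mid[len(ref_mid) - 1 - s] == alt_mid[len(alt_mid) - 1 - s]:
        s += 1
    if s:
        ref_mid, alt_mid = ref_mid[:-s], alt_mid[:-s]
    if not ref_mid and not alt_mid:
        return []
    rid = rec.vcf_id
    ev = rec.info.get("EVENT", rid)
    left = rec.pos + k - 1

    def be(i, pos, orient, insert):
        return Breakend(
            id=f"{rid}_bp1_{i}", contig=rec.contig, lo=pos, hi=pos, nominal=pos,
            orientation=orient, partner_id=f"{rid}_bp1_{3 - i}", insert_seq=insert,
            qual=rec.qual, filter=rec.filter, event_id=ev,
        )

    if ref_mid:  # deletion or replacement
        right = left + len(ref_mid) + 1
        return [be(1, left, "+", alt_mid), be(2, right, "-", alt_mid)]
    # pure insertion
    return [be(1, left, "+", alt_mid), be(2, left + 1, "-", alt_mid)]


def apply_uncertainty(be: Breakend, rec: SvRecord, side: str = "auto") -> Breakend:
    """Attach the record's positional uncertainty to one breakend.

    ``side`` selects CIPOS (``"pos"``) or CIEND (``"end"``, falling back to
    CIPOS when CIEND is absent — symmetric uncertainty is the
    least-surprising default); ``"auto"`` picks the END side for breakends
    placed at the record's END coordinate.  HOMLEN (or len(HOMSEQ)) becomes
    ``homology_len`` and the IMPRECISE flag clears ``precise``.  A precise
    breakend whose interval is wider than the reported homology has its
    homology length raised to the interval width, since for a precise call
    the interval *is* homology.
    """
    if side == "auto":
        side = "pos"
        end = rec.info.get("END")
        if end is not None and abs(be.nominal - int(_scalar(end))) <= 1 \
                and abs(be.nominal - rec.pos) > 1:
            side = "end"
    ci = None
    if side == "end":
        ci = rec.info.get("CIEND")
    if ci is None:
        ci = rec.info.get("CIPOS")
    lo, hi = be.nominal, be.nominal
    if ci is not None:
        a, b = int(ci[0]), int(ci[1])
        if a > b:
            raise InvertedInterval(f"record {rec.vcf_id!r}: CI ({a},{b})")
        lo, hi = max(1, be.nominal + a), be.nominal + b
    homlen = rec.info.get("HOMLEN")
    if homlen is None:
        homseq = rec.info.get("HOMSEQ")
        homlen = len(str(_scalar(homseq))) if homseq is not None else 0
    homlen = int(_scalar(homlen))
    precise = not rec.info.get("IMPRECISE", False)
    if precise:
        homlen = max(homlen, hi - lo)
    return replace(be, lo=lo, hi=hi, homology_len=homlen, precise=precise)


# --------------------------------------------------------------------------- #
# caller dialects

_CT_MAP = {"3": "+", "5": "-"}


def _ct_orientations(rec: SvRecord):
    ct = rec.info.get("CT")
    if ct is not None:
        m = re.fullmatch(r"([35])to([35])", str(_scalar(ct)))
        if m:
            return _CT_MAP[m.group(1)], _CT_MAP[m.group(2)]
        log.warning("record %s: unrecognized CT value %r; using default (+,-)",
                    rec.vcf_id, ct)
    strands = rec.info.get("STRANDS")
    if strands is not None:
        s = str(_scalar(strands))[:2]
        if len(s) == 2 and set(s) <= {"+", "-"}:
            return s[0], s[1]
        log.warning("record %s: unrecognized STRANDS value %r; using default (+,-)",
                    rec.vcf_id, strands)
    return "+", "-"


def normalize_dialect(rec: SvRecord, caller_hint: Optional[str] = None) -> list[SvRecord]:
    """Rewrite non-spec caller conventions into spec-compliant records.

    * ``SVTYPE=TRA``/``CTX`` with ``CHR2``/``END`` becomes two reciprocal BND
      records; orientations come from DELLY ``CT`` (3 = '+', 5 = '-') or
      LUMPY ``STRANDS`` when present, else default to ``(+,-)``.
    * Pindel ``SVTYPE=RPL`` becomes a deletion carrying the replacement
      sequence as junction insert.
    * ``INV3``/``INV5`` flags restrict an inversion to its 3'-3' (``(+,+)``)
      or 5'-5' (``(-,-)``) breakpoint.
    * ``UNK`` / ``IMPRECISE_DIR`` constructs are recognized, warned about and
      skipped (their semantics are caller-private).
    * Anything else passes through unchanged.

    Returns a list (a TRA rewrite yields two records; a skip yields none).
    """
    svtype = rec.info.get("SVTYPE")
    if svtype in ("TRA", "CTX"):
        chr2 = rec.info.get("CHR2")
        end = rec.info.get("END") or rec.info.get("POS2")
        if chr2 is None or end is None:
            log.warning("record %s: %s without CHR2/END; skipped", rec.vcf_id, svtype)
            return []
        end = int(_scalar(end))
        o1, o2 = _ct_orientations(rec)
        id1, id2 = f"{rec.vcf_id}_bp1_1", f"{rec.vcf_id}_bp1_2"
        ev = rec.info.get("EVENT", rec.vcf_id)
        alt1 = render_bnd_alt(BndAltParts(str(_scalar(chr2)), end, o1, o2, ""), rec.ref[:1] or "N")
        alt2 = render_bnd_alt(BndAltParts(rec.contig, rec.pos, o2, o1, ""), "N")
        base = {k: v for k, v in rec.info.items()
                if k in ("CIPOS", "HOMLEN", "HOMSEQ", "IMPRECISE")}
        info1 = dict(base, SVTYPE="BND", MATEID=id2, EVENT=ev)
        info2 = dict(base, SVTYPE="BND", MATEID=id1, EVENT=ev)
        if "CIEND" in rec.info:
            info2["CIPOS"] = rec.info["CIEND"]
        return [
            SvRecord(rec.contig, rec.pos, id1, rec.ref[:1] or "N", alt1, info1,
                     rec.qual, rec.filter, rec.line),
            SvRecord(str(_scalar(chr2)), end, id2, "N", alt2, info2,
                     rec.qual, rec.filter, rec.line),
        ]
    if svtype == "RPL":
        info = dict(rec.info, SVTYPE="DEL")
        insert = ""
        if re.fullmatch(r"[ACGTNacgtn]{2,}", rec.alt or ""):
            insert = rec.alt.upper()[1:]  # beyond the anchor base
        elif rec.info.get("NTLEN") is not None:
            insert = "N" * int(_scalar(rec.info["NTLEN"]))
        info["_RPL_INSERT"] = insert
        return [SvRecord(rec.contig, rec.pos, rec.vcf_id, rec.ref, "<DEL>", info,
                         rec.qual, rec.filter, rec.line)]
    if svtype in ("UNK", "IMPRECISE_DIR") or rec.alt in ("<UNK>",):
        log.warning("record %s: %s construct has no defined breakpoint semantics; skipped",
                    rec.vcf_id, svtype or rec.alt)
        return []
    if (svtype == "INV" or rec.alt.startswith("<INV")) and \
            (rec.info.get("INV3") or rec.info.get("INV5")):
        which = "3" if rec.info.get("INV3") else "5"
        info = dict(rec.info, INV_SINGLE=which)
        return [SvRecord(rec.contig, rec.pos, rec.vcf_id, rec.ref, "<INV>", info,
                         rec.qual, rec.filter, rec.line)]
    return [rec]


# --------------------------------------------------------------------------- #
# whole-file conversion

def read_sv_records(path) -> tuple[list[SvRecord], list[str]]:
    """Read a VCF into :class:`SvRecord` objects plus the header contig order."""
    vf = pysam.VariantFile(str(path))
    contig_order = list(vf.header.contigs)
    records = []
    n = 0
    for rec in vf:
        n += 1
        filt = ";".join(rec.filter.keys()) or None
        info = {}
        for k in rec.info.keys():
            info[k] = rec.info[k]
        if rec.stop is not None and rec.stop > rec.pos and "END" not in info:
            alt0 = (rec.alts or [""])[0] or ""
            if alt0.startswith("<") or "SVTYPE" in info:
                info["END"] = rec.stop
        for alt in rec.alts or []:
            records.append(SvRecord(
                contig=rec.chrom, pos=rec.pos,
                vcf_id=rec.id or f"line{n}",
                ref=(rec.ref or "N").upper(), alt=str(alt),
                info=dict(info), qual=rec.qual, filter=filt, line=n,
            ))
    vf.close()
    return records, contig_order


def _sort_rank(contig_order):
    rank = {c: i for i, c in enumerate(contig_order)}
    def key(contig, nominal, orient, bid):
        r = rank.get(contig)
        ck = (0, r, "") if r is not None else (1, 0, contig)
        return (ck, nominal, 0 if orient == "+" else 1, bid)
    return key


def _ingest(source, config: IngestConfig, singles_only: bool) -> BreakpointSet:
    if isinstance(source, (str, Path)):
        raw, contig_order = read_sv_records(source)
    else:
        raw = list(source)
        contig_order = []
        for r in raw:
            if r.contig not in contig_order:
                contig_order.append(r.contig)
    recs: list[SvRecord] = []
    for r in raw:
        recs.extend(normalize_dialect(r))
    key = _sort_rank(contig_order)

    breakends: list[Breakend] = []
    bnd: dict[str, tuple[SvRecord, BndAltParts]] = {}
    summary = {"records": len(raw), "converted": 0, "skipped": 0, "singles": 0}

    for rec in recs:
        if rec.alt.startswith("<"):
            if singles_only:
                continue
            try:
                bes = symbolic_to_breakends(rec)
            except (MissingEnd, NegativeSpan, MalformedAlt) as exc:
                log.warning("skipping record %s: %s", rec.vcf_id, exc)
                summary["skipped"] += 1
                continue
            breakends.extend(apply_uncertainty(b, rec, side="auto") for b in bes)
            summary["converted"] += 1
            continue
        try:
            parts = parse_bnd_alt(rec.alt, rec.ref)
        except MalformedAlt:
            if singles_only:
                continue
            try:
                bes = direct_alt_to_breakends(rec, config)
            except MalformedAlt as exc:
                log.warning("skipping record %s: %s", rec.vcf_id, exc)
                summary["skipped"] += 1
                continue
            if not bes:
                summary["skipped"] += 1
                continue
            breakends.extend(apply_uncertainty(b, rec, side="auto") for b in bes)
            summary["converted"] += 1
            continue
        if parts.is_single:
            summary["singles"] += 1
            if singles_only:
                be = Breakend(
                    id=rec.vcf_id, contig=rec.contig, lo=rec.pos, hi=rec.pos,
                    nominal=rec.pos, orientation=parts.local_orientation,
                    insert_seq=parts.insert_seq, qual=rec.qual, filter=rec.filter,
                    event_id=rec.info.get("EVENT", rec.vcf_id),
                )
                breakends.append(apply_uncertainty(be, rec, side="pos"))
            continue
        if not singles_only:
            bnd[rec.vcf_id] = (rec, parts)

    # pair BND records via MATEID
    done = set()
    for vid, (rec, parts) in bnd.items():
        if vid in done:
            continue
        mateid = _scalar(rec.info.get("MATEID"))
        mate = bnd.get(mateid) if mateid else None
        if mate is None or mateid == vid:
            done.add(vid)
            summary["skipped" if config.unmated_policy == "drop" else "converted"] += 1
            if config.unmated_policy == "drop":
                log.warning("BND record %s has no mate line; dropped", vid)
                continue
            log.warning("BND record %s has no mate line; downgraded to single breakend", vid)
            be = Breakend(
                id=vid, contig=rec.contig, lo=rec.pos, hi=rec.pos, nominal=rec.pos,
                orientation=parts.local_orientation, insert_seq=parts.insert_seq,
                qual=rec.qual, filter=rec.filter,
                event_id=rec.info.get("EVENT", vid),
            )
            breakends.append(apply_uncertainty(be, rec, side="pos"))
            continue
        mrec, mparts = mate
        done.add(vid)
        done.add(mateid)
        # canonical-first mate's ALT insert is the pair's stored insert
        k1 = key(rec.contig, rec.pos, parts.local_orientation, vid)
        k2 = key(mrec.contig, mrec.pos, mparts.local_orientation, mateid)
        insert = parts.insert_seq if k1 < k2 else mparts.insert_seq
        for r, p_, other in ((rec, parts, mateid), (mrec, mparts, vid)):
            be = Breakend(
                id=r.vcf_id, contig=r.contig, lo=r.pos, hi=r.pos, nominal=r.pos,
                orientation=p_.local_orientation, partner_id=other,
                insert_seq=insert, qual=r.qual, filter=r.filter,
                event_id=r.info.get("EVENT", r.vcf_id),
            )
            breakends.append(apply_uncertainty(be, r, side="pos"))
        summary["converted"] += 1

    bset = BreakpointSet(breakends, contig_order=contig_order)
    bset.summary = summary
    return bset


def breakpoint_ranges(source, config: IngestConfig | None = None) -> BreakpointSet:
    """Convert a VCF (path or iterable of :class:`SvRecord`) into breakpoints.

    Composition of :func:`normalize_dialect`, the per-notation converters and
    :func:`apply_uncertainty`; BND mates are paired via MATEID.  Records in
    single-breakend ALT notation are left to :func:`breakend_ranges`, but
    unmated BND records are downgraded to single breakends (or dropped,
    per :class:`IngestConfig`).
    """
    return _ingest(source, config or IngestConfig(), singles_only=False)


def breakend_ranges(source, config: IngestConfig | None = None) -> BreakpointSet:
    """Extract only single-breakend records (ALT ``.s`` / ``s.``) from a VCF."""
    return _ingest(source, config or IngestConfig(), singles_only=True)


# --------------------------------------------------------------------------- #
# export

_INFO_LINES = [
    ('SVTYPE', '1', 'String', 'Type of structural variant'),
    ('MATEID', '1', 'String', 'ID of mate breakend'),
    ('CIPOS', '2', 'Integer', 'Confidence interval around POS'),
    ('CIEND', '2', 'Integer', 'Confidence interval around END'),
    ('END', '1', 'Integer', 'End position of the variant'),
    ('SVLEN', '1', 'Integer', 'Length of the variant'),
    ('HOMLEN', '1', 'Integer', 'Length of breakpoint microhomology'),
    ('HOMSEQ', '1', 'String', 'Sequence of breakpoint microhomology'),
    ('IMPRECISE', '0', 'Flag', 'Imprecise structural variant'),
    ('EVENT', '1', 'String', 'ID of the associated event'),
    ('SVINSSEQ', '1', 'String', 'Inserted sequence of a symbolic insertion'),
    ('CHR2', '1', 'String', 'Mate chromosome (caller dialect)'),
    ('CT', '1', 'String', 'Connection type (caller dialect)'),
    ('STRANDS', '1', 'String', 'Breakend strands (caller dialect)'),
    ('INV3', '0', 'Flag', 'Only the 3-prime to 3-prime inversion breakpoint'),
    ('INV5', '0', 'Flag', 'Only the 5-prime to 5-prime inversion breakpoint'),
]


def build_vcf_header(contigs, filters=()) -> pysam.VariantHeader:
    """VCF header declaring every INFO key this package reads or writes.

    ``contigs`` is a mapping name -> length (length may be None) or an
    iterable of names.
    """
    header = pysam.VariantHeader()
    if isinstance(contigs, dict):
        items = contigs.items()
    else:
        items = ((c, None) for c in contigs)
    for name, length in items:
        if length:
            header.contigs.add(name, length=length)
        else:
            header.contigs.add(name)
    for ident, number, typ, desc in _INFO_LINES:
        header.info.add(ident, number, typ, desc)
    for f in filters:
        if f not in ("PASS", "."):
            header.filters.add(f, None, None, "passthrough filter")
    return header


def write_bnd_vcf(bset: BreakpointSet, path, contig_lengths: dict | None = None) -> int:
    """Write a breakpoint set as spec-compliant BND / single-breakend records.

    Every partnered pair becomes two reciprocal BND records (MATEID, CIPOS
    from the location interval, HOMLEN, IMPRECISE, inserted sequence in the
    bracketed ALT); single breakends use the ``.s``/``s.`` notation.  Records
    are sorted by contig order then position, and re-ingesting the output
    reproduces the set on all model fields.  Returns the record count.
    """
    contigs = list(bset.contig_order)
    for be in bset:
        if be.contig not in contigs:
            contigs.append(be.contig)
    if contig_lengths:
        cmap = {c: contig_lengths.get(c) for c in contigs}
    else:
        cmap = {c: None for c in contigs}
    filters = sorted({be.filter for be in bset if be.filter} - {"PASS"})
    split_filters = sorted({f for joint in filters for f in joint.split(";")})
    header = build_vcf_header(cmap, filters=split_filters)

    rows = []
    for a, b in bset.breakpoint_pairs():
        ins_a = a.insert_seq
        # mate reads the insert from its own side: reversed junctions flip it
        ins_b = ins_a if a.orientation != b.orientation else revcomp(ins_a)
        for this, other, ins in ((a, b, ins_a), (b, a, ins_b)):
            parts = BndAltParts(other.contig, other.nominal,
                                this.orientation, other.orientation, ins)
            rows.append((this, other, render_bnd_alt(parts, "N")))
    for s in bset.singles():
        parts = BndAltParts(None, None, s.orientation, None, s.insert_seq,
                            is_single=True)
        rows.append((s, None, render_bnd_alt(parts, "N")))

    key = _sort_rank(contigs)
    rows.sort(key=lambda r: key(r[0].contig, r[0].nominal, r[0].orientation, r[0].id))

    out = pysam.VariantFile(str(path), "w", header=header)
    for this, other, alt in rows:
        rec = out.new_record(contig=this.contig, start=this.nominal - 1,
                             alleles=("N", alt), id=this.id)
        rec.info["SVTYPE"] = "BND"
        if other is not None:
            rec.info["MATEID"] = other.id
        if (this.lo, this.hi) != (this.nominal, this.nominal):
            rec.info["CIPOS"] = (this.lo - this.nominal, this.hi - this.nominal)
        if this.homology_len:
            rec.info["HOMLEN"] = this.homology_len
        if not this.precise:
            rec.info["IMPRECISE"] = True
        if this.event_id:
            rec.info["EVENT"] = this.event_id
        if this.qual is not None:
            rec.qual = this.qual
        if this.filter:
            for f in this.filter.split(";"):
                rec.filter.add(f)
        out.write(rec)
    out.close()
    return len(rows)
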
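"""Ground-truth rearrangement simulator.

Generates sets of planted structural variants on synthetic contigs and
renders them in each supported notation (symbolic VCF, BND VCF, direct
REF/ALT sequence, BEDPE, and the deliberately discordant ``dup-as-ins`` /
``ins-as-dup`` renderings), so that every conversion, matching and
reconciliation routine can be exercised against a known answer without any
external data.  No reference FASTA is produced: inserted and deleted
sequences are random ACGT strings from the seeded generator, which suffices
because no routine in this package inspects reference bases.

All randomness flows from the ``seed`` argument through one
``numpy.random.Generator``; identical parameters give identical truth sets
and byte-identical rendered files.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pysam

from .bedpe import write_bedpe
from .errors import ContigTooSmall, UnsupportedCombination
from .model import Breakend, BreakpointSet
from .vcf_io import BndAltParts, build_vcf_header, render_bnd_alt, write_bnd_vcf
from .model import revcomp

__all__ = ["Event", "RearrangementTruth", "simulate_truth", "render",
           "plant_transitive", "perturb_breakpoint_set",
           "DEFAULT_CONTIGS", "DEFAULT_MIX"]

DEFAULT_CONTIGS = {"ctg1": 10_000_000, "ctg2": 10_000_000, "ctg3": 10_000_000}
DEFAULT_MIX = {"DEL": 0.22, "DUP": 0.18, "INS": 0.18, "INV": 0.16,
               "TRA": 0.14, "SINGLE": 0.12}

# breakends produced per event kind
DECOMPOSITION_SIZE = {"DEL": 2, "DUP": 2, "INS": 2, "INV": 4, "TRA": 2,
                      "SINGLE": 1, "JUNCTION": 2, "TRANSITIVE": 2}

_BASES = np.array(list("ACGT"))


@dataclass
class Event:
    """One planted rearrangement (VCF-style coordinates, 1-based)."""

    id: str
    kind: str                      # DEL DUP INS INV TRA SINGLE JUNCTION TRANSITIVE
    contig: str
    pos: int
    end: Optional[int] = None      # DEL/DUP/INV span end
    contig2: Optional[str] = None  # TRA/JUNCTION/TRANSITIVE far side
    pos2: Optional[int] = None
    orient1: str = "+"
    orient2: str = "-"
    insert_seq: str = ""
    ci_pos: Optional[tuple] = None
    ci_end: Optional[tuple] = None
    homlen: int = 0
    precise: bool = True
    qual: Optional[float] = None
    filter: Optional[str] = "PASS"


@dataclass
class ChainTruth:
    """Label for one planted transitive candidate."""

    candidate_event: str
    constituent_events: list
    negative: bool
    reason: str = ""  # '', 'insert-off', 'gap-too-big'


@dataclass
class RearrangementTruth:
    """Simulator output: planted events plus their breakpoint-set form."""

    seed: int
    contigs: dict
    events: list = dc_field(default_factory=list)
    chains: list = dc_field(default_factory=list)
    occupied: dict = dc_field(default_factory=dict)
    _bset: Optional[BreakpointSet] = None

    def breakpoint_set(self) -> BreakpointSet:
        if self._bset is None:
            bes = []
            for ev in self.events:
                bes.extend(event_breakends(ev))
            self._bset = BreakpointSet(bes, contig_order=list(self.contigs))
        return self._bset

    def pair_id_of_event(self, event_id: str) -> str:
        bset = self.breakpoint_set()
        return bset.pair_id(bset.get(f"{event_id}_bp1_1"))


def _interval(pos: int, ci) -> tuple[int, int]:
    if ci is None:
        return pos, pos
    return max(1, pos + ci[0]), pos + ci[1]


def event_breakends(ev: Event) -> list[Breakend]:
    """Decompose a planted event into model breakends (the ground truth)."""

    def be(k, i, contig, pos, orient, partner, insert="", ci=None):
        lo, hi = _interval(pos, ci)
        homlen = ev.homlen
        if ev.precise:
            homlen = max(homlen, hi - lo)
        return Breakend(
            id=f"{ev.id}_bp{k}_{i}", contig=contig, lo=lo, hi=hi, nominal=pos,
            orientation=orient, partner_id=partner, insert_seq=insert,
            homology_len=homlen, precise=ev.precise, qual=ev.qual,
            filter=ev.filter, event_id=ev.id)

    rid = ev.id
    p, e = ev.pos, ev.end
    if ev.kind == "DEL":
        return [be(1, 1, ev.contig, p, "+", f"{rid}_bp1_2", ev.insert_seq, ev.ci_pos),
                be(1, 2, ev.contig, e + 1, "-", f"{rid}_bp1_1", ev.insert_seq, ev.ci_end)]
    if ev.kind == "DUP":
        return [be(1, 1, ev.contig, p + 1, "-", f"{rid}_bp1_2", "", ev.ci_pos),
                be(1, 2, ev.contig, e, "+", f"{rid}_bp1_1", "", ev.ci_end)]
    if ev.kind == "INS":
        return [be(1, 1, ev.contig, p, "+", f"{rid}_bp1_2", ev.insert_seq, ev.ci_pos),
                be(1, 2, ev.contig, p + 1, "-", f"{rid}_bp1_1", ev.insert_seq, ev.ci_pos)]
    if ev.kind == "INV":
        return [be(1, 1, ev.contig, p, "+", f"{rid}_bp1_2", "", ev.ci_pos),
                be(1, 2, ev.contig, e, "+", f"{rid}_bp1_1", "", ev.ci_end),
                be(2, 1, ev.contig, p + 1, "-", f"{rid}_bp2_2", "", ev.ci_pos),
                be(2, 2, ev.contig, e + 1, "-", f"{rid}_bp2_1", "", ev.ci_end)]
    if ev.kind in ("TRA", "JUNCTION", "TRANSITIVE"):
        return [be(1, 1, ev.contig, p, ev.orient1, f"{rid}_bp1_2", ev.insert_seq, ev.ci_pos),
                be(1, 2, ev.contig2, ev.pos2, ev.orient2, f"{rid}_bp1_1", ev.insert_seq, ev.ci_end)]
    if ev.kind == "SINGLE":
        return [be(1, 1, ev.contig, p, ev.orient1, None, ev.insert_seq, ev.ci_pos)]
    raise ValueError(f"unknown event kind {ev.kind!r}")


# --------------------------------------------------------------------------- #
# placement

def _random_seq(rng: np.random.Generator, length: int) -> str:
    if length <= 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _reserve(truth: RearrangementTruth, rng: np.random.Generator, span: int,
             margin: int = 2000, tries: int = 2000,
             forbidden=None) -> tuple[str, int]:
    """Pick (contig, start) so [start, start+span] plus margin is unoccupied."""
    names = list(truth.contigs)
    lengths = np.array([truth.contigs[c] for c in names], dtype=float)
    weights = lengths / lengths.sum()
    for _ in range(tries):
        contig = names[rng.choice(len(names), p=weights)]
        limit = truth.contigs[contig] - span - margin
        if limit <= margin + 1:
            continue
        start = int(rng.integers(margin + 1, limit))
        lo, hi = start - margin, start + span + margin
        blocks = truth.occupied.setdefault(contig, [])
        if any(not (hi < b_lo or lo > b_hi) for b_lo, b_hi in blocks):
            continue
        if forbidden and any(c == contig and not (hi < f_lo or lo > f_hi)
                             for c, f_lo, f_hi in forbidden):
            continue
        blocks.append((lo, hi))
        return contig, start
    raise ContigTooSmall(
        f"could not place an event of span {span} after {tries} attempts")


def _precision(rng: np.random.Generator, mix=(0.70, 0.15, 0.15)):
    """Draw (precise, ci_pos, ci_end, homlen) for one event."""
    r = rng.random()
    if r < mix[0]:
        return True, None, None, 0
    if r < mix[0] + mix[1]:  # imprecise caller CI
        u1, v1 = int(rng.integers(3, 50)), int(rng.integers(3, 50))
        u2, v2 = int(rng.integers(3, 50)), int(rng.integers(3, 50))
        return False, (-u1, v1), (-u2, v2), 0
    h = int(rng.integers(1, 21))  # precise with microhomology
    return True, (0, h), (0, h), h


def simulate_truth(n_events: int, event_mix: dict | None = None,
                   contigs: dict | None = None, seed: int = 0,
                   size_range: tuple[int, int] = (50, 10_000),
                   precision_mix=(0.70, 0.15, 0.15),
                   forbidden=None,
                   id_prefix: str = "ev") -> RearrangementTruth:
    """Plant ``n_events`` non-overlapping rearrangements.

    ``event_mix`` maps kind -> proportion (default :data:`DEFAULT_MIX`);
    DEL/DUP/INV spans and INS insert lengths are drawn uniformly from
    ``size_range``.  ``forbidden`` is an optional list of ``(contig, lo,
    hi)`` exclusion zones (used e.g. to place decoy events away from real
    boundaries).  Deterministic given ``seed``.
    """
    contigs = dict(contigs or DEFAULT_CONTIGS)
    mix = dict(event_mix or DEFAULT_MIX)
    kinds = sorted(mix)
    probs = np.array([mix[k] for k in kinds], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    truth = RearrangementTruth(seed=seed, contigs=contigs)
    lo_sz, hi_sz = size_range
    for i in range(n_events):
        kind = kinds[rng.choice(len(kinds), p=probs)]
        precise, ci_pos, ci_end, homlen = _precision(rng, precision_mix)
        qual = float(int(rng.integers(10, 1000)))
        eid = f"{id_prefix}{i:04d}"
        if kind in ("DEL", "DUP", "INV"):
            span = int(rng.integers(lo_sz, hi_sz + 1))
            contig, start = _reserve(truth, rng, span, forbidden=forbidden)
            ev = Event(eid, kind, contig, start, end=start + span,
                       ci_pos=ci_pos, ci_end=ci_end, homlen=homlen,
                       precise=precise, qual=qual)
        elif kind == "INS":
            ell = int(rng.integers(lo_sz, hi_sz + 1))
            contig, start = _reserve(truth, rng, 1, forbidden=forbidden)
            ev = Event(eid, kind, contig, start,
                       insert_seq=_random_seq(rng, ell),
                       ci_pos=ci_pos, ci_end=ci_end, homlen=homlen,
                       precise=precise, qual=qual)
        elif kind == "TRA":
            c1, p1 = _reserve(truth, rng, 1, forbidden=forbidden)
            c2, p2 = _reserve(truth, rng, 1, forbidden=forbidden)
            o1, o2 = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")][rng.integers(0, 4)]
            ev = Event(eid, kind, c1, p1, contig2=c2, pos2=p2,
                       orient1=o1, orient2=o2,
                       ci_pos=ci_pos, ci_end=ci_end, homlen=homlen,
                       precise=precise, qual=qual)
        else:  # SINGLE
            contig, start = _reserve(truth, rng, 1, forbidden=forbidden)
            ev = Event(eid, kind, contig, start,
                       orient1="+" if rng.random() < 0.5 else "-",
                       insert_seq=_random_seq(rng, int(rng.integers(20, 200))),
                       ci_pos=ci_pos, homlen=homlen, precise=precise, qual=qual)
        truth.events.append(ev)
    return truth


def plant_transitive(truth: RearrangementTruth, n_chains: int, chain_len: int,
                     gap_range: tuple[int, int] = (10, 300), seed: int = 1,
                     junction_insert_range: tuple[int, int] = (0, 10),
                     negative: str | None = None) -> RearrangementTruth:
    """Add ``n_chains`` junction chains plus one transitive candidate each.

    Each chain is ``chain_len`` junctions hopping across contigs; segment
    gaps between consecutive junctions are drawn from ``gap_range``.  The
    candidate joins the chain's outermost breakends and carries inserted
    sequence whose length equals the total intervening derivative sequence
    (segment gaps plus the junctions' own inserts), so it is exactly
    transitive.  ``negative`` plants controls instead: ``"insert-off"``
    offsets the candidate insert length by 500 bp, ``"gap-too-big"`` draws
    one segment gap in [1200, 2000].  Labels accumulate in
    ``truth.chains``; the truth breakpoint set is rebuilt lazily.
    """
    rng = np.random.default_rng(seed)
    truth._bset = None
    base = sum(1 for c in truth.chains) + len(
        [e for e in truth.events if e.kind in ("JUNCTION", "TRANSITIVE")])
    for c in range(n_chains):
        tag = f"c{base + c:03d}"
        anchors = [_reserve(truth, rng, 2500, margin=5000)
                   for _ in range(chain_len + 1)]
        gaps = [int(rng.integers(gap_range[0], gap_range[1] + 1))
                for _ in range(chain_len - 1)]
        bad_gap = None
        if negative == "gap-too-big":
            bad_gap = int(rng.integers(0, len(gaps))) if gaps else None
            if bad_gap is not None:
                gaps[bad_gap] = int(rng.integers(1200, 2001))
        junctions = []
        x = [anchors[0][1]]
        for i in range(1, chain_len):
            x.append(anchors[i][1] + gaps[i - 1])
        total_ins = 0
        for i in range(chain_len):
            jlen = int(rng.integers(junction_insert_range[0],
                                    junction_insert_range[1] + 1))
            total_ins += jlen
            jev = Event(f"tj{tag}_{i}", "JUNCTION",
                        anchors[i][0], x[i], contig2=anchors[i + 1][0],
                        pos2=anchors[i + 1][1], orient1="+", orient2="-",
                        insert_seq=_random_seq(rng, jlen), qual=60.0)
            junctions.append(jev)
            truth.events.append(jev)
        m = sum(gaps) + total_ins
        if negative == "insert-off":
            m += 500
        cev = Event(f"tv{tag}", "TRANSITIVE",
                    anchors[0][0], anchors[0][1],
                    contig2=anchors[-1][0], pos2=anchors[-1][1],
                    orient1="+", orient2="-",
                    insert_seq=_random_seq(rng, m), qual=60.0)
        truth.events.append(cev)
        truth.chains.append(ChainTruth(
            candidate_event=cev.id,
            constituent_events=[j.id for j in junctions],
            negative=negative is not None,
            reason=negative or ""))
    return truth


# --------------------------------------------------------------------------- #
# rendering

def _symbolic_capable(kind: str) -> bool:
    return kind in ("DEL", "DUP", "INS", "INV")


def render(truth: RearrangementTruth, notation: str, path) -> str:
    """Write the truth set to ``path`` in the requested notation.

    ``symbolic`` uses <DEL>/<DUP>/<INS>/<INV> alleles where possible
    (interchromosomal junctions and single breakends must use BND/breakend
    records in any notation); ``bnd`` writes everything as breakend records;
    ``direct`` writes REF/ALT sequences (deletions and insertions only);
    ``bedpe`` writes extended BEDPE; ``dup-as-ins`` and ``ins-as-dup``
    mimic the discordant notations of long-/short-read callers.
    """
    path = str(path)
    if notation == "bnd":
        write_bnd_vcf(truth.breakpoint_set(), path, contig_lengths=truth.contigs)
        return path
    if notation == "bedpe":
        write_bedpe(truth.breakpoint_set(), path, extended=True)
        return path
    if notation in ("symbolic", "dup-as-ins", "ins-as-dup"):
        _render_vcf(truth, notation, path)
        return path
    if notation == "direct":
        _render_direct(truth, path)
        return path
    raise UnsupportedCombination(f"unknown notation {notation!r}")


def _mk_symbolic(out, ev: Event, kind: str, pos: int, end: int | None,
                 svlen: int | None, insseq: str | None):
    # stop passed at creation: htslib needs END to size a symbolic allele
    rec = out.new_record(contig=ev.contig, start=pos - 1,
                         stop=end if end is not None else pos,
                         alleles=("N", f"<{kind}>"), id=ev.id)
    rec.info["SVTYPE"] = kind
    if svlen is not None:
        rec.info["SVLEN"] = svlen
    if insseq:
        rec.info["SVINSSEQ"] = insseq
    if ev.ci_pos:
        rec.info["CIPOS"] = ev.ci_pos
    if ev.ci_end and end is not None:
        rec.info["CIEND"] = ev.ci_end
    if ev.homlen:
        rec.info["HOMLEN"] = ev.homlen
    if not ev.precise:
        rec.info["IMPRECISE"] = True
    if ev.qual is not None:
        rec.qual = ev.qual
    if ev.filter:
        rec.filter.add(ev.filter)
    return rec


def _bnd_event_records(out, ev: Event):
    """Render one non-symbolic event as BND / single-breakend records."""
    bes = event_breakends(ev)
    recs = []
    if len(bes) == 1:
        s = bes[0]
        parts = BndAltParts(None, None, s.orientation, None, s.insert_seq,
                            is_single=True)
        rec = out.new_record(contig=s.contig, start=s.nominal - 1,
                             alleles=("N", render_bnd_alt(parts, "N")), id=s.id)
        rec.info["SVTYPE"] = "BND"
        _attach(rec, s)
        return [rec]
    a, b = bes
    ins_a = a.insert_seq
    ins_b = ins_a if a.orientation != b.orientation else revcomp(ins_a)
    for this, other, ins in ((a, b, ins_a), (b, a, ins_b)):
        parts = BndAltParts(other.contig, other.nominal, this.orientation,
                            other.orientation, ins)
        rec = out.new_record(contig=this.contig, start=this.nominal - 1,
                             alleles=("N", render_bnd_alt(parts, "N")),
                             id=this.id)
        rec.info["SVTYPE"] = "BND"
        rec.info["MATEID"] = other.id
        _attach(rec, this)
        recs.append(rec)
    return recs


def _attach(rec, be: Breakend):
    if (be.lo, be.hi) != (be.nominal, be.nominal):
        rec.info["CIPOS"] = (be.lo - be.nominal, be.hi - be.nominal)
    if be.homology_len:
        rec.info["HOMLEN"] = be.homology_len
    if not be.precise:
        rec.info["IMPRECISE"] = True
    if be.event_id:
        rec.info["EVENT"] = be.event_id
    if be.qual is not None:
        rec.qual = be.qual
    if be.filter:
        rec.filter.add(be.filter)


def _render_vcf(truth: RearrangementTruth, notation: str, path: str):
    header = build_vcf_header(truth.contigs, filters=("PASS",))
    out = pysam.VariantFile(path, "w", header=header)
    rng = np.random.default_rng((truth.seed, sum(ord(ch) for ch in notation)))
    recs = []
    for ev in truth.events:
        kind = ev.kind
        if notation == "dup-as-ins" and kind == "DUP":
            # tandem duplication of [pos+1, end] == insertion at the left
            # boundary of the duplicated sequence (length end - pos)
            length = ev.end - ev.pos
            ev2 = Event(ev.id, "INS", ev.contig, ev.pos, ci_pos=ev.ci_pos,
                        homlen=ev.homlen, precise=ev.precise, qual=ev.qual)
            recs.append(_mk_symbolic(out, ev2, "INS", ev.pos, None, length,
                                     _random_seq(rng, length)))
            continue
        if notation == "ins-as-dup" and kind == "INS":
            ell = len(ev.insert_seq)
            if ev.pos - ell >= 1:
                recs.append(_mk_symbolic(out, ev, "DUP", ev.pos - ell,
                                         ev.pos, ell, None))
                continue
        if _symbolic_capable(kind):
            p, e = ev.pos, ev.end
            if kind == "DEL":
                recs.append(_mk_symbolic(out, ev, "DEL", p, e, -(e - p), None))
            elif kind == "DUP":
                recs.append(_mk_symbolic(out, ev, "DUP", p, e, e - p, None))
            elif kind == "INV":
                recs.append(_mk_symbolic(out, ev, "INV", p, e, e - p, None))
            else:  # INS
                recs.append(_mk_symbolic(out, ev, "INS", p, None,
                                         len(ev.insert_seq), ev.insert_seq))
        else:
            recs.extend(_bnd_event_records(out, ev))
    order = {c: i for i, c in enumerate(truth.contigs)}
    recs.sort(key=lambda r: (order.get(r.chrom, len(order)), r.pos, r.id or ""))
    for rec in recs:
        out.write(rec)
    out.close()


def _render_direct(truth: RearrangementTruth, path: str):
    bad = [e.kind for e in truth.events if e.kind not in ("DEL", "INS")]
    if bad:
        raise UnsupportedCombination(
            f"direct sequence notation cannot express event kinds {sorted(set(bad))}")
    header = build_vcf_header(truth.contigs, filters=("PASS",))
    out = pysam.VariantFile(path, "w", header=header)
    rng = np.random.default_rng((truth.seed, 7))
    recs = []
    for ev in truth.events:
        if ev.kind == "DEL":
            ref = "N" + _random_seq(rng, ev.end - ev.pos)
            rec = out.new_record(contig=ev.contig, start=ev.pos - 1,
                                 alleles=(ref, "N"), id=ev.id)
            # rlen of the explicit REF already places stop at ev.end
            rec.info["SVTYPE"] = "DEL"
        else:
            rec = out.new_record(contig=ev.contig, start=ev.pos - 1,
                                 alleles=("N", "N" + ev.insert_seq), id=ev.id)
            rec.info["SVTYPE"] = "INS"
        if ev.ci_pos:
            rec.info["CIPOS"] = ev.ci_pos
        if ev.ci_end and ev.kind == "DEL":
            rec.info["CIEND"] = ev.ci_end
        if ev.homlen:
            rec.info["HOMLEN"] = ev.homlen
        if not ev.precise:
            rec.info["IMPRECISE"] = True
        if ev.qual is not None:
            rec.qual = ev.qual
        if ev.filter:
            rec.filter.add(ev.filter)
        recs.append(rec)
    order = {c: i for i, c in enumerate(truth.contigs)}
    recs.sort(key=lambda r: (order.get(r.chrom, len(order)), r.pos, r.id or ""))
    for rec in recs:
        out.write(rec)
    out.close()


def perturb_breakpoint_set(bset: BreakpointSet, max_shift: int,
                           seed: int = 0) -> BreakpointSet:
    """Shift every breakend's position by a uniform offset in
    [-max_shift, max_shift] (mates shifted independently); used to build
    jittered call sets for matching experiments."""
    from .model import clone_breakend
    rng = np.random.default_rng(seed)
    out = []
    for be in bset:
        d = int(rng.integers(-max_shift, max_shift + 1))
        if be.lo + d < 1:
            d = 1 - be.lo
        out.append(clone_breakend(be, lo=be.lo + d, hi=be.hi + d,
                                  nominal=be.nominal + d))
    return BreakpointSet(out, contig_order=bset.contig_order)
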
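"""Shared fixtures and helpers for the svbreaks test suite."""

import textwrap

import pytest
from hypothesis import settings

from svbreaks import Breakend, BreakpointSet

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def bnd(bid, contig, pos, orientation, partner=None, insert="", lo=None,
        hi=None, homlen=0, precise=True, **kw):
    """Terse breakend factory for hand-built sets."""
    return Breakend(
        id=bid, contig=contig, lo=lo if lo is not None else pos,
        hi=hi if hi is not None else pos, nominal=pos,
        orientation=orientation, partner_id=partner, insert_seq=insert,
        homology_len=homlen, precise=precise, **kw)


def make_pair(id1, contig1, pos1, o1, contig2, pos2, o2, insert="", **kw):
    """Two reciprocal breakends named <id1>_1/<id1>_2."""
    a = bnd(f"{id1}_1", contig1, pos1, o1, partner=f"{id1}_2", insert=insert, **kw)
    b = bnd(f"{id1}_2", contig2, pos2, o2, partner=f"{id1}_1", insert=insert, **kw)
    return [a, b]


def pair_multiset(bset: BreakpointSet, with_insert_seq=False):
    """Canonical multiset of pair signatures for set comparisons."""
    out = []
    for a, b in bset.breakpoint_pairs():
        sig = lambda be: (be.contig, be.lo, be.hi, be.nominal, be.orientation,
                          be.homology_len, be.precise)
        ins = a.insert_seq if with_insert_seq else len(a.insert_seq)
        out.append((sig(a), sig(b), ins))
    for s in bset.singles():
        out.append((("single", s.contig, s.lo, s.hi, s.nominal, s.orientation),
                    None, len(s.insert_seq)))
    return sorted(out, key=repr)


def model_fields(bset: BreakpointSet):
    """Full per-breakend field tuples (id-sorted) for identity checks."""
    return sorted(
        (be.id, be.contig, be.lo, be.hi, be.nominal, be.orientation,
         be.partner_id, be.insert_seq, be.homology_len, be.precise,
         be.qual, be.filter, be.event_id)
        for be in bset)


VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=100000000>
    ##contig=<ID=chr2,length=100000000>
    ##contig=<ID=chr3,length=100000000>
    ##contig=<ID=chr5,length=100000000>
    ##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
    ##INFO=<ID=END,Number=1,Type=Integer,Description="x">
    ##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="x">
    ##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="x">
    ##INFO=<ID=CIEND,Number=2,Type=Integer,Description="x">
    ##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="x">
    ##INFO=<ID=HOMSEQ,Number=1,Type=String,Description="x">
    ##INFO=<ID=MATEID,Number=1,Type=String,Description="x">
    ##INFO=<ID=EVENT,Number=1,Type=String,Description="x">
    ##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="x">
    ##INFO=<ID=CHR2,Number=1,Type=String,Description="x">
    ##INFO=<ID=CT,Number=1,Type=String,Description="x">
    ##INFO=<ID=STRANDS,Number=1,Type=String,Description="x">
    ##INFO=<ID=INV3,Number=0,Type=Flag,Description="x">
    ##INFO=<ID=INV5,Number=0,Type=Flag,Description="x">
    ##INFO=<ID=SVINSSEQ,Number=1,Type=String,Description="x">
    ##INFO=<ID=NTLEN,Number=1,Type=Integer,Description="x">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
    """)


@pytest.fixture
def vcf_file(tmp_path):
    """Write body lines under a permissive SV header; returns the path."""

    def _write(body, name="test.vcf"):
        path = tmp_path / name
        text = body if body.endswith("\n") or not body else body + "\n"
        path.write_text(VCF_HEADER + text)
        return str(path)

    return _write
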
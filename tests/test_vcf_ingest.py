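"""VCF notation conversion: symbolic/direct/BND ingest, dialects, round trips."""

import pytest

from svbreaks import (
    IngestConfig,
    SvRecord,
    apply_uncertainty,
    breakend_ranges,
    breakpoint_ranges,
    direct_alt_to_breakends,
    normalize_dialect,
    symbolic_to_breakends,
    write_bnd_vcf,
)
from svbreaks.errors import MissingEnd, NegativeSpan

from conftest import model_fields


def rec(contig="chr1", pos=100, vcf_id="v1", ref="N", alt="<DEL>", info=None, **kw):
    return SvRecord(contig=contig, pos=pos, vcf_id=vcf_id, ref=ref, alt=alt,
                    info=info or {}, **kw)


def sig(breakends):
    return [(b.contig, b.nominal, b.orientation) for b in breakends]


class TestSymbolic:
    def test_del_joins_flanks(self):
        bes = symbolic_to_breakends(rec(alt="<DEL>", pos=100, info={"END": 200}))
        assert sig(bes) == [("chr1", 100, "+"), ("chr1", 201, "-")]
        assert bes[0].partner_id == bes[1].id

    def test_dup_joins_end_back_to_start(self):
        bes = symbolic_to_breakends(rec(alt="<DUP>", pos=100, info={"END": 200}))
        assert sig(bes) == [("chr1", 101, "-"), ("chr1", 200, "+")]

    def test_dup_tandem_subtype_same_as_dup(self):
        bes = symbolic_to_breakends(rec(alt="<DUP:TANDEM>", pos=100, info={"END": 200}))
        assert sig(bes) == [("chr1", 101, "-"), ("chr1", 200, "+")]

    def test_inversion_decomposes_into_two_breakpoints(self):
        bes = symbolic_to_breakends(rec(alt="<INV>", pos=100, info={"END": 200}))
        assert sig(bes) == [("chr1", 100, "+"), ("chr1", 200, "+"),
                            ("chr1", 101, "-"), ("chr1", 201, "-")]

    def test_insertion_carries_sequence_or_padding(self):
        bes = symbolic_to_breakends(rec(alt="<INS>", pos=500,
                                        info={"SVLEN": 4, "SVINSSEQ": "ACGT"}))
        assert sig(bes) == [("chr1", 500, "+"), ("chr1", 501, "-")]
        assert bes[0].insert_seq == "ACGT"
        padded = symbolic_to_breakends(rec(alt="<INS>", pos=500, info={"SVLEN": 6}))
        assert padded[0].insert_seq == "N" * 6

    def test_svlen_substitutes_for_end(self):
        bes = symbolic_to_breakends(rec(alt="<DEL>", pos=100, info={"SVLEN": -100}))
        assert sig(bes) == [("chr1", 100, "+"), ("chr1", 201, "-")]

    def test_missing_end_and_negative_span(self):
        with pytest.raises(MissingEnd):
            symbolic_to_breakends(rec(alt="<DEL>", pos=100))
        with pytest.raises(NegativeSpan):
            symbolic_to_breakends(rec(alt="<DEL>", pos=100, info={"END": 50}))


class TestDirect:
    def test_net_deletion(self):
        ref = "A" + "T" * 100
        bes = direct_alt_to_breakends(rec(pos=100, ref=ref, alt="A"))
        assert sig(bes) == [("chr1", 100, "+"), ("chr1", 201, "-")]

    def test_net_insertion_keeps_sequence(self):
        ins = "ACGT" * 15
        bes = direct_alt_to_breakends(rec(pos=500, ref="A", alt="A" + ins))
        assert sig(bes) == [("chr1", 500, "+"), ("chr1", 501, "-")]
        assert bes[0].insert_seq == ins

    def test_snv_and_small_indel_skipped(self):
        assert direct_alt_to_breakends(rec(ref="A", alt="C")) == []
        assert direct_alt_to_breakends(rec(ref="A", alt="ACGT")) == []

    def test_min_sv_size_configurable(self):
        bes = direct_alt_to_breakends(rec(ref="A", alt="ACGTACGT"),
                                      IngestConfig(min_sv_size=5))
        assert len(bes) == 2


class TestUncertainty:
    def test_cipos_widens_interval(self):
        be = symbolic_to_breakends(rec(alt="<DEL>", pos=1000, info={"END": 2000}))[0]
        out = apply_uncertainty(be, rec(alt="<DEL>", pos=1000,
                                        info={"END": 2000, "CIPOS": (-3, 5),
                                              "IMPRECISE": True}))
        assert (out.lo, out.hi, out.nominal) == (997, 1005, 1000)
        assert not out.precise

    def test_no_ci_means_point_interval(self):
        be = symbolic_to_breakends(rec(alt="<DEL>", pos=1000, info={"END": 2000}))[0]
        out = apply_uncertainty(be, rec(alt="<DEL>", pos=1000, info={"END": 2000}))
        assert (out.lo, out.hi) == (1000, 1000) and out.precise

    def test_homology_makes_precise_interval(self):
        # CIPOS=(0,4) with HOMLEN=4 and no IMPRECISE: precise call located
        # over a 5 bp homologous range
        r = rec(alt="<DEL>", pos=1000,
                info={"END": 2000, "CIPOS": (0, 4), "HOMLEN": 4})
        out = apply_uncertainty(symbolic_to_breakends(r)[0], r)
        assert out.precise and out.homology_len == 4
        assert out.hi - out.lo + 1 == 5

    def test_end_side_uses_ciend(self):
        r = rec(alt="<DEL>", pos=1000,
                info={"END": 2000, "CIPOS": (-2, 2), "CIEND": (-7, 7),
                      "IMPRECISE": True})
        b1, b2 = symbolic_to_breakends(r)
        assert apply_uncertainty(b1, r).width == 4
        assert apply_uncertainty(b2, r).width == 14


class TestDialects:
    def test_delly_tra_becomes_bnd_pair(self):
        r = rec(pos=500, alt="<TRA>", ref="N",
                info={"SVTYPE": "TRA", "CHR2": "chr5", "END": 900, "CT": "3to5"})
        out = normalize_dialect(r)
        assert len(out) == 2
        bset = breakpoint_ranges(out)
        (a, b), = bset.breakpoint_pairs()
        assert (a.contig, a.nominal, a.orientation) == ("chr1", 500, "+")
        assert (b.contig, b.nominal, b.orientation) == ("chr5", 900, "-")

    def test_ct_5to5_gives_minus_minus(self):
        r = rec(pos=500, alt="<TRA>",
                info={"SVTYPE": "TRA", "CHR2": "chr5", "END": 900, "CT": "5to5"})
        bset = breakpoint_ranges(normalize_dialect(r))
        (a, b), = bset.breakpoint_pairs()
        assert (a.orientation, b.orientation) == ("-", "-")

    def test_inv3_keeps_only_plus_plus_breakpoint(self):
        full = symbolic_to_breakends(rec(alt="<INV>", pos=100, info={"END": 200}))
        r3 = rec(alt="<INV>", pos=100, info={"SVTYPE": "INV", "END": 200, "INV3": True})
        only3 = symbolic_to_breakends(normalize_dialect(r3)[0])
        assert sig(only3) == sig(full)[:2]
        assert {b.orientation for b in only3} == {"+"}
        r5 = rec(alt="<INV>", pos=100, info={"SVTYPE": "INV", "END": 200, "INV5": True})
        only5 = symbolic_to_breakends(normalize_dialect(r5)[0])
        assert {b.orientation for b in only5} == {"-"}

    def test_rpl_becomes_deletion_with_insert(self):
        r = rec(pos=100, ref="N", alt="NACGTT",
                info={"SVTYPE": "RPL", "END": 300})
        out, = normalize_dialect(r)
        bes = symbolic_to_breakends(out)
        assert sig(bes) == [("chr1", 100, "+"), ("chr1", 301, "-")]
        assert bes[0].insert_seq == "ACGTT"

    def test_compliant_record_passes_through_unchanged(self):
        r = rec(alt="<DEL>", info={"SVTYPE": "DEL", "END": 200})
        assert normalize_dialect(r) == [r]

    def test_unk_skipped(self):
        assert normalize_dialect(rec(alt="<UNK>", info={"SVTYPE": "UNK"})) == []


class TestFileIngest:
    def test_mixed_file_breakend_count(self, vcf_file):
        path = vcf_file(
            "chr1\t100\td1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=200\n"
            "chr1\t5000\ti1\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=6000\n"
            "chr2\t100\tb1\tN\tN[chr3:400[\t.\tPASS\tSVTYPE=BND;MATEID=b2\n"
            "chr3\t400\tb2\tN\t]chr2:100]N\t.\tPASS\tSVTYPE=BND;MATEID=b1\n")
        bset = breakpoint_ranges(path)
        assert len(bset) == 2 + 4 + 2
        assert len(bset.breakpoint_pairs()) == 4

    def test_unmated_bnd_policies(self, vcf_file):
        path = vcf_file("chr1\t100\tb1\tN\tN[chr3:400[\t.\tPASS\tSVTYPE=BND;MATEID=bX\n")
        down = breakpoint_ranges(path, IngestConfig(unmated_policy="downgrade"))
        assert len(down) == 1 and down.get("b1").partner_id is None
        drop = breakpoint_ranges(path, IngestConfig(unmated_policy="drop"))
        assert len(drop) == 0

    def test_breakend_ranges_returns_only_singles(self, vcf_file):
        path = vcf_file(
            "chr1\t100\td1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=200\n"
            "chr2\t100\tb1\tN\tN[chr3:400[\t.\tPASS\tSVTYPE=BND;MATEID=b2\n"
            "chr3\t400\tb2\tN\t]chr2:100]N\t.\tPASS\tSVTYPE=BND;MATEID=b1\n"
            "chr3\t1234\ts1\tG\tG.\t.\tPASS\tSVTYPE=BND\n")
        singles = breakend_ranges(path)
        assert [(b.id, b.contig, b.nominal, b.orientation)
                for b in singles] == [("s1", "chr3", 1234, "+")]
        # and breakpoint_ranges leaves the single to breakend_ranges
        assert "s1" not in breakpoint_ranges(path)

    def test_del_only_file_has_no_singles(self, vcf_file):
        path = vcf_file("chr1\t100\td1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=200\n")
        assert len(breakend_ranges(path)) == 0


class TestWriter:
    def test_one_deletion_gives_reciprocal_bnd_lines(self, vcf_file, tmp_path):
        src = vcf_file("chr1\t100\td1\tN\t<DEL>\t60\tPASS\tSVTYPE=DEL;END=200\n")
        bset = breakpoint_ranges(src)
        out = tmp_path / "out.vcf"
        assert write_bnd_vcf(bset, out) == 2
        lines = [l.split("\t") for l in out.read_text().splitlines()
                 if not l.startswith("#")]
        assert len(lines) == 2
        ids = [l[2] for l in lines]
        mateids = [dict(kv.split("=") for kv in l[7].split(";") if "=" in kv)["MATEID"]
                   for l in lines]
        assert mateids == ids[::-1]

    def test_empty_set_writes_header_only(self, tmp_path):
        from svbreaks import make_breakpoint_set
        out = tmp_path / "empty.vcf"
        assert write_bnd_vcf(make_breakpoint_set([]), out) == 0
        body = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert body == []

    def test_round_trip_identity_on_model_fields(self, vcf_file, tmp_path):
        src = vcf_file(
            "chr1\t100\td1\tN\t<DEL>\t60\tPASS\tSVTYPE=DEL;END=200;CIPOS=-5,5;CIEND=-5,5;IMPRECISE\n"
            "chr1\t5000\ti1\tN\t<INV>\t33\tPASS\tSVTYPE=INV;END=6000;CIPOS=0,3;CIEND=0,3;HOMLEN=3\n"
            "chr2\t100\tb1\tN\tNGT[chr3:400[\t.\tPASS\tSVTYPE=BND;MATEID=b2\n"
            "chr3\t400\tb2\tN\t]chr2:100]GTN\t.\tPASS\tSVTYPE=BND;MATEID=b1\n"
            "chr3\t1234\ts1\tG\tGACGT.\t12\tPASS\tSVTYPE=BND\n")
        bset = breakpoint_ranges(src)
        singles = breakend_ranges(src)
        merged = list(bset) + list(singles)
        from svbreaks import make_breakpoint_set
        full = make_breakpoint_set(merged, contig_order=bset.contig_order)
        out = tmp_path / "rt.vcf"
        write_bnd_vcf(full, out)
        back_pairs = breakpoint_ranges(str(out))
        back_singles = breakend_ranges(str(out))
        back = make_breakpoint_set(list(back_pairs) + list(back_singles),
                                   contig_order=back_pairs.contig_order)
        assert model_fields(back) == model_fields(full)
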
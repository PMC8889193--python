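"""Domain types, interval arithmetic and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_cg_scan
from oximap import io as oio
from oximap.core import (
    CGSite,
    ExpressionRecord,
    FragmentAlignment,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    ModCall,
    ParseError,
    Scaffold,
    ValidationError,
    WGBSCall,
    validate_against_scaffolds,
)


class TestTypes:
    def test_interval_rejects_empty_and_inverted(self):
        with pytest.raises(ValidationError):
            GenomicInterval("s1", 100, 100)
        with pytest.raises(ValidationError):
            GenomicInterval("s1", 10, 5)
        with pytest.raises(ValidationError):
            GenomicInterval("s1", -1, 5)

    def test_scaffold_requires_positive_length(self):
        with pytest.raises(ValidationError):
            Scaffold("s1", 0)

    def test_gene_model_validates_children(self):
        body = GenomicInterval("s1", 100, 500, "+")
        with pytest.raises(ValidationError):
            GeneModel("g", body, exons=(GenomicInterval("s1", 50, 200, "+"),))
        with pytest.raises(ValidationError):
            GeneModel(
                "g",
                body,
                exons=(
                    GenomicInterval("s1", 100, 300, "+"),
                    GenomicInterval("s1", 250, 500, "+"),
                ),
            )

    def test_gene_upstream_is_strand_aware(self):
        plus = GeneModel("g1", GenomicInterval("s1", 5000, 6000, "+"))
        minus = GeneModel("g2", GenomicInterval("s1", 5000, 6000, "-"))
        assert plus.upstream_interval() == GenomicInterval("s1", 4000, 5000, "+")
        assert minus.upstream_interval(10_000) == GenomicInterval("s1", 6000, 7000, "-")
        edge = GeneModel("g3", GenomicInterval("s1", 5000, 6000, "-"))
        assert edge.upstream_interval(6000) is None

    def test_wgbs_counts_bounded(self):
        with pytest.raises(ValidationError):
            WGBSCall(CGSite("s1", 5), methylated=6, total=5)

    def test_modcall_coverage_integer(self):
        with pytest.raises(ValidationError):
            ModCall(CGSite("s1", 5), "5hmC", -1)
        with pytest.raises(ValidationError):
            ModCall(CGSite("s1", 5), "7mG", 3)


class TestIntervalSet:
    def test_union_merges_overlaps(self):
        s = IntervalSet(
            [GenomicInterval("s1", 0, 10), GenomicInterval("s1", 5, 20), GenomicInterval("s1", 30, 40)]
        )
        assert s.total_bases() == 30
        assert [(iv.start, iv.end) for iv in s.intervals()] == [(0, 20), (30, 40)]

    def test_covered_bases_matches_mask(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            spans = [
                (int(a), int(a) + int(l))
                for a, l in zip(rng.integers(0, 900, 15), rng.integers(1, 120, 15))
            ]
            mask = np.zeros(1200, dtype=bool)
            for a, b in spans:
                mask[a:b] = True
            s = IntervalSet(GenomicInterval("x", a, b) for a, b in spans)
            qs = rng.integers(0, 600, 30)
            qe = qs + rng.integers(1, 500, 30)
            got = s.covered_bases("x", qs, qe)
            want = [mask[a:b].sum() for a, b in zip(qs, qe)]
            np.testing.assert_array_equal(got, want)

    def test_contains_and_overlaps(self):
        s = IntervalSet([GenomicInterval("s1", 10, 20)])
        np.testing.assert_array_equal(s.contains("s1", [9, 10, 19, 20]), [False, True, True, False])
        np.testing.assert_array_equal(
            s.overlaps("s1", [0, 19, 20], [10, 25, 30]), [False, True, False]
        )
        assert not s.contains("s2", [15])[0]

    def test_validate_against_scaffolds(self):
        scafs = [Scaffold("s1", 100)]
        with pytest.raises(ValidationError):
            validate_against_scaffolds([GenomicInterval("s2", 0, 10)], scafs)
        with pytest.raises(ValidationError):
            validate_against_scaffolds([GenomicInterval("s1", 50, 150)], scafs)
        with pytest.warns(UserWarning):
            kept = validate_against_scaffolds(
                [GenomicInterval("s2", 0, 10), GenomicInterval("s1", 0, 10)], scafs, lenient=True
            )
        assert kept == [GenomicInterval("s1", 0, 10)]


class TestBed:
    def test_bed3_maps_fields(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\n")
        assert oio.read_intervals(p, "BED3") == [GenomicInterval("chr1", 0, 100)]

    def test_empty_interval_is_error(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t100\n")
        with pytest.raises(ValidationError):
            oio.read_intervals(p, "BED3")

    def test_bed6_strand(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\tx\t0\t−\n")  # typographic minus tolerated
        (iv,) = oio.read_intervals(p, "BED6")
        assert iv.strand == "-"

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\nchr1\tnope\t3\n")
        with pytest.raises(ParseError, match=":2"):
            oio.read_intervals(p, "BED3")

    def test_roundtrip(self, tmp_path):
        ivs = [GenomicInterval("s1", 5, 10), GenomicInterval("s1", 0, 3), GenomicInterval("s2", 1, 9)]
        p = tmp_path / "rt.bed"
        oio.write_intervals(p, ivs)
        assert oio.read_intervals(p, "BED3") == sorted(ivs)


class TestGff3:
    GFF = (
        "##gff-version 3\n"
        "s1\tx\tgene\t1\t300\t.\t+\t.\tID=gA\n"
        "s1\tx\texon\t1\t120\t.\t+\t.\tID=gA.e1;Parent=gA\n"
        "s1\tx\texon\t200\t300\t.\t+\t.\tID=gA.e2;Parent=gA\n"
        "s1\tx\tfive_prime_UTR\t1\t50\t.\t+\t.\tID=gA.u5;Parent=gA\n"
        "s1\tx\tgene\t500\t800\t.\t-\t.\tID=gB\n"
    )

    def test_coordinates_converted(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(self.GFF)
        genes = oio.read_gene_models(p)
        ga = next(g for g in genes if g.gene_id == "gA")
        assert (ga.body.start, ga.body.end) == (0, 300)
        assert [(e.start, e.end) for e in ga.exons] == [(0, 120), (199, 300)]
        assert ga.utr5[0] == GenomicInterval("s1", 0, 50, "+")
        gb = next(g for g in genes if g.gene_id == "gB")
        assert gb.utr5 == () and gb.utr3 == ()

    def test_exon_outside_parent_is_error(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "s1\tx\tgene\t1\t300\t.\t+\t.\tID=gA\n"
            "s1\tx\texon\t250\t400\t.\t+\t.\tID=gA.e1;Parent=gA\n"
        )
        with pytest.raises(ValidationError):
            oio.read_gene_models(p)

    def test_duplicate_gene_id_is_error(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "s1\tx\tgene\t1\t300\t.\t+\t.\tID=gA\n"
            "s1\tx\tgene\t400\t600\t.\t+\t.\tID=gA\n"
        )
        with pytest.raises(ValidationError):
            oio.read_gene_models(p)

    def test_roundtrip_identity(self, tmp_path, small_genome):
        genes = small_genome.genes[:40]
        p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
        oio.write_gene_models(p1, genes)
        back = oio.read_gene_models(p1)
        assert [g.body for g in back] == [g.body for g in genes]
        assert [g.exons for g in back] == [g.exons for g in genes]
        oio.write_gene_models(p2, back)
        assert p1.read_bytes() == p2.read_bytes()


class TestModCalls:
    def test_c_and_cg_span_dialects(self, tmp_path):
        p = tmp_path / "m.bedGraph"
        p.write_text("s1\t10\t11\t4\ns1\t20\t22\t7\n")
        calls = oio.read_modcalls(p, "5hmC")
        assert [(c.site.pos, c.coverage) for c in calls] == [(10, 4), (20, 7)]

    def test_noninteger_coverage_rejected(self, tmp_path):
        p = tmp_path / "m.bedGraph"
        p.write_text("s1\t10\t11\t2.5\n")
        with pytest.raises(ValidationError):
            oio.read_modcalls(p, "5hmC")

    def test_negative_coverage_rejected(self, tmp_path):
        p = tmp_path / "m.bedGraph"
        p.write_text("s1\t10\t11\t-1\n")
        with pytest.raises(ValidationError):
            oio.read_modcalls(p, "5hmC")

    def test_roundtrip(self, tmp_path):
        calls = [
            ModCall(CGSite("s1", 5), "5fC", 3),
            ModCall(CGSite("s1", 2), "5fC", 9),
        ]
        p = tmp_path / "m.bedGraph"
        oio.write_modcalls(p, calls)
        back = oio.read_modcalls(p, "5fC")
        assert [(c.site, c.coverage) for c in back] == [
            (CGSite("s1", 2), 9),
            (CGSite("s1", 5), 3),
        ]


class TestTablesRoundtrip:
    def test_wgbs(self, tmp_path):
        calls = [WGBSCall(CGSite("s1", 9), 3, 5), WGBSCall(CGSite("s1", 2), 0, 7)]
        p = tmp_path / "w.tsv"
        oio.write_wgbs(p, calls)
        assert oio.read_wgbs(p) == sorted(calls, key=lambda c: c.site)

    def test_expression(self, tmp_path):
        recs = [ExpressionRecord("g2", 0.0), ExpressionRecord("g1", 12.5)]
        p = tmp_path / "e.tsv"
        oio.write_expression(p, recs)
        assert oio.read_expression(p) == sorted(recs, key=lambda r: r.gene_id)

    def test_fragments(self, tmp_path):
        frags = [FragmentAlignment("s1", 10, 210, "a"), FragmentAlignment("s1", 5, 200, "a")]
        p = tmp_path / "f.bed"
        oio.write_fragments(p, frags)
        assert oio.read_fragments(p) == sorted(frags)

    def test_fragment_mapq_filter(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("s1\t0\t200\tr1\t45\ns1\t300\t500\tr2\t12\ns1\t600\t800\tr3\n")
        kept = oio.read_fragments(p, min_mapq=30)
        # low-MAPQ row dropped; row without score column kept
        assert [f.left for f in kept] == [0, 600]

    def test_scaffolds(self, tmp_path):
        scafs = [Scaffold("s2", 500), Scaffold("s1", 100)]
        p = tmp_path / "s.tsv"
        oio.write_scaffolds(p, scafs)
        assert oio.read_scaffolds(p) == sorted(scafs, key=lambda s: s.id)


class TestCgEnumeration:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGCGT", [1, 3]), ("AAAA", []), ("CGCG", [0, 2]), ("cgCg", [0, 2]), ("", []), ("C", [])],
    )
    def test_examples(self, seq, expected):
        sites = oio.enumerate_cg_sites(sequence=seq, scaffold="s")
        assert [s.pos for s in sites] == expected

    def test_requires_exactly_one_source(self):
        from oximap.core import ConfigError

        with pytest.raises(ConfigError):
            oio.enumerate_cg_sites()
        with pytest.raises(ConfigError):
            oio.enumerate_cg_sites(sequence="ACGT", sites=[CGSite("s", 1)])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_scan_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        got = [s.pos for s in oio.enumerate_cg_sites(sequence=seq)]
        assert got == brute_cg_scan(seq)

    def test_fasta_source(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">s1\nACGCGT\n>s2\nTTCG\n")
        sites = oio.enumerate_cg_sites(fasta_path=p)
        assert sites == [CGSite("s1", 1), CGSite("s1", 3), CGSite("s2", 2)]


class TestRepeatMasker:
    OUT = (
        "   SW   perc perc perc  query     position in query    matching repeat\n"
        "score   div. del. ins.  sequence  begin end  (left)    repeat  class/family ...\n"
        "\n"
        "  463   1.3  0.6  1.7  s1         101   600  (0)  +  Gypsy-1   LTR/Gypsy   1 500 (0) 1\n"
        "  239  15.4  0.0  0.0  s1        1001  1100  (0)  C  A-rich    Low_complexity  1 100 (0) 2\n"
        "  311   5.0  0.0  0.0  s2         201   450  (0)  +  Mar-3     DNA/Mariner 1 250 (0) 3\n"
    )

    def test_converts_coordinates_and_classes(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(self.OUT)
        tes = oio.read_repeatmasker_out(p)
        assert len(tes) == 3
        gypsy = tes[0]
        assert (gypsy.location.start, gypsy.location.end) == (100, 600)
        assert (gypsy.te_class, gypsy.order, gypsy.family) == ("I", "LTR", "Gypsy")
        mariner = tes[2]
        assert mariner.te_class == "II"

    def test_te_only_drops_low_complexity(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(self.OUT)
        tes = oio.read_repeatmasker_out(p, te_only=True)
        assert [t.family for t in tes] == ["Gypsy", "Mariner"]
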
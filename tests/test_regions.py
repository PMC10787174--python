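import numpy as np
import pytest

from cnegrn.regions import (BedParseError, GeneModel, GenomicRegion,
                            RegionSet, annotate_location, intersect,
                            parse_region_id, read_bed, read_gene_models,
                            window_query, write_bed)


def _random_regions(rng, n, n_chroms=3, span=10_000):
    regs = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, span))
        regs.append(GenomicRegion(chrom, start,
                                  start + int(rng.integers(1, 200)),
                                  f"r{i}"))
    return RegionSet(regs)


class TestGenomicRegion:
    def test_validation(self):
        with pytest.raises(ValueError):
            GenomicRegion("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicRegion("chr1", -1, 100)
        r = GenomicRegion("chr1", 100, 200)
        assert r.length == 100 and r.id == "chr1:100-200"

    def test_overlap_arithmetic(self):
        a = GenomicRegion("chr1", 100, 200)
        assert a.overlap(GenomicRegion("chr1", 150, 250)) == 50
        assert a.overlap(GenomicRegion("chr1", 200, 300)) == 0  # abutment
        assert a.overlap(GenomicRegion("chr2", 100, 200)) == 0


class TestBedIO:
    def test_read_bed4(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tpk1\n")
        rs = read_bed(str(p))
        r = rs["pk1"]
        assert (r.chrom, r.start, r.end) == ("chr1", 100, 200)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert len(read_bed(str(p))) == 0

    @pytest.mark.parametrize("line", ["chr1\t200\t100", "chr1\t100",
                                      "chr1\tx\t200"])
    def test_malformed_lines_name_the_line(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\tok\n" + line + "\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(str(p))

    def test_round_trip_identity(self, tmp_path, bundle_dir):
        rs = read_bed(str(bundle_dir / "cnes.bed"))
        out = tmp_path / "rt.bed"
        write_bed(rs, str(out))
        rt = read_bed(str(out))
        assert [(r.chrom, r.start, r.end, r.id) for r in rs] == \
               [(r.chrom, r.start, r.end, r.id) for r in rt]


class TestParseRegionId:
    def test_start_length_dialect(self):
        # printed coordinate is 1-based; length is the second field
        r = parse_region_id("chr1:196579342-242", "start-length")
        assert (r.start, r.end, r.length) == (196579341, 196579341 + 242, 242)
        assert parse_region_id("chr11:40325877-150", "start-length").length == 150

    def test_start_end_dialect(self):
        r = parse_region_id("chr1:101-200", "start-end")
        assert (r.start, r.end, r.length) == (100, 200, 100)

    @pytest.mark.parametrize("bad", ["chr1:a-b", "chr1:100-0", "chr1"])
    def test_errors(self, bad):
        with pytest.raises(ValueError):
            parse_region_id(bad, "start-length")

    def test_dialect_must_be_explicit(self):
        with pytest.raises(ValueError):
            parse_region_id("chr1:1-2", "guess")


class TestIntersect:
    def test_basic_pair(self):
        a = RegionSet([GenomicRegion("chr1", 100, 200, "a")])
        b = RegionSet([GenomicRegion("chr1", 150, 250, "b")])
        assert intersect(a, b) == [("a", "b", 50)]

    def test_half_open_abutment(self):
        a = RegionSet([GenomicRegion("chr1", 100, 200, "a")])
        b = RegionSet([GenomicRegion("chr1", 200, 300, "b")])
        assert intersect(a, b) == []

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        a = _random_regions(rng, 1000)
        b = _random_regions(rng, 1000)
        for min_ov in (1, 25):
            got = sorted(intersect(a, b, min_ov))
            expected = sorted(
                (ra.id, rb.id, ra.overlap(rb))
                for ra in a for rb in b if ra.overlap(rb) >= min_ov)
            assert got == expected

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(1)
        a = _random_regions(rng, 200)
        b = _random_regions(rng, 200)
        fwd = {(x, y, o) for x, y, o in intersect(a, b)}
        rev = {(y, x, o) for x, y, o in intersect(b, a)}
        assert fwd == rev


class TestWindowQuery:
    def test_window_edge_inclusion(self):
        rs = RegionSet([GenomicRegion("chr1", 1_999_000, 2_001_000, "r")])
        assert len(window_query(rs, "chr1", 1_000_000, 1_000_000)) == 1

    def test_flank_zero_contains_anchor_only(self):
        rs = RegionSet([GenomicRegion("chr1", 100, 200, "in"),
                        GenomicRegion("chr1", 300, 400, "out")])
        assert window_query(rs, "chr1", 150, 0).ids == ["in"]
        assert window_query(rs, "chr1", 250, 0).ids == []

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            window_query(RegionSet(), "chr1", 0, -1)

    def test_against_scan_oracle(self):
        rng = np.random.default_rng(2)
        rs = _random_regions(rng, 500)
        for _ in range(20):
            chrom = f"chr{rng.integers(1, 4)}"
            anchor = int(rng.integers(0, 10_000))
            flank = int(rng.integers(0, 500))
            got = set(window_query(rs, chrom, anchor, flank).ids)
            lo, hi = anchor - flank, anchor + flank
            expected = {r.id for r in rs
                        if r.chrom == chrom and r.start <= hi and r.end - 1 >= lo}
            assert got == expected


class TestAnnotateLocation:
    @pytest.fixture
    def genes(self):
        return [GeneModel("g1", "chr1", 10_000, 20_000, "+",
                          exons=[(10_000, 11_000), (19_000, 20_000)])]

    def test_promoter_within_3kb_of_tss(self, genes):
        r = GenomicRegion("chr1", 11_000, 11_100)  # 1 kb downstream of TSS
        assert annotate_location(r, genes) == "promoter"

    def test_intronic_far_from_tss(self, genes):
        r = GenomicRegion("chr1", 15_000, 15_100)
        assert annotate_location(r, genes) == "intron"

    def test_exonic(self, genes):
        # > 3 kb from the TSS and inside the terminal exon
        assert annotate_location(GenomicRegion("chr1", 19_500, 19_600),
                                 genes) == "exon"

    def test_distal(self, genes):
        assert annotate_location(GenomicRegion("chr1", 70_000, 70_100),
                                 genes) == "distal_intergenic"

    def test_unknown_chromosome_is_distal(self, genes):
        assert annotate_location(GenomicRegion("chrX", 0, 100),
                                 genes) == "distal_intergenic"

    def test_every_region_gets_exactly_one_category(self, genes):
        rng = np.random.default_rng(3)
        cats = {"promoter", "exon", "intron", "distal_intergenic"}
        for _ in range(200):
            start = int(rng.integers(0, 40_000))
            r = GenomicRegion("chr1", start, start + int(rng.integers(1, 500)))
            assert annotate_location(r, genes) in cats


class TestGeneModels:
    def test_tss_strand_rule(self):
        plus = GeneModel("a", "chr1", 100, 200, "+")
        minus = GeneModel("b", "chr1", 100, 200, "-")
        assert plus.tss == 100 and minus.tss == 199

    def test_gtf_reader(self, bundle_dir, bundle):
        genes = read_gene_models(str(bundle_dir / "genes.gtf"))
        assert {g.gene_id for g in genes} == \
               {g.gene_id for g in bundle.gene_models}
        by_id = {g.gene_id: g for g in genes}
        for g in bundle.gene_models:
            assert (by_id[g.gene_id].start, by_id[g.gene_id].end) == \
                   (g.start, g.end)
            assert by_id[g.gene_id].exons == g.exons
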
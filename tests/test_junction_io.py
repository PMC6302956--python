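"""Junction formats, set algebra, reference classes and evaluation."""

import numpy as np
import pytest

from splicefilter.junction_io import (
    MarkedJunctionSet,
    ParseError,
    ReferenceIndex,
    compare_to_reference,
    evaluate,
    load_reference,
    read_junctions,
    set_operate,
    write_junctions,
)
from splicefilter.model import (
    HammingScores,
    IntronLocus,
    JunctionMetrics,
    JunctionRecord,
    JunctionVerdict,
    SpliceSiteCall,
)


def make_records(n=5, seed=0):
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n):
        start = 1000 + i * 500
        locus = IntronLocus("chr1", start, start + 100, "+")
        metrics = JunctionMetrics(
            nb_raw=int(rng.integers(1, 50)),
            nb_unique_split=int(rng.integers(0, 10)),
            nb_unique_mapped=int(rng.integers(0, 10)),
            nb_reliable=int(rng.integers(0, 10)),
            reliable_ratio=float(rng.random()),
            entropy=float(rng.random() * 4),
            deviations=rng.random(20),
            max_overhang=int(rng.integers(5, 38)),
            maxmmes=int(rng.integers(1, 38)),
            mean_mismatches=float(rng.random() * 2),
        )
        out[locus] = JunctionRecord(
            locus=locus,
            metrics=metrics,
            site_call=SpliceSiteCall("GT", "AG", "canonical", "+"),
            hamming=HammingScores(7, 8, 10),
            intron_score=float(rng.random()),
            pwm_score=float(rng.normal()),
            splicing_signal=float(rng.normal()),
            verdict=JunctionVerdict(float(rng.random()), bool(rng.integers(0, 2))),
            anchor_left_start=start - 30,
            anchor_right_end=start + 140,
        )
    return out


class TestTabFormat:
    def test_round_trip_preserves_every_field(self, tmp_path):
        records = make_records()
        path = tmp_path / "j.tab"
        write_junctions(records, str(path), "tab")
        back = read_junctions(str(path), "tab")
        assert set(back) == set(records)
        for locus, rec in records.items():
            got = back[locus]
            assert got.locus == rec.locus and got.locus.strand == rec.locus.strand
            assert got.metrics.nb_raw == rec.metrics.nb_raw
            assert got.metrics.entropy == rec.metrics.entropy
            assert np.array_equal(got.metrics.deviations, rec.metrics.deviations)
            assert got.verdict == rec.verdict
            assert got.intron_score == rec.intron_score

    def test_write_read_write_is_byte_identical(self, tmp_path):
        records = make_records(seed=3)
        a, b = tmp_path / "a.tab", tmp_path / "b.tab"
        write_junctions(records, str(a), "tab")
        write_junctions(read_junctions(str(a), "tab"), str(b), "tab")
        assert a.read_bytes() == b.read_bytes()

    def test_empty_set_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.tab"
        write_junctions({}, str(path), "tab")
        lines = path.read_text().splitlines()
        assert len(lines) == 2 and lines[0].startswith("#")
        assert read_junctions(str(path), "tab") == {}

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tab"
        write_junctions(make_records(1), str(path), "tab")
        with open(path, "a") as fh:
            fh.write("chr1\toops\n")
        with pytest.raises(ParseError, match=":4:"):
            read_junctions(str(path), "tab")


class TestBedFormats:
    def test_bed12_block_arithmetic(self, tmp_path):
        """Anchors [1000,1030)+[1130,1170) become blockSizes 30,40 at chromStart 1000."""
        locus = IntronLocus("chr1", 1030, 1130, "+")
        rec = JunctionRecord(
            locus=locus,
            verdict=JunctionVerdict(0.75, True),
            anchor_left_start=1000,
            anchor_right_end=1170,
        )
        path = tmp_path / "j.bed"
        write_junctions({locus: rec}, str(path), "bed_exon")
        fields = path.read_text().strip().split("\t")
        assert fields[1] == "1000" and fields[2] == "1170"
        assert fields[4] == "750"  # round(1000 * probability)
        assert (fields[6], fields[7]) == ("1030", "1130")  # thick = intron
        assert fields[9] == "2"
        assert fields[10] == "30,40"
        assert fields[11] == "0,130"

    def test_bed12_round_trip_byte_identical(self, tmp_path):
        records = make_records(seed=5)
        a, b = tmp_path / "a.bed", tmp_path / "b.bed"
        write_junctions(records, str(a), "bed_exon")
        write_junctions(read_junctions(str(a), "bed_exon"), str(b), "bed_exon")
        assert a.read_bytes() == b.read_bytes()

    def test_bed12_reconstructs_locus_and_anchors(self, tmp_path):
        records = make_records(seed=6)
        path = tmp_path / "j.bed"
        write_junctions(records, str(path), "bed_exon")
        back = read_junctions(str(path), "bed_exon")
        assert set(back) == set(records)
        for locus, rec in records.items():
            assert back[locus].anchor_left_start == rec.anchor_left_start
            assert back[locus].anchor_right_end == rec.anchor_right_end

    def test_wrong_block_count_rejected(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text(
            "chr1\t100\t400\tj\t0\t+\t150\t350\t255,0,0\t3\t50,50,50\t0,100,250\n"
        )
        with pytest.raises(ParseError, match="blockCount"):
            read_junctions(str(path), "bed_exon")

    def test_intron_bed_round_trip(self, tmp_path):
        records = make_records(seed=7)
        path = tmp_path / "j.ibed"
        write_junctions(records, str(path), "intron_bed")
        back = read_junctions(str(path), "intron_bed")
        assert set(back) == set(records)

    def test_hint_gff_and_mapper_sj_are_writable(self, tmp_path):
        records = make_records(1, seed=8)
        write_junctions(records, str(tmp_path / "h.gff3"), "hint_gff")
        gff = (tmp_path / "h.gff3").read_text().splitlines()
        assert gff[0] == "##gff-version 3"
        locus = next(iter(records))
        fields = gff[1].split("\t")
        # GFF is 1-based inclusive over the intron
        assert (int(fields[3]), int(fields[4])) == (locus.start + 1, locus.end)
        write_junctions(records, str(tmp_path / "h.ss"), "mapper_sj")
        ss = (tmp_path / "h.ss").read_text().strip().split("\t")
        assert (int(ss[1]), int(ss[2])) == (locus.start - 1, locus.end)


def _loci(*intervals, contig="c", strand="+"):
    return [IntronLocus(contig, s, e, strand) for s, e in intervals]


class TestSetOps:
    def test_union_counts_sample_presence(self):
        shared = _loci((100, 200))
        sets = [
            MarkedJunctionSet.from_loci(shared + _loci((300 + i * 50, 400 + i * 50)))
            for i in range(6)
        ]
        union = set_operate(sets, "union")
        assert union.records[shared[0]].sample_count == 6
        assert len(union) == 7

    def test_disjoint_union_size_is_sum(self):
        sets = [
            MarkedJunctionSet.from_loci(_loci((i * 1000, i * 1000 + 100)))
            for i in range(1, 4)
        ]
        assert len(set_operate(sets, "union")) == 3

    def test_self_subtraction_is_empty(self):
        s = MarkedJunctionSet.from_loci(_loci((100, 200), (300, 400)))
        assert len(set_operate([s, s], "subtract")) == 0

    def test_intersection_keeps_common_keys_only(self):
        a = MarkedJunctionSet.from_loci(_loci((100, 200), (300, 400)))
        b = MarkedJunctionSet.from_loci(_loci((300, 400), (500, 600)))
        out = set_operate([a, b], "intersection")
        assert out.keys() == {IntronLocus("c", 300, 400)}

    def test_union_commutative_on_keys(self):
        a = MarkedJunctionSet.from_loci(_loci((100, 200), (300, 400)))
        b = MarkedJunctionSet.from_loci(_loci((300, 400), (500, 600)))
        assert set_operate([a, b], "union").keys() == set_operate([b, a], "union").keys()


class TestReferenceClasses:
    @pytest.fixture()
    def two_intron_reference(self):
        return ReferenceIndex.from_loci(_loci((100, 200), (300, 400)))

    def test_exact_intron_is_class1(self, two_intron_reference):
        breakdown = compare_to_reference(_loci((100, 200)), two_intron_reference)
        assert breakdown.counts == (1, 0, 0, 0)

    def test_cross_intron_sites_are_class2(self, two_intron_reference):
        """Donor of intron A combined with acceptor of intron B."""
        breakdown = compare_to_reference(_loci((100, 400)), two_intron_reference)
        assert breakdown.counts == (0, 1, 0, 0)

    def test_one_known_site_is_class3(self, two_intron_reference):
        breakdown = compare_to_reference(_loci((100, 250)), two_intron_reference)
        assert breakdown.counts == (0, 0, 1, 0)

    def test_two_novel_sites_are_class4(self, two_intron_reference):
        breakdown = compare_to_reference(_loci((150, 250)), two_intron_reference)
        assert breakdown.counts == (0, 0, 0, 1)

    def test_counts_partition_the_input(self, two_intron_reference):
        rng = np.random.default_rng(11)
        junctions = _loci(*[(int(s), int(s) + 70) for s in rng.integers(0, 2000, 40)])
        breakdown = compare_to_reference(junctions, two_intron_reference)
        assert sum(breakdown.counts) == len(junctions)
        assert len(breakdown.labels) == len(set(j.key() for j in junctions))

    def test_strand_agnostic_when_unknown(self, two_intron_reference):
        unknown = _loci((100, 200), strand="?")
        assert compare_to_reference(unknown, two_intron_reference).counts[0] == 1
        minus = _loci((100, 200), strand="-")
        # both strands known and different: not the same intron
        assert compare_to_reference(minus, two_intron_reference).counts[0] == 0


class TestEvaluate:
    def test_perfect_prediction(self):
        truth = _loci((1, 10), (20, 30))
        assert evaluate(truth, truth) == (1.0, 1.0, 1.0)

    def test_half_recall_full_precision(self):
        truth = _loci((1, 10), (20, 30))
        recall, precision, f1 = evaluate(truth[:1], truth)
        assert (recall, precision) == (0.5, 1.0)
        assert f1 == pytest.approx(2 / 3)

    def test_empty_prediction_degenerate(self):
        assert evaluate([], _loci((1, 10))) == (0.0, 0.0, 0.0)

    def test_swapping_arguments_swaps_recall_precision(self):
        a, b = _loci((1, 10), (20, 30), (40, 50)), _loci((20, 30), (60, 70))
        r1, p1, _ = evaluate(a, b)
        r2, p2, _ = evaluate(b, a)
        assert (r1, p1) == (p2, r2)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_loci((1, 10)), [])


class TestLoadReference:
    def test_gtf_exon_pair_coordinate_conversion(self, tmp_path):
        """1-based exon end 100 + next start 200 give intron [100, 199)."""
        gtf = tmp_path / "r.gtf"
        attrs = 'gene_id "g1"; transcript_id "t1";'
        gtf.write_text(
            f'chr1\tsrc\texon\t1\t100\t.\t+\t.\t{attrs}\n'
            f'chr1\tsrc\texon\t200\t300\t.\t+\t.\t{attrs}\n'
        )
        ref = load_reference(str(gtf), "gtf")
        assert set(ref.introns) == {("chr1", 100, 199)}

    def test_shared_intron_deduplicated_and_single_exon_ignored(self, tmp_path):
        gff = tmp_path / "r.gff3"
        lines = ["##gff-version 3"]
        for tid in ("t1", "t2"):
            lines.append(f"chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID={tid}")
            lines.append(f"chr1\tsrc\texon\t1\t100\t.\t+\t.\tID={tid}.e1;Parent={tid}")
            lines.append(f"chr1\tsrc\texon\t200\t300\t.\t+\t.\tID={tid}.e2;Parent={tid}")
        lines.append("chr1\tsrc\tmRNA\t500\t600\t.\t+\t.\tID=t3")
        lines.append("chr1\tsrc\texon\t500\t600\t.\t+\t.\tID=t3.e1;Parent=t3")
        gff.write_text("\n".join(lines) + "\n")
        ref = load_reference(str(gff), "gff3")
        assert set(ref.introns) == {("chr1", 100, 199)}

    def test_intron_bed_reference(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t100\t199\ti0\t0\t+\n")
        ref = load_reference(str(bed))
        assert set(ref.introns) == {("chr1", 100, 199)}
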
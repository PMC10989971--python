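"""Window statistics against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circleplot import fixtures, stats_prep
from circleplot.formats_io import ContinuousRecord, SkeletonRecord
from circleplot.stats_prep import WindowSpec, iter_windows


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestWindowSpec:
    def test_tiling_flag(self):
        assert WindowSpec(100).tiling
        assert not WindowSpec(100, 50).tiling

    @pytest.mark.parametrize("w,s", [(0, 1), (1, 0), (-5, 5)])
    def test_invalid(self, w, s):
        with pytest.raises(ValueError):
            WindowSpec(w, s)

    def test_tiling_windows_partition_chromosome(self):
        windows = list(iter_windows(1050, WindowSpec(100)))
        assert windows[0] == (1, 100)
        assert windows[-1] == (1001, 1050)  # partial terminal window kept
        covered = sum(e - s + 1 for s, e in windows)
        assert covered == 1050
        # disjoint and contiguous
        for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
            assert s2 == e1 + 1


class TestFastaLengths:
    def test_basic_and_wrapped(self, tmp_path):
        fa = write(tmp_path, "a.fa", ">a\nACGT\n>b desc\nAC\nGT\nAA\n")
        recs = stats_prep.fasta_lengths(fa)
        assert recs == [SkeletonRecord("a", 4), SkeletonRecord("b", 6)]

    def test_duplicate_ids_rejected(self, tmp_path):
        fa = write(tmp_path, "d.fa", ">a\nAC\n>a\nGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            stats_prep.fasta_lengths(fa)

    def test_empty_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            stats_prep.fasta_lengths(write(tmp_path, "e.fa", ""))


class TestWindowComposition:
    def test_extreme_windows(self, tmp_path):
        fa = write(tmp_path, "x.fa", ">s\nGGGGGCGCNNnn\n")
        comp = stats_prep.window_composition(fa, WindowSpec(4))
        # window 1 "GGGG": skew 1, gc 1, n 0
        assert comp.gc_skew[0].value == 1.0
        assert comp.gc_content[0].value == 1.0
        assert comp.n_ratio[0].value == 0.0
        # window 2 "GCGC": skew 0
        assert comp.gc_skew[1].value == 0.0
        # window 3 "NNnn": no called base
        assert comp.gc_content[2].value == 0.0
        assert comp.n_ratio[2].value == 1.0

    def test_case_insensitive_and_nonacgtn_as_n(self, tmp_path):
        fa = write(tmp_path, "y.fa", ">s\ngcGCRYKM\n")
        comp = stats_prep.window_composition(fa, WindowSpec(8))
        assert comp.gc_content[0].value == 1.0  # 4 called, all GC
        assert comp.n_ratio[0].value == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self, genome, genome_dir):
        spec = WindowSpec(1000, 500)
        comp = stats_prep.window_composition(str(genome_dir / "genome.fa"), spec)
        oracle = fixtures.brute_force_composition(genome.sequences, spec)
        assert comp.gc_content == oracle[0]
        assert comp.gc_skew == oracle[1]
        assert comp.n_ratio == oracle[2]

    def test_bounds(self, genome_dir):
        comp = stats_prep.window_composition(str(genome_dir / "genome.fa"), WindowSpec(1000, 500))
        assert all(-1.0 <= r.value <= 1.0 for r in comp.gc_skew)
        assert all(0.0 <= r.value <= 1.0 for r in comp.gc_content)
        assert all(0.0 <= r.value <= 1.0 for r in comp.n_ratio)

    @settings(deadline=None, max_examples=30)
    @given(seq=st.text(alphabet="ACGT", min_size=10, max_size=200))
    def test_reverse_complement_negates_skew(self, seq):
        import tempfile
        from pathlib import Path

        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        d = Path(tempfile.mkdtemp())
        fa = write(d, "f.fa", f">f\n{seq}\n")
        fa_rc = write(d, "r.fa", f">f\n{rc}\n")
        spec = WindowSpec(len(seq))
        fwd = stats_prep.window_composition(fa, spec)
        rev = stats_prep.window_composition(fa_rc, spec)
        assert rev.gc_skew[0].value == pytest.approx(-fwd.gc_skew[0].value)
        assert rev.gc_content[0].value == pytest.approx(fwd.gc_content[0].value)


class TestGeneDensity:
    def test_counts_in_single_window(self, tmp_path):
        gff = write(
            tmp_path, "g.gff3",
            "##gff-version 3\n"
            + "".join(f"Chr1\t.\tgene\t{p}\t{p+10}\t.\t+\t.\tID=g{i}\n"
                      for i, p in enumerate((5, 50, 99)))
            + "Chr1\t.\tmRNA\t5\t15\t.\t+\t.\tID=m1\n",
        )
        skel = [SkeletonRecord("Chr1", 200)]
        rows = stats_prep.gene_density(gff, WindowSpec(100), "gene", skel)
        assert rows[0].value == 3.0 and rows[1].value == 0.0

    def test_empty_annotation_all_zero(self, tmp_path):
        gff = write(tmp_path, "e.gff3", "##gff-version 3\n")
        rows = stats_prep.gene_density(gff, WindowSpec(100), "gene",
                                       [SkeletonRecord("Chr1", 250)])
        assert [r.value for r in rows] == [0.0, 0.0, 0.0]

    def test_conservation(self, genome, genome_dir, skeleton):
        rows = stats_prep.gene_density(str(genome_dir / "genes.gff3"),
                                       WindowSpec(5000), "gene", skeleton)
        assert sum(r.value for r in rows) == 100
        ann = fixtures.make_annotation(genome, 100, seed=1)
        assert rows == ann.true_density(genome.lengths, WindowSpec(5000))


class TestCoverageBins:
    def test_flag_exclusions(self, tmp_path):
        sam = write(
            tmp_path, "t.sam",
            "@HD\tVN:1.6\n@SQ\tSN:Chr1\tLN:1000\n"
            "r1\t0\tChr1\t10\t60\t5M\t*\t0\t0\tACGTA\tIIIII\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\tACGTA\tIIIII\n"      # unmapped
            "r3\t256\tChr1\t20\t60\t5M\t*\t0\t0\tACGTA\tIIIII\n"  # secondary
            "r4\t2048\tChr1\t30\t60\t5M\t*\t0\t0\tACGTA\tIIIII\n"  # supplementary
            "r5\t16\tChr1\t40\t60\t5M\t*\t0\t0\tACGTA\tIIIII\n",  # reverse, counted
        )
        rows = stats_prep.coverage_bins(sam, WindowSpec(1000))
        assert rows[0].value == 2.0

    def test_conservation_against_fixture(self, genome, genome_dir, skeleton):
        aln = fixtures.make_alignments(genome, 1000, seed=2)
        rows = stats_prep.coverage_bins(str(genome_dir / "reads.sam"),
                                        WindowSpec(5000), skeleton)
        assert sum(r.value for r in rows) == len(aln.counted) == 1000 - aln.n_excluded
        assert rows == aln.true_bins(genome.lengths, WindowSpec(5000))


class TestVcfBins:
    def test_header_only_zeros(self, tmp_path):
        vcf = write(
            tmp_path, "h.vcf",
            "##fileformat=VCFv4.2\n##contig=<ID=Chr1,length=500>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n",
        )
        rows = stats_prep.vcf_bins(vcf, WindowSpec(100))
        assert len(rows) == 5 and all(r.value == 0.0 for r in rows)

    def test_filter_column_not_applied(self, tmp_path):
        vcf = write(
            tmp_path, "f.vcf",
            "##fileformat=VCFv4.2\n"
            '##FILTER=<ID=LowQual,Description="x">\n'
            "##contig=<ID=Chr1,length=100>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "Chr1\t10\t.\tA\tG\t30\tPASS\t.\n"
            "Chr1\t20\t.\tC\tT\t5\tLowQual\t.\n",
        )
        rows = stats_prep.vcf_bins(vcf, WindowSpec(100))
        assert rows[0].value == 2.0

    def test_conservation_against_fixture(self, genome, genome_dir, skeleton):
        var = fixtures.make_variants(genome, 300, seed=3)
        rows = stats_prep.vcf_bins(str(genome_dir / "variants.vcf"),
                                   WindowSpec(5000), skeleton)
        assert sum(r.value for r in rows) == 300
        assert rows == var.true_bins(genome.lengths, WindowSpec(5000))


class TestGenePositions:
    def test_requested_order_and_warnings(self, genome_dir):
        records, warnings = stats_prep.gene_positions(
            str(genome_dir / "genes.gff3"), ["gene0002", "gene0001", "nope"]
        )
        assert [r.label for r in records] == ["gene0002", "gene0001"]
        assert len(warnings) == 1 and "nope" in warnings[0]

    def test_subset_matches_direct_scan(self, genome, genome_dir):
        ann = fixtures.make_annotation(genome, 100, seed=1)
        wanted = ann.gene_ids[10:20]
        records, warnings = stats_prep.gene_positions(str(genome_dir / "genes.gff3"), wanted)
        assert not warnings
        truth = {gid: (c, s, e) for gid, (c, s, e) in zip(ann.gene_ids, ann.positions)}
        assert [(r.chrom_id, r.start, r.end) for r in records] == [truth[g] for g in wanted]


class TestDiscreteColorScheme:
    def test_distinct_and_deterministic(self):
        a = stats_prep.discrete_color_scheme(12)
        b = stats_prep.discrete_color_scheme(12)
        assert a == b
        assert len({(c.r, c.g, c.b) for c in a}) == 12

    def test_n1_and_invalid(self):
        assert len(stats_prep.discrete_color_scheme(1)) == 1
        with pytest.raises(ValueError):
            stats_prep.discrete_color_scheme(0)


class TestBinContinuous:
    SKEL = [SkeletonRecord("Chr1", 1000)]

    def test_none_is_identity(self):
        recs = [ContinuousRecord("Chr1", 1, 10, 5.0)]
        assert stats_prep.bin_continuous(recs, self.SKEL, WindowSpec(100), "none") == recs

    def test_mean_of_two(self):
        recs = [
            ContinuousRecord("Chr1", 10, 20, 2.0),
            ContinuousRecord("Chr1", 30, 40, 4.0),
        ]
        rows = stats_prep.bin_continuous(recs, self.SKEL, WindowSpec(100), "mean")
        assert rows[0].value == 3.0 and len(rows) == 1  # empty windows omitted for mean

    def test_sum_conservation(self):
        rng = np.random.default_rng(7)
        recs = [
            ContinuousRecord("Chr1", int(p), int(p) + 5, float(v))
            for p, v in zip(rng.integers(1, 990, 500), rng.normal(size=500))
        ]
        rows = stats_prep.bin_continuous(recs, self.SKEL, WindowSpec(100), "sum")
        assert sum(r.value for r in rows) == pytest.approx(sum(r.value for r in recs))
        assert len(rows) == 10  # count/sum keep empty windows

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            stats_prep.bin_continuous([], self.SKEL, WindowSpec(100), "median")
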
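"""VCF/BED/outgroup I/O, polarization and fixed-substitution calling."""

import numpy as np
import pytest

from regsel.genomic_io import (NO_OUTGROUP, POLARIZED, UNPOLARIZABLE,
                               GenotypeTable, OutgroupAlleles,
                               call_substitutions, polarize, read_intervals,
                               read_outgroups, read_variants, write_intervals,
                               write_outgroups, write_vcf)
from regsel.intervals import IntervalSet

POOLS = {"P1": ["ind1", "ind2"]}


def write_test_vcf(path, records):
    lines = ["##fileformat=VCFv4.2",
             "##contig=<ID=chr1,length=1000000>",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tind1\tind2"]
    lines += records
    path.write_text("\n".join(lines) + "\n")


class TestReadVariants:
    def test_filters_indels_and_multiallelics(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        write_test_vcf(vcf, [
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t0|0",
            "chr1\t200\t.\tA\tAT\t.\tPASS\t.\tGT\t0|1\t0|0",
            "chr1\t300\t.\tC\tT\t.\tPASS\t.\tGT\t0|0\t1|1",
            "chr1\t400\t.\tC\tT,G\t.\tPASS\t.\tGT\t0|1\t0|2",
            "chr1\t500\t.\tG\tA\t.\tPASS\t.\tGT\t1|1\t0|0",
        ])
        gt = read_variants(vcf, POOLS)
        assert gt.n_sites == 3
        assert gt.load_report.excluded == {"indel": 1, "multiallelic": 1}

    def test_empty_vcf_ok(self, tmp_path):
        vcf = tmp_path / "b.vcf"
        write_test_vcf(vcf, [])
        gt = read_variants(vcf, POOLS)
        assert gt.n_sites == 0

    def test_sites_sorted_by_position(self, tmp_path):
        vcf = tmp_path / "c.vcf"
        write_test_vcf(vcf, [
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t0|0",
            "chr1\t50\t.\tC\tT\t.\tPASS\t.\tGT\t0|1\t0|0",
        ])
        gt = read_variants(vcf, POOLS)
        assert gt.pos.tolist() == [50, 100]

    def test_missing_individual_is_hard_error(self, tmp_path):
        vcf = tmp_path / "d.vcf"
        write_test_vcf(vcf, [])
        with pytest.raises(ValueError, match="ghost"):
            read_variants(vcf, {"P1": ["ind1", "ghost"]})

    def test_low_call_rate_site_dropped(self, tmp_path):
        vcf = tmp_path / "e.vcf"
        write_test_vcf(vcf, [
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t.|.\t0|1",
            "chr1\t200\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t0|1",
        ])
        gt = read_variants(vcf, POOLS, min_call_rate=0.8)
        assert gt.pos.tolist() == [200]
        assert gt.load_report.excluded["low_call_rate"] == 1

    def test_vcf_roundtrip(self, tmp_path, small_dataset):
        gt = small_dataset.genotypes
        path = tmp_path / "rt.vcf"
        write_vcf(gt, path)
        gt2 = read_variants(path, gt.pools)
        assert gt2.n_sites == gt.n_sites
        assert np.array_equal(gt2.pos, gt.pos)
        assert np.array_equal(gt2.haplotypes, gt.haplotypes)


class TestBed:
    def test_read_merges_and_roundtrips(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t10\t20\nchr1\t15\t30\nchr2\t0\t5\n")
        s = read_intervals(bed)
        assert list(s) == [("chr1", 10, 30), ("chr2", 0, 5)]
        out = tmp_path / "b.bed"
        write_intervals(s, out)
        s2 = read_intervals(out)
        assert s2 == s and s2.total_length == s.total_length

    def test_adjacent_rows_merge(self, tmp_path):
        bed = tmp_path / "c.bed"
        bed.write_text("chr1\t10\t20\nchr1\t20\t30\n")
        assert list(read_intervals(bed)) == [("chr1", 10, 30)]

    def test_empty_file(self, tmp_path):
        bed = tmp_path / "d.bed"
        bed.write_text("")
        assert read_intervals(bed).total_length == 0

    def test_bad_interval_reports_line(self, tmp_path):
        bed = tmp_path / "e.bed"
        bed.write_text("chr1\t10\t20\nchr1\t30\t30\n")
        with pytest.raises(ValueError, match=":2"):
            read_intervals(bed)


def make_gt(ref, alt, haps, pools=None):
    n = len(haps)
    return GenotypeTable(
        chrom=np.array(["chr1"] * 1, dtype=object),
        pos=np.array([100], dtype=np.int64),
        ref=np.array([ref]), alt=np.array([alt]),
        haplotypes=np.array([haps], dtype=np.int8),
        individuals=[f"i{k}" for k in range(n // 2)],
        pools=pools or {"P": [f"i{k}" for k in range(n // 2)]})


def make_og(alleles):
    return OutgroupAlleles(chrom=np.array(["chr1"], dtype=object),
                           pos=np.array([100], dtype=np.int64),
                           alleles=np.array([alleles], dtype="<U1"))


class TestPolarize:
    def test_unanimous_outgroups(self):
        gt = make_gt("A", "G", [0, 1, 0, 1])
        t = polarize(gt, make_og(["A", "A", "A"]))
        assert t.status[0] == POLARIZED
        assert t.derived[0, 0] == 2  # the two G haplotypes

    def test_two_of_three_consensus(self):
        gt = make_gt("A", "G", [0, 1, 1, 1])
        t = polarize(gt, make_og(["A", "A", "C"]))
        assert t.status[0] == POLARIZED and t.derived[0, 0] == 3

    def test_consensus_matching_neither_allele(self):
        gt = make_gt("A", "G", [0, 1, 0, 0])
        t = polarize(gt, make_og(["C", "C", "C"]))
        assert t.status[0] == UNPOLARIZABLE

    def test_no_outgroup_data(self):
        gt = make_gt("A", "G", [0, 1, 0, 0])
        t = polarize(gt, make_og([".", ".", "."]))
        assert t.status[0] == NO_OUTGROUP

    def test_derived_counts_invariant_to_ref_alt_swap(self):
        """Polarity comes from outgroups, not the reference genome."""
        og = make_og(["A", "A", "A"])
        t1 = polarize(make_gt("A", "G", [0, 1, 1, 0]), og)
        # swap labels: ref=G, alt=A; allele codes flip
        t2 = polarize(make_gt("G", "A", [1, 0, 0, 1]), og)
        assert t1.derived[0, 0] == t2.derived[0, 0] == 2

    def test_status_partition(self, small_dataset):
        t = polarize(small_dataset.genotypes, small_dataset.outgroups)
        assert ((t.status == POLARIZED).sum() + (t.status == UNPOLARIZABLE).sum()
                + (t.status == NO_OUTGROUP).sum()) == t.n_sites


class TestCallSubstitutions:
    mask = IntervalSet.from_pairs([("chr1", 0, 1000)])

    def test_fixed_derived_site_flagged(self):
        gt = make_gt("A", "G", [1, 1, 1, 1])
        t = call_substitutions(gt, make_og(["A", "A", "A"]), self.mask)
        assert t.is_fixed_substitution[0]

    def test_polymorphic_site_not_flagged(self):
        gt = make_gt("A", "G", [1, 1, 1, 0])
        t = call_substitutions(gt, make_og(["A", "A", "A"]), self.mask)
        assert not t.is_fixed_substitution[0]

    def test_site_outside_mask_excluded(self):
        gt = make_gt("A", "G", [1, 1, 1, 1])
        far = IntervalSet.from_pairs([("chr1", 5000, 6000)])
        t = call_substitutions(gt, make_og(["A", "A", "A"]), far)
        assert not t.is_fixed_substitution[0]


def test_outgroup_table_roundtrip(tmp_path, small_dataset):
    path = tmp_path / "og.tsv"
    write_outgroups(small_dataset.outgroups, path)
    og = read_outgroups(path)
    assert np.array_equal(og.pos, small_dataset.outgroups.pos)
    assert np.array_equal(og.alleles, small_dataset.outgroups.alleles)
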
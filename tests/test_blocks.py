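"""VCF/BED reading, block construction and folding rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusesweep.blocks import (
    BlockSet,
    Intervals,
    VariantTable,
    build_blocks,
    choose_block_length,
    exons_from_gff,
    expected_block_length,
    load_filtered_sites,
)
from fusesweep.coalescent import config_index

from conftest import full_mask


def write_vcf(path, rows, samples=("d0", "d1", "d2", "d3"), chrom="chr1",
              length=100_000):
    header = (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID={chrom},length={length}>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for pos, alt, gts in rows:
            fh.write(f"{chrom}\t{pos}\t.\tA\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


class TestLoadFilteredSites:
    def test_exon_padding_excludes_sites(self, tmp_path):
        # exon at [1000, 1100); pad 10 -> [990, 1110) excluded.
        # 5 SNPs: 995 and 1105 fall inside the padded exon, 3 remain.
        vcf = tmp_path / "toy.vcf"
        g = ["0/1", "0/0", "0/0", "0/0"]
        write_vcf(vcf, [(p, "T", g) for p in (500, 995, 1050, 1105, 2000)])
        # careful: VCF POS is 1-based; 0-based positions are POS - 1
        exons = Intervals.from_records([("chr1", 999, 1099)])
        mask = full_mask("chr1", 100_000)
        tab = load_filtered_sites(vcf, ["d0", "d1", "d2", "d3"],
                                  exclude_track=exons, callable_mask=mask)
        # 995 and 1105 (1-based) fall inside the padded exon and are dropped
        assert list(tab.pos) == [500, 2000]

    def test_pad_boundary_is_half_open(self, tmp_path):
        vcf = tmp_path / "b.vcf"
        g = ["0/1", "0/0", "0/0", "0/0"]
        # exon [1000,1100) 0-based, pad 10 -> [990, 1110): 0-based 989 kept,
        # 990 dropped, 1109 dropped, 1110 kept
        write_vcf(vcf, [(990, "T", g), (991, "T", g), (1110, "T", g),
                        (1111, "T", g)])
        exons = Intervals.from_records([("chr1", 1000, 1100)])
        tab = load_filtered_sites(vcf, ["d0", "d1", "d2", "d3"],
                                  exclude_track=exons,
                                  callable_mask=full_mask("chr1", 100_000))
        assert list(tab.pos) == [990, 1111]

    def test_subset_alt_counts(self, tmp_path):
        # genotypes 0/1, 0/1, 1/1, 0/0: subset excluding d3 sees 0/1,0/1,1/1
        vcf = tmp_path / "c.vcf"
        write_vcf(vcf, [(100, "T", ["0/1", "0/1", "1/1", "0/0"])])
        tab = load_filtered_sites(vcf, ["d0", "d1", "d2", "d3"],
                                  callable_mask=full_mask("chr1", 100_000))
        # total alts = 4; subset j = total - dip_j
        assert list(tab.alt_counts[0]) == [3, 3, 2, 4]

    def test_missing_genotype_drops_site(self, tmp_path):
        vcf = tmp_path / "d.vcf"
        write_vcf(vcf, [(100, "T", ["./.", "0/1", "0/0", "0/0"]),
                        (200, "T", ["0/1", "0/1", "0/0", "0/0"])])
        tab = load_filtered_sites(vcf, ["d0", "d1", "d2", "d3"],
                                  callable_mask=full_mask("chr1", 100_000))
        assert list(tab.pos) == [200]
        assert tab.n_dropped_missing == 1

    def test_multiallelic_dropped(self, tmp_path):
        vcf = tmp_path / "e.vcf"
        write_vcf(vcf, [(100, "T,G", ["0/1", "0/1", "0/2", "0/0"]),
                        (200, "T", ["0/1", "0/0", "0/0", "0/0"])])
        tab = load_filtered_sites(vcf, ["d0", "d1", "d2", "d3"],
                                  callable_mask=full_mask("chr1", 100_000))
        assert list(tab.pos) == [200]

    def test_missing_sample_is_fatal(self, tmp_path):
        vcf = tmp_path / "f.vcf"
        write_vcf(vcf, [(100, "T", ["0/1", "0/0", "0/0", "0/0"])])
        with pytest.raises(ValueError, match="missing"):
            load_filtered_sites(vcf, ["d0", "d1", "d2", "nope"])

    def test_retained_sites_respect_tracks(self, tmp_path, rng):
        # re-intersection invariant on a random fixture
        vcf = tmp_path / "g.vcf"
        g = ["0/1", "0/0", "0/1", "0/0"]
        pos = np.sort(rng.choice(np.arange(1, 50_000), 300, replace=False))
        write_vcf(vcf, [(int(p), "T", g) for p in pos])
        mask = Intervals.from_records([("chr1", 0, 20_000),
                                       ("chr1", 30_000, 50_000)])
        excl = Intervals.from_records([("chr1", 5_000, 6_000)])
        tab = load_filtered_sites(vcf, ["d0", "d1", "d2", "d3"],
                                  exclude_track=excl, callable_mask=mask)
        p0 = tab.pos - 1
        assert mask.contains("chr1", p0).all()
        assert not excl.pad(10).contains("chr1", p0).any()


class TestBlockLength:
    def test_target_segsites_arithmetic(self):
        assert choose_block_length(1_500, 100_000) == 100
        assert choose_block_length(150_000, 100_000) == 1

    def test_monomorphic_region_rejected(self):
        with pytest.raises(ValueError):
            choose_block_length(0, 100_000)

    def test_expected_length_from_per_site_theta(self):
        # theta per site 0.0058 -> 113 bases gives theta per block 0.66
        assert expected_block_length(0.0058) == 113


class TestBuildBlocks:
    def _variants(self, pos, counts, chrom="chr1"):
        return VariantTable(np.array([chrom] * len(pos), dtype=object),
                            np.asarray(pos), np.asarray(counts))

    def test_hand_enumerated_configs(self):
        # l = 10, window [0, 40): 4 blocks; 1-based SNP positions
        pos = [1, 5, 8, 12, 15, 25, 35, 36, 37, 38, 39, 40]
        # all subsets identical: per-site count 1 (singleton)
        counts = [[1, 1, 1, 1]] * 11 + [[2, 2, 2, 2]]
        v = self._variants(pos, counts)
        bs = build_blocks(v, full_mask("chr1", 40), test_point=20,
                          block_length_l=10, window=40)
        sub0 = bs.config_idx[bs.subset_id == 0]
        # block 0: pos 1,5,8 -> 3 singletons -> MORE; block 1: 12,15 -> 2
        # singletons; block 2: 25 -> 1; block 3: 35..39 -> 5 singletons ->
        # MORE plus pos 40 a doubleton
        assert sub0[0] == config_index(3, 0, 0)
        assert sub0[1] == config_index(2, 0, 0)
        assert sub0[2] == config_index(1, 0, 0)
        assert sub0[3] == config_index(3, 1, 0)

    def test_folding_caps_mixed_counts(self):
        # one block, alt counts {1, 1, 5} in subset 0 -> folded {1,1,1} -> MORE
        v = self._variants([2, 4, 6], [[1, 0, 0, 0], [1, 0, 0, 0], [5, 0, 0, 0]])
        bs = build_blocks(v, full_mask("chr1", 10), test_point=5,
                          block_length_l=10, window=10)
        assert bs.config_idx[bs.subset_id == 0][0] == config_index(3, 0, 0)
        # subsets with count 0 see an empty block
        assert bs.config_idx[bs.subset_id == 1][0] == config_index(0, 0, 0)

    def test_counts_of_six_are_invisible(self):
        v = self._variants([2], [[6, 6, 6, 6]])
        bs = build_blocks(v, full_mask("chr1", 10), test_point=5,
                          block_length_l=10, window=10)
        assert (bs.config_idx == 0).all()

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.integers(0, 6), min_size=1, max_size=15))
    def test_folding_is_involution_safe(self, alts):
        # replacing every count c by 6 - c leaves configurations unchanged
        pos = np.arange(1, len(alts) + 1) * 3
        a = np.array(alts)[:, None].repeat(4, axis=1)
        mask = full_mask("chr1", int(pos[-1]) + 5)
        kw = dict(test_point=pos[-1] // 2, block_length_l=7,
                  window=2 * int(pos[-1]) + 10)
        b1 = build_blocks(self._variants(pos, a), mask, **kw)
        b2 = build_blocks(self._variants(pos, 6 - a), mask, **kw)
        assert np.array_equal(b1.config_idx, b2.config_idx)

    def test_masked_gaps_do_not_split_blocks(self):
        # callable runs are concatenated across mask gaps
        mask = Intervals.from_records([("chr1", 0, 6), ("chr1", 100, 106)])
        v = self._variants([3, 103], [[1, 1, 1, 1]] * 2)
        bs = build_blocks(v, mask, test_point=50, block_length_l=12,
                          window=200)
        assert bs.n_blocks == 1
        assert bs.config_idx[bs.subset_id == 0][0] == config_index(2, 0, 0)

    def test_trailing_partial_block_discarded(self):
        v = self._variants([1], [[1, 1, 1, 1]])
        bs = build_blocks(v, full_mask("chr1", 25), test_point=12,
                          block_length_l=10, window=26)
        assert bs.n_blocks == 2

    def test_distance_is_midpoint_offset(self):
        v = self._variants([1], [[1, 1, 1, 1]])
        bs = build_blocks(v, full_mask("chr1", 40), test_point=20,
                          block_length_l=10, window=40)
        sub0 = bs.subset_id == 0
        assert np.allclose(bs.midpoint[sub0], [5, 15, 25, 35])
        assert np.allclose(bs.distance[sub0], [15, 5, 5, 15])


class TestTables:
    def test_tsv_roundtrip(self, tmp_path):
        from fusesweep.simulate import neutral_scenario, simulate_blockset

        bs = simulate_blockset(neutral_scenario(region_length=20_000), seed=3)
        path = tmp_path / "blocks.tsv"
        bs.to_tsv(path)
        back = BlockSet.from_tsv(path)
        assert np.array_equal(back.config_idx, bs.config_idx)
        assert np.array_equal(back.subset_id, bs.subset_id)
        assert back.block_length_l == bs.block_length_l
        assert back.test_point == bs.test_point

    def test_gff_exon_extraction(self, tmp_path):
        gff = tmp_path / "ann.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t500\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\texon\t11\t60\t.\t+\t.\tParent=g1\n"
            "chr1\tsrc\texon\t101\t160\t.\t+\t.\tParent=g1\n"
        )
        iv = exons_from_gff(gff)
        assert iv.contains("chr1", [10, 59, 60, 100, 159, 160]).tolist() == \
            [True, True, False, True, True, False]

    def test_variant_table_validation(self):
        with pytest.raises(ValueError):
            VariantTable(np.array(["c", "c"], dtype=object),
                         np.array([5, 5]), np.zeros((2, 4))).validate()
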
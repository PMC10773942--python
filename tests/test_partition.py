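"""Alignment-partition condensation: record semantics, invariants, I/O."""

import numpy as np
import pytest

from tesv.partition import (
    PairPartition,
    SegClass,
    condense_gvcf,
    partition_proportions,
    read_segments,
    read_snp_bed,
    write_partition,
)

from conftest import baseline_labels_from_gvcf, expand_partition_labels, make_partition


def write_test_gvcf(path, records, contigs={"chr1": 1000}):
    """records: list of (chrom, pos1, ref, alt, info) raw VCF fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End">\n')
        fh.write('##ALT=<ID=NON_REF,Description="block">\n')
        for c, n in contigs.items():
            fh.write(f"##contig=<ID={c},length={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, info in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}\n")


class TestRecordSemantics:
    def test_snp_record_contributes_alignable_base_and_snp(self, tmp_path):
        p = tmp_path / "a.gvcf"
        write_test_gvcf(
            p,
            [
                ("chr1", 1, "A", "<NON_REF>", "END=500"),
                ("chr1", 501, "A", "G", "."),
                ("chr1", 502, "A", "<NON_REF>", "END=1000"),
            ],
        )
        part = condense_gvcf(str(p))
        segs = part.segments["chr1"]
        assert [(s.seg_class, s.ref_len) for s in segs] == [(SegClass.ALIGNABLE, 1000)]
        assert list(part.snp_positions_ref["chr1"]) == [500]
        assert list(part.snp_positions_query["chr1"]) == [500]

    def test_large_one_sided_deletion_becomes_sv_ref(self, tmp_path):
        p = tmp_path / "a.gvcf"
        write_test_gvcf(
            p,
            [
                ("chr1", 1, "A", "<NON_REF>", "END=399"),
                ("chr1", 400, "A" * 121, "A", "."),
                ("chr1", 521, "A", "<NON_REF>", "END=1000"),
            ],
        )
        part = condense_gvcf(str(p))
        classes = [(s.seg_class, s.ref_len, s.query_len) for s in part.segments["chr1"]]
        assert classes == [
            (SegClass.ALIGNABLE, 400, 400),
            (SegClass.SV_REF, 120, 0),
            (SegClass.ALIGNABLE, 480, 480),
        ]

    def test_small_indel_absorbed_into_alignable(self, tmp_path):
        p = tmp_path / "a.gvcf"
        write_test_gvcf(
            p,
            [
                ("chr1", 1, "A", "<NON_REF>", "END=399"),
                ("chr1", 400, "A" * 31, "A", "."),  # 30 bp deletion: below floor
                ("chr1", 431, "A", "<NON_REF>", "END=1000"),
            ],
        )
        part = condense_gvcf(str(p))
        segs = part.segments["chr1"]
        assert [(s.seg_class, s.ref_len, s.query_len) for s in segs] == [
            (SegClass.ALIGNABLE, 1000, 970)
        ]

    def test_sv_floor_is_strict_51_qualifies_50_does_not(self, tmp_path):
        for extra, expect_sv in ((50, False), (51, True)):
            p = tmp_path / f"f{extra}.gvcf"
            write_test_gvcf(
                p,
                [
                    ("chr1", 1, "A", "<NON_REF>", "END=399"),
                    ("chr1", 400, "A" * (extra + 1), "A", "."),
                    ("chr1", 401 + extra, "A", "<NON_REF>", "END=1000"),
                ],
            )
            part = condense_gvcf(str(p))
            classes = {s.seg_class for s in part.segments["chr1"]}
            assert (SegClass.SV_REF in classes) == expect_sv

    def test_two_sided_record_becomes_unalignable_full_span(self, tmp_path):
        p = tmp_path / "a.gvcf"
        write_test_gvcf(
            p,
            [
                ("chr1", 1, "A", "<NON_REF>", "END=400"),
                ("chr1", 401, "G" * 60, "T" * 10, "."),
                ("chr1", 461, "A", "<NON_REF>", "END=1000"),
            ],
        )
        part = condense_gvcf(str(p))
        un = [s for s in part.segments["chr1"] if s.seg_class is SegClass.UNALIGNABLE]
        assert len(un) == 1
        assert (un[0].ref_len, un[0].query_len) == (60, 10)

    def test_equal_length_substitution_yields_per_base_snps(self, tmp_path):
        p = tmp_path / "a.gvcf"
        write_test_gvcf(
            p,
            [
                ("chr1", 1, "A", "<NON_REF>", "END=100"),
                ("chr1", 101, "ACA", "GCG", "."),
                ("chr1", 104, "A", "<NON_REF>", "END=1000"),
            ],
        )
        part = condense_gvcf(str(p))
        assert [(s.seg_class, s.ref_len) for s in part.segments["chr1"]] == [
            (SegClass.ALIGNABLE, 1000)
        ]
        assert list(part.snp_positions_ref["chr1"]) == [100, 102]

    def test_uncovered_gap_becomes_missing(self, tmp_path):
        p = tmp_path / "a.gvcf"
        write_test_gvcf(
            p,
            [
                ("chr1", 1, "A", "<NON_REF>", "END=300"),
                ("chr1", 601, "A", "<NON_REF>", "END=1000"),
            ],
        )
        part = condense_gvcf(str(p))
        assert [(s.seg_class, s.ref_len, s.query_len) for s in part.segments["chr1"]] == [
            (SegClass.ALIGNABLE, 300, 300),
            (SegClass.MISSING, 300, 0),
            (SegClass.ALIGNABLE, 400, 400),
        ]

    def test_unsorted_records_raise_naming_position(self, tmp_path):
        p = tmp_path / "a.gvcf"
        write_test_gvcf(
            p,
            [
                ("chr1", 1, "A", "<NON_REF>", "END=500"),
                ("chr1", 400, "A", "G", "."),
            ],
        )
        with pytest.raises(ValueError, match="chr1:400"):
            condense_gvcf(str(p))

    def test_multiallelic_record_rejected_listing_allele_lengths(self, tmp_path):
        p = tmp_path / "a.gvcf"
        write_test_gvcf(p, [("chr1", 1, "A", "G,T", ".")])
        with pytest.raises(ValueError, match="allele lengths"):
            condense_gvcf(str(p))


class TestProportions:
    def test_single_alignable_chromosome_is_fraction_one(self, uniform_partition):
        props = partition_proportions(uniform_partition, "ref")
        assert props["ALIGNABLE"] == (10_000, 1.0)
        assert props["SV_REF"] == (0, 0.0)
        assert props["UNALIGNABLE"] == (0, 0.0)

    def test_sv_fraction_arithmetic(self):
        part = make_partition(
            [
                (SegClass.ALIGNABLE, 4000, 4000),
                (SegClass.SV_REF, 2000, 0),
                (SegClass.ALIGNABLE, 4000, 4000),
            ]
        )
        props = partition_proportions(part, "ref")
        assert props["ALIGNABLE"] == (8000, 0.8)
        assert props["SV_REF"] == (2000, 0.2)

    def test_missing_pooled_with_unalignable(self):
        part = make_partition(
            [
                (SegClass.ALIGNABLE, 700, 700),
                (SegClass.MISSING, 200, 0),
                (SegClass.UNALIGNABLE, 100, 40),
            ]
        )
        props = partition_proportions(part, "ref")
        assert props["UNALIGNABLE"][0] == 300
        assert sum(frac for _, frac in props.values()) == pytest.approx(1.0)

    def test_bad_side_rejected(self, uniform_partition):
        with pytest.raises(ValueError, match="side"):
            partition_proportions(uniform_partition, "both")

    def test_fractions_match_truth_table_tallies(self, small_sim):
        """Planted-event bp, recomputed naively per base from the truth
        table, must equal the reported class fractions."""
        q = "q1"
        part = small_sim.partitions[q]
        ref_labels, _ = expand_partition_labels(part, "chr1")
        props = partition_proportions(part, "ref")
        for cls in ("ALIGNABLE", "SV_REF"):
            assert props[cls][0] == int((ref_labels == cls).sum())
        pooled = int(
            ((ref_labels == "UNALIGNABLE") | (ref_labels == "MISSING")).sum()
        )
        assert props["UNALIGNABLE"][0] == pooled


class TestInvariants:
    def test_conservation_and_validation(self, small_sim):
        for q, part in small_sim.partitions.items():
            part.validate()
            for side in ("ref", "query"):
                total = sum(
                    (s.ref_len if side == "ref" else s.query_len)
                    for segs in part.segments.values()
                    for s in segs
                )
                assert total == sum(part.chrom_lengths(side).values())

    def test_condense_is_idempotent_under_rewrite(self, small_sim, tmp_path):
        from tesv.simulate import write_gvcf

        write_gvcf(small_sim, "q1", tmp_path / "a.gvcf")
        p1 = condense_gvcf(str(tmp_path / "a.gvcf"), query_name="q1")
        p2 = condense_gvcf(str(tmp_path / "a.gvcf"), query_name="q1")
        assert p1.segments == p2.segments

    def test_segment_tsv_round_trip(self, small_sim, tmp_path):
        part = small_sim.partitions["q1"]
        paths = write_partition(part, tmp_path)
        back = read_segments(
            paths["segments"],
            comparison_id=part.comparison_id,
            snps_ref=read_snp_bed(paths["snps_ref"]),
            snps_query=read_snp_bed(paths["snps_query"]),
        )
        assert back.segments == part.segments
        assert back.chrom_lengths_ref == part.chrom_lengths_ref
        for chrom in part.snp_positions_ref:
            assert np.array_equal(
                back.snp_positions_ref[chrom], part.snp_positions_ref[chrom]
            )

    def test_per_base_oracle_agreement(self, small_sim, tmp_path):
        """Naive per-base labeling from raw GVCF records agrees with the
        condensed segments at every base."""
        from tesv.simulate import write_gvcf

        gvcf = tmp_path / "a.gvcf"
        write_gvcf(small_sim, "q1", gvcf)
        part = condense_gvcf(str(gvcf), query_name="q1")
        oracle = baseline_labels_from_gvcf(str(gvcf))
        for chrom, (ref_exp, q_exp, snps_exp) in oracle.items():
            ref_got, q_got = expand_partition_labels(part, chrom)
            assert np.array_equal(ref_got, ref_exp)
            assert np.array_equal(q_got, q_exp)
            assert list(part.snp_positions_ref[chrom]) == snps_exp
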
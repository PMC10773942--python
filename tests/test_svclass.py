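"""Five-way SV categorisation, indel direction, TE-SV links, bp tallies."""

from fractions import Fraction

import numpy as np
import pytest

from tesv.annotations import TEAnnotation
from tesv.svclass import (
    IndelCall,
    SVCategory,
    SVRecord,
    call_indel_direction,
    classify_sv,
    classify_svs,
    extract_svs,
    link_polymorphic_tes,
    tally_indel_bp,
)

from conftest import bruteforce_sv_category


def te(te_id, start, end, chrom="chr1", method="structural", superfamily="RLG"):
    return TEAnnotation(
        te_id=te_id, chrom=chrom, start=start, end=end, strand="+",
        superfamily=superfamily, family=f"{superfamily}_fam", method=method,
    )


def sv(start, end, lineage="ref", chrom="chr1"):
    return SVRecord(
        sv_id=f"sv_{chrom}_{start}", comparison_id="ref_vs_q", lineage=lineage,
        chrom=chrom, start=start, end=end,
    )


class TestCategories:
    def test_no_te_overlap(self):
        svc = classify_sv(sv(1000, 2000), [te("t1", 5000, 9000)])
        assert svc.category is SVCategory.NO_TE
        assert svc.full_te_ids == () and svc.partial_te_ids == ()

    def test_partial_overlap_only_is_incomplete(self):
        # SV covers the first 2 kb of a 6 kb TE
        svc = classify_sv(sv(0, 10_000), [te("t1", 8000, 14_000)])
        assert svc.category is SVCategory.INCOMPLETE_TE
        assert svc.partial_te_ids == ("t1",)

    def test_te_eq_sv_mutual_95(self):
        # 5000 bp SV entirely containing a 4900 bp TE: TE-in-SV 1.0, SV covered 0.98
        svc = classify_sv(sv(0, 5000), [te("t1", 50, 4950)])
        assert svc.category is SVCategory.TE_EQ_SV
        assert svc.full_te_ids == ("t1",)

    def test_multi_te(self):
        tes = [te(f"t{i}", 1000 + i * 5000, 5000 + i * 5000) for i in range(3)]
        svc = classify_sv(sv(0, 20_000), tes)
        assert svc.category is SVCategory.MULTI_TE
        assert len(svc.full_te_ids) == 3

    def test_te_within_sv(self):
        svc = classify_sv(sv(0, 20_000), [te("t1", 7000, 13_000)])
        assert svc.category is SVCategory.TE_WITHIN_SV

    def test_sv_side_test_is_strict_at_exactly_95(self):
        # TE covers exactly 95.000% of the SV: strict > fails -> TE_WITHIN_SV
        svc = classify_sv(sv(0, 10_000), [te("t1", 250, 9750)])
        assert Fraction(9500, 10_000) == Fraction(19, 20)
        assert svc.category is SVCategory.TE_WITHIN_SV

    def test_te_side_test_is_strict_at_exactly_95(self):
        # TE has exactly 95.000% of its bp inside the SV: not a full TE
        svc = classify_sv(sv(0, 9500), [te("t1", 0, 10_000)])
        assert svc.category is SVCategory.INCOMPLETE_TE

    def test_dominant_te_with_nested_fragment_is_te_eq_sv(self):
        # a small contained homology fragment must not flip TE=SV to MULTI
        tes = [te("host", 10, 4990), te("frag", 1000, 1400, method="homology")]
        svc = classify_sv(sv(0, 5000), tes)
        assert svc.category is SVCategory.TE_EQ_SV

    def test_wrong_lineage_te_set_rejected(self):
        with pytest.raises(ValueError, match="lineage"):
            classify_sv(sv(0, 5000, lineage="ref"), [], te_lineage="query")

    def test_monotone_flip_te_eq_to_te_within_only(self):
        """Shrinking the contained TE below 95% SV coverage flips
        TE_EQ_SV -> TE_WITHIN_SV and never any other transition."""
        seen = []
        for te_len in range(9700, 9000, -100):
            svc = classify_sv(sv(0, 10_000), [te("t1", 0, te_len)])
            seen.append(svc.category)
        assert set(seen) == {SVCategory.TE_EQ_SV, SVCategory.TE_WITHIN_SV}
        flip = seen.index(SVCategory.TE_WITHIN_SV)
        assert all(c is SVCategory.TE_EQ_SV for c in seen[:flip])
        assert all(c is SVCategory.TE_WITHIN_SV for c in seen[flip:])

    @pytest.mark.parametrize("seed", range(8))
    def test_categories_match_bruteforce_on_random_layouts(self, seed):
        """The five categories are mutually exclusive, exhaustive, and
        identical to an enumeration-based classifier."""
        rng = np.random.default_rng(seed)
        tes = []
        for i in range(60):
            start = int(rng.integers(0, 80_000))
            tes.append(te(f"t{i}", start, start + int(rng.integers(100, 9000))))
        for j in range(40):
            start = int(rng.integers(0, 80_000))
            record = sv(start, start + int(rng.integers(51, 15_000)) + 1)
            svc = classify_sv(record, tes)
            assert svc.category.value == bruteforce_sv_category(
                record.start, record.end, tes
            )


class TestDirectionAndLinks:
    @pytest.mark.parametrize(
        "category,expected",
        [
            (SVCategory.TE_EQ_SV, IndelCall.PUTATIVE_INSERTION),
            (SVCategory.INCOMPLETE_TE, IndelCall.PUTATIVE_DELETION),
            (SVCategory.MULTI_TE, IndelCall.PUTATIVE_DELETION),
            (SVCategory.TE_WITHIN_SV, IndelCall.PUTATIVE_DELETION),
            (SVCategory.NO_TE, IndelCall.UNASSIGNED),
        ],
    )
    def test_direction_mapping(self, category, expected):
        from tesv.svclass import SVClass

        svc = SVClass(
            sv_record=sv(0, 1000), category=category,
            full_te_ids=(), partial_te_ids=(), te_bp_in_sv=0,
        )
        assert call_indel_direction(svc).indel_call is expected

    def test_te_fully_inside_one_sv_links_to_it(self):
        svcs = classify_svs([sv(0, 6000)], [te("t1", 100, 5950)])
        links = link_polymorphic_tes([te("t1", 100, 5950)], svcs)
        assert links["t1"][0] == svcs[0].sv_id
        assert links["t1"][1] is SVCategory.TE_EQ_SV

    def test_te_split_between_two_svs_is_unlinked(self):
        tes = [te("t1", 4000, 14_000)]  # 60% in first SV, 40% in second
        svcs = classify_svs([sv(0, 10_000), sv(10_000, 20_000)], tes)
        links = link_polymorphic_tes(tes, svcs)
        assert links["t1"] == (None, None)


class TestTally:
    def make_classified(self):
        tes = [te("t1", 0, 1000), te("t2", 1100, 2000), te("t3", 2100, 4000)]
        return classify_svs([sv(0, 1000), sv(1050, 4050)], tes)

    def test_insertion_and_deletion_bp(self):
        svcs = self.make_classified()
        assert [s.category for s in svcs] == [SVCategory.TE_EQ_SV, SVCategory.MULTI_TE]
        ins_bp, del_bp, counts = tally_indel_bp(svcs)
        assert (ins_bp, del_bp) == (1000, 3000)
        assert counts["TE_EQ_SV"] == 1 and counts["MULTI_TE"] == 1

    def test_empty_region_set_gives_zero(self):
        ins_bp, del_bp, counts = tally_indel_bp(self.make_classified(), regions=[])
        assert (ins_bp, del_bp) == (0, 0)
        assert sum(counts.values()) == 0

    def test_region_membership_requires_half_of_sv(self):
        svcs = self.make_classified()
        # first SV [0,1000) is 100% inside; second [1050,4050) only ~31%
        ins_bp, del_bp, _ = tally_indel_bp(svcs, regions=[("chr1", 0, 2000)])
        assert (ins_bp, del_bp) == (1000, 0)
        # extend region to cover >= 50% of the second SV
        ins_bp, del_bp, _ = tally_indel_bp(svcs, regions=[("chr1", 0, 2550)])
        assert (ins_bp, del_bp) == (1000, 3000)


class TestExtract:
    def test_svs_extracted_from_both_lineages(self, small_sim):
        part = small_sim.partitions["q1"]
        both = extract_svs(part)
        refs = extract_svs(part, lineage="ref")
        queries = extract_svs(part, lineage="query")
        assert len(both) == len(refs) + len(queries)
        assert all(s.length > 50 for s in both)
        # coordinates sit on the carrying lineage
        for s in queries:
            assert s.lineage == "query"

    def test_planted_events_recover_expected_categories(self, small_sim):
        """Every planted insertion/deletion classifies to its expected
        category and direction in the comparison that carries it."""
        sim = small_sim
        cfg = sim.config
        by_key = {}
        for q in cfg.query_names:
            part = sim.partitions[q]
            for lin in ("ref", "query"):
                tes = sim.tes_by_genome["ref" if lin == "ref" else q]
                for s in classify_svs(extract_svs(part, lineage=lin), tes):
                    by_key[(q, lin, s.sv_record.chrom, s.sv_record.start, s.sv_record.end)] = s
        n_checked = 0
        for ev in sim.truth:
            if ev.expected_sv_category is None:
                continue
            comps = cfg.query_names if ev.lineage == "ref" else [ev.lineage]
            for q in comps:
                s = by_key.get((q, ev.sv_lineage, ev.chrom, ev.sv_start, ev.sv_end))
                assert s is not None, ev.event_id
                assert s.category is ev.expected_sv_category, ev.event_id
                assert s.indel_call is ev.expected_indel_call, ev.event_id
                n_checked += 1
        assert n_checked > 0
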
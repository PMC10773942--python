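"""Annotation QC filtering: prefilter, dedupe, overlap-rule soundness."""

import numpy as np
import pytest

from tesv.annotations import (
    Removal,
    RemovalReason,
    TEAnnotation,
    dedupe_identical,
    filter_annotations,
    prefilter,
    read_te_gff3,
    resolve_overlaps,
    write_te_gff3,
)

from conftest import check_filter_rules


def te(te_id, start, end, method="structural", superfamily="RLG", family=None, chrom="chr1"):
    return TEAnnotation(
        te_id=te_id,
        chrom=chrom,
        start=start,
        end=end,
        strand="+",
        superfamily=superfamily,
        family=family or f"{superfamily}_fam",
        method=method,
    )


class TestPrefilter:
    def test_helitron_and_non_te_and_subfeatures_removed(self):
        annos = [
            te("ok1", 1000, 6000),
            TEAnnotation("hel1", "chr1", 7000, 8000, "+", "HELITRON", "hel_fam", "structural"),
            TEAnnotation("knob1", "chr1", 9000, 9500, "+", "NON_TE", "knob180", "homology"),
            TEAnnotation(
                "ltr1", "chr1", 1000, 1350, "+", "RLG", "RLG_fam", "structural",
                feature_type="long_terminal_repeat",
            ),
        ]
        kept, removed = prefilter(annos, drop_families=[])
        assert [t.te_id for t in kept] == ["ok1"]
        reasons = {r.te_id: r.reason for r in removed}
        assert reasons == {
            "hel1": RemovalReason.HELITRON,
            "knob1": RemovalReason.NON_TE,
            "ltr1": RemovalReason.LTR_SUBFEATURE,
        }

    def test_listed_family_removed(self):
        annos = [
            te("bad", 100, 400, method="homology", superfamily="DTA", family="DTA_ZM00081_consensus"),
            te("good", 1000, 1400, method="homology", superfamily="DTA"),
        ]
        kept, removed = prefilter(annos)
        assert [t.te_id for t in kept] == ["good"]
        assert removed[0].reason is RemovalReason.DROPPED_FAMILY

    def test_full_length_structural_retained_unchanged(self):
        annos = [te("rlg", 10, 9000)]
        kept, removed = prefilter(annos)
        assert kept == annos and removed == []


class TestDedupe:
    def test_structural_preferred_over_homology(self):
        a = te("s1", 100, 500, method="structural")
        b = te("h1", 100, 500, method="homology")
        kept, removed = dedupe_identical([b, a])
        assert [t.te_id for t in kept] == ["s1"]
        assert removed[0].te_id == "h1" and removed[0].reason is RemovalReason.DUPLICATE

    def test_same_method_tie_deterministic_under_seed(self):
        dups = [te("h1", 100, 500, method="homology"), te("h2", 100, 500, method="homology")]
        first = dedupe_identical(dups, seed=7)[0]
        for _ in range(3):
            assert dedupe_identical(dups, seed=7)[0] == first
        assert len(first) == 1

    def test_no_duplicates_identity(self):
        annos = [te("a", 0, 100), te("b", 200, 300)]
        kept, removed = dedupe_identical(annos)
        assert kept == annos and removed == []


class TestOverlapRules:
    def test_boundary_rule_inclusive_at_5bp(self):
        s = te("s1", 1000, 9000, method="structural")
        h_near = te("h1", 1003, 20000, method="homology")  # start within 5 bp of s start
        h_far = te("h2", 1006 + 9000, 30000, method="homology")
        kept, removed = resolve_overlaps([s, h_near, h_far])
        ids = {t.te_id for t in kept}
        assert "h1" not in ids and "s1" in ids and "h2" in ids
        r = {x.te_id: x for x in removed}
        assert r["h1"].reason is RemovalReason.BOUNDARY_5BP
        assert r["h1"].partner_id == "s1"

    def test_boundary_rule_structural_pair_keeps_larger(self):
        big = te("big", 1000, 10000, method="structural")
        small = te("small", 1002, 5000, method="structural")
        kept, removed = resolve_overlaps([small, big])
        assert [t.te_id for t in kept] == ["big"]
        assert removed[0].reason is RemovalReason.BOUNDARY_5BP

    def test_hh_overlap_removes_both_mutual_violators(self):
        # 15% mutual overlap: both removed under the literal reading
        a = te("h1", 0, 1000, method="homology")
        b = te("h2", 850, 1850, method="homology")
        kept, removed = resolve_overlaps([a, b])
        assert kept == []
        assert {x.reason for x in removed} == {RemovalReason.HH_OVERLAP}

    def test_hh_keep_longer_alternative(self):
        a = te("h1", 0, 1000, method="homology")
        b = te("h2", 850, 2050, method="homology")
        kept, _ = resolve_overlaps([a, b], hh_keep_longer=True)
        assert [t.te_id for t in kept] == ["h2"]

    def test_hh_one_sided_violation_drops_only_violator(self):
        # overlap 120 bp: 12% of the short one, 2.4% of the long one
        short = te("h1", 0, 1000, method="homology")
        long_ = te("h2", 880, 5880, method="homology")
        kept, removed = resolve_overlaps([short, long_])
        assert [t.te_id for t in kept] == ["h2"]
        assert removed[0].te_id == "h1"

    def test_hs_contained_homology_retained(self):
        s = te("s1", 1000, 9000, method="structural")
        nested = te("h1", 2000, 3000, method="homology")
        kept, _ = resolve_overlaps([s, nested])
        assert {t.te_id for t in kept} == {"s1", "h1"}

    def test_hs_partial_overlap_removed(self):
        s = te("s1", 1000, 9000, method="structural")
        h = te("h1", 8500, 10500, method="homology")  # 25% of own length inside s
        kept, removed = resolve_overlaps([s, h])
        assert [t.te_id for t in kept] == ["s1"]
        assert removed[0].reason is RemovalReason.HS_OVERLAP

    def test_ss_class_ii_preferred_over_longer_class_i(self):
        c1 = te("rlg", 1000, 6000, method="structural", superfamily="RLG")
        c2 = te("dta", 5200, 6000 + 200, method="structural", superfamily="DTA")
        kept, removed = resolve_overlaps([c1, c2], boundary_bp=0)
        assert [t.te_id for t in kept] == ["dta"]
        assert removed[0].reason is RemovalReason.SS_OVERLAP

    def test_ss_nested_structural_exempt(self):
        outer = te("outer", 1000, 11000, method="structural")
        inner = te("inner", 3000, 5000, method="structural")
        kept, _ = resolve_overlaps([outer, inner])
        assert {t.te_id for t in kept} == {"outer", "inner"}

    def test_non_overlapping_set_unchanged(self):
        annos = [te("a", 0, 1000), te("b", 2000, 3000, method="homology"), te("c", 4000, 9000)]
        kept, removed = resolve_overlaps(annos)
        assert sorted(t.te_id for t in kept) == ["a", "b", "c"] and removed == []


class TestFilterProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_no_rule_violations_after_filtering_random_sets(self, seed):
        """All-pairs brute-force checker finds zero violations among the
        retained annotations of adversarial random layouts."""
        rng = np.random.default_rng(seed)
        annos = []
        for i in range(300):
            start = int(rng.integers(0, 200_000))
            length = int(rng.integers(80, 8000))
            method = "structural" if rng.random() < 0.4 else "homology"
            sf = ["RLG", "RLC", "DTA", "DTT"][int(rng.integers(4))]
            annos.append(te(f"t{i}", start, start + length, method=method, superfamily=sf))
        kept, removed = resolve_overlaps(annos, seed=seed)
        assert check_filter_rules(kept) == []
        # partition property: kept and removed split the input exactly
        kept_ids = {t.te_id for t in kept}
        removed_ids = {r.te_id for r in removed}
        assert kept_ids | removed_ids == {t.te_id for t in annos}
        assert kept_ids & removed_ids == set()

    def test_filtering_deterministic_under_seed(self):
        rng = np.random.default_rng(99)
        annos = []
        for i in range(150):
            start = int(rng.integers(0, 50_000))
            annos.append(
                te(
                    f"t{i}",
                    start,
                    start + int(rng.integers(100, 4000)),
                    method="structural" if rng.random() < 0.5 else "homology",
                )
            )
        k1, r1 = resolve_overlaps(annos, seed=5)
        k2, r2 = resolve_overlaps(annos, seed=5)
        assert k1 == k2
        assert [(x.te_id, x.reason) for x in r1] == [(x.te_id, x.reason) for x in r2]


class TestGFFRoundTrip:
    def test_te_gff3_round_trip(self, tmp_path):
        annos = [
            TEAnnotation("a", "chr1", 100, 9000, "+", "RLG", "RLG_huck", "structural", 0.97),
            TEAnnotation("b", "chr1", 10000, 10400, "-", "DTA", "DTA_hbr", "homology"),
        ]
        path = tmp_path / "te.gff3"
        write_te_gff3(annos, path)
        back = read_te_gff3(path)
        assert [(t.te_id, t.start, t.end, t.superfamily, t.method) for t in back] == [
            (t.te_id, t.start, t.end, t.superfamily, t.method) for t in annos
        ]
        assert back[0].ltr_identity == pytest.approx(0.97)

    def test_panedta_classification_attributes_parse(self, tmp_path):
        path = tmp_path / "pan.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tEDTA\tCopia_LTR_retrotransposon\t101\t8000\t.\t+\t.\t"
            "ID=TE1;Name=RLC_opie;Classification=LTR/Copia;Method=structural;Identity=0.99\n"
            "chr1\tEDTA\thelitron\t9001\t9800\t.\t+\t.\t"
            "ID=TE2;Name=DHH_x;Classification=DNA/Helitron;Method=homology\n"
        )
        back = read_te_gff3(path)
        assert back[0].superfamily == "RLC" and back[0].start == 100
        assert back[1].superfamily == "HELITRON"
        kept, removed = filter_annotations(back)
        assert [t.te_id for t in kept] == ["TE1"]
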
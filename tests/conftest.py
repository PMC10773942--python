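"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's interval arithmetic: they
expand everything to per-base label arrays (small genomes only) or
enumerate all pairs, so agreement with the fast implementations is a
meaningful check.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from tesv.partition import SegClass


# ---------------------------------------------------------------------------
# per-base oracles
# ---------------------------------------------------------------------------


def baseline_labels_from_gvcf(gvcf_path: str, min_sv_len: int = 50):
    """Naive per-base labeling straight from raw GVCF text records.

    Returns chrom -> (ref_labels, query_labels, snp_ref_positions).
    Label arrays hold SegClass values per base; this reimplements the
    condensation semantics base by base without any segment or merging
    machinery.
    """
    contigs: dict[str, int] = {}
    records: dict[str, list[tuple[int, str, str, int | None]]] = {}
    with open(gvcf_path) as fh:
        for line in fh:
            if line.startswith("##contig"):
                inner = line.strip()[len("##contig=<") : -1]
                kv = dict(p.split("=", 1) for p in inner.split(","))
                contigs[kv["ID"]] = int(kv["length"])
                continue
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos, ref, alt, info = f[0], int(f[1]) - 1, f[3], f[4], f[7]
            end = None
            for item in info.split(";"):
                if item.startswith("END="):
                    end = int(item[4:])
            records.setdefault(chrom, []).append((pos, ref, alt, end))

    out = {}
    for chrom, clen in contigs.items():
        ref_lab = np.full(clen, SegClass.MISSING.value, dtype=object)
        q_lab = []  # label per query base, in order
        snps = []
        for pos, ref, alt, end in sorted(records.get(chrom, [])):
            if alt in ("<NON_REF>", "."):
                span = (end if end is not None else pos + len(ref)) - pos
                ref_lab[pos : pos + span] = SegClass.ALIGNABLE.value
                q_lab += [SegClass.ALIGNABLE.value] * span
                continue
            if len(ref) == len(alt):
                for i, (x, y) in enumerate(zip(ref, alt)):
                    if x != y:
                        snps.append(pos + i)
                ref_lab[pos : pos + len(ref)] = SegClass.ALIGNABLE.value
                q_lab += [SegClass.ALIGNABLE.value] * len(alt)
                continue
            # strip common prefix
            p = 0
            while p < min(len(ref), len(alt)) and ref[p] == alt[p]:
                p += 1
            r_extra, a_extra = len(ref) - p, len(alt) - p
            if r_extra > 0 and a_extra > 0:
                ref_lab[pos : pos + len(ref)] = SegClass.UNALIGNABLE.value
                q_lab += [SegClass.UNALIGNABLE.value] * len(alt)
            elif r_extra > 0:
                ref_lab[pos : pos + p] = SegClass.ALIGNABLE.value
                q_lab += [SegClass.ALIGNABLE.value] * p
                cls = SegClass.SV_REF if r_extra > min_sv_len else SegClass.ALIGNABLE
                ref_lab[pos + p : pos + len(ref)] = cls.value
            else:
                ref_lab[pos : pos + p] = SegClass.ALIGNABLE.value
                q_lab += [SegClass.ALIGNABLE.value] * p
                cls = SegClass.SV_QUERY if a_extra > min_sv_len else SegClass.ALIGNABLE
                q_lab += [cls.value] * a_extra
        out[chrom] = (ref_lab, np.asarray(q_lab, dtype=object), sorted(snps))
    return out


def expand_partition_labels(partition, chrom: str):
    """Per-base label arrays (ref, query) from a partition's segments."""
    segs = partition.segments[chrom]
    ref = np.empty(partition.chrom_lengths_ref[chrom], dtype=object)
    q = np.empty(partition.chrom_lengths_query[chrom], dtype=object)
    for s in segs:
        ref[s.ref_start : s.ref_end] = s.seg_class.value
        q[s.query_start : s.query_end] = s.seg_class.value
    return ref, q


def bruteforce_feature_status(
    intervals, ref_labels, sv_class: str, threshold=Fraction(19, 20)
):
    """Statuses by naive per-base counting over a label array."""
    alignable = sv = total = 0
    for a, b in intervals:
        for x in range(a, b):
            total += 1
            if ref_labels[x] == SegClass.ALIGNABLE.value:
                alignable += 1
            elif ref_labels[x] == sv_class:
                sv += 1
    if Fraction(alignable, total) >= threshold:
        return "SHARED"
    if Fraction(sv, total) >= threshold:
        return "POLYMORPHIC"
    return "AMBIGUOUS"


def bruteforce_sv_category(sv_start, sv_end, tes, threshold=Fraction(19, 20)):
    """Five-way SV category by exhaustive per-TE fraction enumeration."""
    sv_len = sv_end - sv_start
    overlapping = []
    for t in tes:
        ov = min(t.end, sv_end) - max(t.start, sv_start)
        if ov > 0:
            overlapping.append((t, ov))
    if not overlapping:
        return "NO_TE"
    full = [(t, ov) for t, ov in overlapping if Fraction(ov, t.end - t.start) > threshold]
    if not full:
        return "INCOMPLETE_TE"
    if any(Fraction(ov, sv_len) > threshold for _, ov in full):
        return "TE_EQ_SV"
    if len(full) >= 2:
        return "MULTI_TE"
    return "TE_WITHIN_SV"


def check_filter_rules(kept, boundary_bp=5, hh_frac=0.10, hs_frac=0.05):
    """All-pairs checker: returns the list of rule violations among kept
    annotations (empty list = sound)."""
    violations = []
    for i, a in enumerate(kept):
        for b in kept:
            if a is b or a.chrom != b.chrom:
                continue
            ov = max(0, min(a.end, b.end) - max(a.start, b.start))
            contained = b.start <= a.start and a.end <= b.end
            if b.is_structural:
                near = any(
                    abs(x - y) <= boundary_bp
                    for x in (a.start, a.end)
                    for y in (b.start, b.end)
                )
                if near:
                    violations.append(("BOUNDARY", a.te_id, b.te_id))
            if not a.is_structural and not b.is_structural and ov > hh_frac * (a.end - a.start):
                violations.append(("HH", a.te_id, b.te_id))
            if not a.is_structural and b.is_structural:
                if ov > hs_frac * (a.end - a.start) and not contained:
                    violations.append(("HS", a.te_id, b.te_id))
            if a.is_structural and b.is_structural:
                if ov > 0 and not contained and not (a.start <= b.start and b.end <= a.end):
                    violations.append(("SS", a.te_id, b.te_id))
    return violations


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_sim():
    """A 200 kb, 2-query scenario with every event type planted."""
    from tesv.simulate import SimConfig, simulate

    cfg = SimConfig(
        seed=3,
        genome_bp=200_000,
        n_queries=2,
        n_te_insertions=4,
        n_del_single_te=2,
        n_del_multi_te=2,
        n_del_internal_te=2,
        n_del_non_te=2,
        n_small_indels=3,
        n_unalignable=2,
        n_missing=1,
    )
    return simulate(cfg)


@pytest.fixture()
def uniform_partition():
    """A single fully-alignable 10 kb chromosome."""
    from tesv.partition import PairPartition, SegClass, Segment

    seg = Segment("chr1", 0, 10_000, "chr1", 0, 10_000, SegClass.ALIGNABLE)
    return PairPartition(
        comparison_id="ref_vs_q",
        segments={"chr1": [seg]},
        snp_positions_ref={"chr1": np.asarray([], dtype=np.int64)},
        snp_positions_query={"chr1": np.asarray([], dtype=np.int64)},
        chrom_lengths_ref={"chr1": 10_000},
        chrom_lengths_query={"chr1": 10_000},
    )


def make_partition(segment_spec, comparison_id="ref_vs_q", snps_ref=None):
    """Build a partition from (class, ref_len, query_len) tuples on one
    chromosome, with optional reference SNP positions."""
    from tesv.partition import PairPartition, _ChromBuilder

    b = _ChromBuilder("chr1", "chr1")
    for cls, rl, ql in segment_spec:
        b.add(cls, rl, ql)
    snps = np.asarray(sorted(snps_ref or []), dtype=np.int64)
    return PairPartition(
        comparison_id=comparison_id,
        segments={"chr1": b.segments},
        snp_positions_ref={"chr1": snps},
        snp_positions_query={"chr1": snps.copy()},
        chrom_lengths_ref={"chr1": b.ref_pos},
        chrom_lengths_query={"chr1": b.query_pos},
    )
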
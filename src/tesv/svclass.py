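"""Classify structural variants by their transposable-element content.

Each structural variant (a > 50 bp one-sided indel: sequence present in
one genome, 0 bp in the other) is categorised by the TE annotations of
the genome that carries the sequence:

* ``NO_TE``         — no overlapping TE at all;
* ``INCOMPLETE_TE`` — TEs overlap, but none has > 95% of its own length
  inside the SV (deletions clipping a TE edge or its interior);
* ``TE_EQ_SV``      — a single TE and the SV mutually cover > 95% of
  each other (a simple TE presence/absence locus);
* ``MULTI_TE``      — two or more full-length TEs inside the SV;
* ``TE_WITHIN_SV``  — exactly one full-length TE covering < 95% of the SV.

``TE = SV`` events are putative TE insertions; the other TE-containing
categories are putative deletions of ancestral sequence; ``NO_TE`` SVs
are left unassigned.  Both 95% tests are strict (exactly 95.000% does
not qualify) and evaluated in exact integer arithmetic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd

from tesv.annotations import TEAnnotation, merge_intervals
from tesv.partition import PairPartition, SegClass


class SVCategory(str, enum.Enum):
    NO_TE = "NO_TE"
    INCOMPLETE_TE = "INCOMPLETE_TE"
    TE_EQ_SV = "TE_EQ_SV"
    MULTI_TE = "MULTI_TE"
    TE_WITHIN_SV = "TE_WITHIN_SV"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class IndelCall(str, enum.Enum):
    PUTATIVE_INSERTION = "PUTATIVE_INSERTION"
    PUTATIVE_DELETION = "PUTATIVE_DELETION"
    UNASSIGNED = "UNASSIGNED"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class SVRecord:
    """One structural variant on the coordinates of its carrying lineage.

    ``anchor_start``/``anchor_end`` locate the SV on the *reference*
    coordinate system regardless of lineage: for reference-carried SVs
    they equal the SV span, for query-carried SVs they are the
    zero-length insertion point.  Region restrictions (SNP-depleted
    regions are detected on reference coordinates) use the anchor.
    """

    sv_id: str
    comparison_id: str
    lineage: str  # genome carrying the sequence: "ref" | "query"
    chrom: str
    start: int
    end: int
    anchor_start: int = -1
    anchor_end: int = -1

    def __post_init__(self):
        if self.length <= 50:
            raise ValueError(
                f"{self.sv_id}: SV length {self.length} must exceed 50 bp"
            )
        if self.anchor_start < 0:
            anchor = (self.start, self.end) if self.lineage == "ref" else (self.start, self.start)
            object.__setattr__(self, "anchor_start", anchor[0])
            object.__setattr__(self, "anchor_end", anchor[1])

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SVClass:
    sv_record: SVRecord
    category: SVCategory
    full_te_ids: tuple[str, ...]
    partial_te_ids: tuple[str, ...]
    te_bp_in_sv: int
    indel_call: IndelCall = IndelCall.UNASSIGNED

    @property
    def sv_id(self) -> str:
        return self.sv_record.sv_id


def extract_svs(partition: PairPartition, lineage: str | None = None) -> list[SVRecord]:
    """Pull SV records (> 50 bp one-sided segments) out of a partition.

    Coordinates are on the carrying lineage's genome.  ``lineage`` limits
    extraction to one side; default is both.
    """
    out = []
    for chrom_ref, segs in partition.segments.items():
        for s in segs:
            if s.seg_class is SegClass.SV_REF and lineage in (None, "ref"):
                out.append(
                    SVRecord(
                        sv_id=f"{partition.comparison_id}:ref:{s.chrom_ref}:{s.ref_start}-{s.ref_end}",
                        comparison_id=partition.comparison_id,
                        lineage="ref",
                        chrom=s.chrom_ref,
                        start=s.ref_start,
                        end=s.ref_end,
                    )
                )
            elif s.seg_class is SegClass.SV_QUERY and lineage in (None, "query"):
                out.append(
                    SVRecord(
                        sv_id=f"{partition.comparison_id}:query:{s.chrom_query}:{s.query_start}-{s.query_end}",
                        comparison_id=partition.comparison_id,
                        lineage="query",
                        chrom=s.chrom_query,
                        start=s.query_start,
                        end=s.query_end,
                        anchor_start=s.ref_start,
                        anchor_end=s.ref_end,
                    )
                )
    return out


_STRICT_95 = Fraction(19, 20)


def classify_sv(
    sv: SVRecord,
    tes: list[TEAnnotation],
    threshold: float | Fraction = _STRICT_95,
    te_lineage: str | None = None,
) -> SVClass:
    """Assign one SV its five-way TE-content category.

    ``tes`` must be the (filtered) annotation set of the same lineage as
    the SV; pass ``te_lineage`` to enable the check.  Decision order:
    no overlap -> NO_TE; no full TE -> INCOMPLETE_TE; a full TE covering
    > 95% of the SV -> TE_EQ_SV; >= 2 full TEs -> MULTI_TE; else
    TE_WITHIN_SV.
    """
    if te_lineage is not None and te_lineage != sv.lineage:
        raise ValueError(
            f"TE annotations are from lineage {te_lineage!r} but SV {sv.sv_id} "
            f"is on lineage {sv.lineage!r}"
        )
    thr = threshold if isinstance(threshold, Fraction) else Fraction(str(threshold))
    full: list[tuple[int, TEAnnotation]] = []  # (overlap bp, te)
    partial: list[TEAnnotation] = []
    te_intervals = []
    for t in tes:
        if t.chrom != sv.chrom:
            continue
        ov = min(t.end, sv.end) - max(t.start, sv.start)
        if ov <= 0:
            continue
        te_intervals.append((max(t.start, sv.start), min(t.end, sv.end)))
        if Fraction(ov, t.length) > thr:
            full.append((ov, t))
        else:
            partial.append(t)
    te_bp = sum(b - a for a, b in merge_intervals(te_intervals))
    full.sort(key=lambda x: (-x[0], x[1].te_id))
    full_ids = tuple(t.te_id for _, t in full)
    partial_ids = tuple(t.te_id for t in partial)

    if not full and not partial:
        category = SVCategory.NO_TE
    elif not full:
        category = SVCategory.INCOMPLETE_TE
    elif any(Fraction(ov, sv.length) > thr for ov, _ in full):
        # the single best TE covers > 95% of the SV
        category = SVCategory.TE_EQ_SV
    elif len(full) >= 2:
        category = SVCategory.MULTI_TE
    else:
        category = SVCategory.TE_WITHIN_SV
    return SVClass(
        sv_record=sv,
        category=category,
        full_te_ids=full_ids,
        partial_te_ids=partial_ids,
        te_bp_in_sv=te_bp,
    )


_DIRECTION = {
    SVCategory.TE_EQ_SV: IndelCall.PUTATIVE_INSERTION,
    SVCategory.INCOMPLETE_TE: IndelCall.PUTATIVE_DELETION,
    SVCategory.MULTI_TE: IndelCall.PUTATIVE_DELETION,
    SVCategory.TE_WITHIN_SV: IndelCall.PUTATIVE_DELETION,
    SVCategory.NO_TE: IndelCall.UNASSIGNED,
}


def call_indel_direction(svc: SVClass) -> SVClass:
    """Map category to a putative insertion/deletion call.

    A TE whose boundaries match the SV (TE = SV) is most simply explained
    by a TE insertion in the carrying lineage; SVs containing extra,
    multiple, or partial TE sequence are most simply explained by a
    deletion in the other lineage; TE-free SVs stay unassigned.
    """
    return replace(svc, indel_call=_DIRECTION[svc.category])


def classify_svs(
    svs: list[SVRecord],
    tes: list[TEAnnotation],
    threshold: float | Fraction = _STRICT_95,
) -> list[SVClass]:
    """Classify and direction-call a list of same-lineage SVs."""
    return [call_indel_direction(classify_sv(sv, tes, threshold)) for sv in svs]


def link_polymorphic_tes(
    polymorphic_tes: list[TEAnnotation],
    svcs: list[SVClass],
    threshold: float | Fraction = _STRICT_95,
) -> dict[str, tuple[str | None, SVCategory | None]]:
    """Assign each polymorphic TE to the SV holding most of its sequence.

    A TE links to the SV with the largest bp overlap when that overlap
    exceeds ``threshold`` of the TE's length; otherwise it is flagged
    unlinked (``(None, None)``).  TEs and SVs must share lineage and
    coordinates.
    """
    thr = threshold if isinstance(threshold, Fraction) else Fraction(str(threshold))
    by_chrom: dict[str, list[SVClass]] = {}
    for s in svcs:
        by_chrom.setdefault(s.sv_record.chrom, []).append(s)
    out: dict[str, tuple[str | None, SVCategory | None]] = {}
    for t in polymorphic_tes:
        best: tuple[int, SVClass] | None = None
        for s in by_chrom.get(t.chrom, []):
            ov = min(t.end, s.sv_record.end) - max(t.start, s.sv_record.start)
            if ov > 0 and (best is None or ov > best[0]):
                best = (ov, s)
        if best is not None and Fraction(best[0], t.length) > thr:
            out[t.te_id] = (best[1].sv_id, best[1].category)
        else:
            out[t.te_id] = (None, None)
    return out


def _interval_overlap_bp(
    start: int, end: int, region_starts: np.ndarray, region_ends: np.ndarray
) -> int:
    if len(region_starts) == 0 or end <= start:
        return 0
    lo = np.maximum(region_starts, start)
    hi = np.minimum(region_ends, end)
    return int(np.maximum(hi - lo, 0).sum())


def in_regions(
    start: int,
    end: int,
    regions: dict[str, np.ndarray] | list[tuple[str, int, int]],
    chrom: str,
    min_frac: float = 0.5,
) -> bool:
    """Membership rule shared across analyses: >= ``min_frac`` of the
    interval's bp must lie inside the region set (disjoint intervals).
    A zero-length interval (an insertion point) is a member when the
    point falls inside a region."""
    if isinstance(regions, dict):
        arr = regions.get(chrom)
        if arr is None or len(arr) == 0:
            return False
        starts, ends = arr[:, 0], arr[:, 1]
    else:
        rows = [(a, b) for c, a, b in regions if c == chrom]
        if not rows:
            return False
        starts = np.asarray([a for a, _ in rows])
        ends = np.asarray([b for _, b in rows])
    if end <= start:
        return bool(((starts <= start) & (start < ends)).any())
    ov = _interval_overlap_bp(start, end, starts, ends)
    return 2 * ov >= (end - start) if min_frac == 0.5 else ov >= min_frac * (end - start)


def tally_indel_bp(
    svcs: list[SVClass],
    regions: list[tuple[str, int, int]] | None = None,
) -> tuple[int, int, dict[str, int]]:
    """Sum SV bp by putative direction, optionally within a region set.

    Returns (insertion_bp, deletion_bp, counts per category).  With a
    region set, an SV counts if at least 50% of its bases fall inside.
    """
    region_map: dict[str, np.ndarray] | None = None
    if regions is not None:
        region_map = {}
        for chrom, a, b in regions:
            region_map.setdefault(chrom, []).append((a, b))
        region_map = {
            c: np.asarray(sorted(v), dtype=np.int64) for c, v in region_map.items()
        }
    ins_bp = del_bp = 0
    counts = {c.value: 0 for c in SVCategory}
    for s in svcs:
        r = s.sv_record
        if region_map is not None and not in_regions(
            r.anchor_start, r.anchor_end, region_map, r.chrom
        ):
            continue
        counts[s.category.value] += 1
        if s.indel_call is IndelCall.PUTATIVE_INSERTION:
            ins_bp += r.length
        elif s.indel_call is IndelCall.PUTATIVE_DELETION:
            del_bp += r.length
    return ins_bp, del_bp, counts


def svclasses_to_frame(svcs: list[SVClass]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                s.sv_id,
                s.sv_record.comparison_id,
                s.sv_record.lineage,
                s.sv_record.chrom,
                s.sv_record.start,
                s.sv_record.end,
                s.sv_record.length,
                s.category.value,
                s.indel_call.value,
                ",".join(s.full_te_ids),
                ",".join(s.partial_te_ids),
                s.te_bp_in_sv,
            )
            for s in svcs
        ],
        columns=[
            "sv_id",
            "comparison_id",
            "lineage",
            "chrom",
            "start",
            "end",
            "length",
            "category",
            "indel_call",
            "full_te_ids",
            "partial_te_ids",
            "te_bp_in_sv",
        ],
    )
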
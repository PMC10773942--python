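"""Shared / polymorphic / ambiguous feature calls and cross-comparison bins.

A feature (TE or gene) is compared against the alignment partition of
its own genome: with at least 95% of its bases in alignable sequence it
is *shared* with the other genome, with at least 95% in own-lineage
structural-variant sequence it is *polymorphic* (present here, absent
there), and anything else is *ambiguous*.  Threshold comparisons use
exact integer arithmetic, so a feature at exactly the threshold is
classified inclusively ("at least 95%").

Across many pairwise comparisons against a common reference the calls
aggregate into pangenome bins: core (shared in every comparison),
near-core (all but one or two), variable, private (never shared).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from tesv.annotations import GeneAnnotation, TEAnnotation, merge_intervals
from tesv.partition import PairPartition, SegClass


class Status(str, enum.Enum):
    SHARED = "SHARED"
    POLYMORPHIC = "POLYMORPHIC"
    AMBIGUOUS = "AMBIGUOUS"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class Bin(str, enum.Enum):
    CORE = "CORE"
    NEAR_CORE = "NEAR_CORE"
    VARIABLE = "VARIABLE"
    PRIVATE = "PRIVATE"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class LTRAgeBin(str, enum.Enum):
    VERY_YOUNG = "VERY_YOUNG"
    YOUNG = "YOUNG"
    MODERATE = "MODERATE"
    OLD = "OLD"
    UNBINNED = "UNBINNED"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class FeatureCall:
    """Per-comparison call for one feature, with exact bp-derived fractions."""

    feature_id: str
    comparison_id: str
    lineage: str  # "ref" | "query"
    status: Status
    frac_alignable: Fraction
    frac_sv_own: Fraction
    frac_unalignable: Fraction


@dataclass(frozen=True)
class ConsistencyBin:
    feature_id: str
    n_comparisons: int
    n_shared: int
    bin: Bin


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    return Fraction(str(x))


def classify_feature(
    intervals: list[tuple[int, int]],
    partition: PairPartition,
    lineage: str,
    chrom: str,
    feature_id: str = "",
    threshold: float | Fraction = Fraction(19, 20),
) -> FeatureCall:
    """Classify a feature given its (merged) intervals on one genome.

    ``intervals`` are 0-based half-open on the ``lineage`` genome's
    coordinates; for genes they are either the full span or the merged
    exon set.  Overlap is accumulated across all segments of a class
    (union), and the threshold test is exact rational arithmetic —
    e.g. 950/1000 >= 19/20 is shared.  MISSING bases count as
    unalignable.
    """
    thr = _as_fraction(threshold)
    intervals = merge_intervals(intervals)
    total = sum(b - a for a, b in intervals)
    if total <= 0:
        raise ValueError(f"zero-length feature {feature_id!r}")
    views = partition.side_intervals(lineage)
    if chrom not in views:
        raise ValueError(f"chromosome {chrom!r} not in partition ({lineage} side)")
    view = views[chrom]
    clen = partition.chrom_lengths(lineage).get(chrom)
    sv_own = SegClass.SV_REF if lineage == "ref" else SegClass.SV_QUERY

    alignable = sv = unalign = 0
    for a, b in intervals:
        if a < 0 or (clen is not None and b > clen):
            raise ValueError(
                f"feature {feature_id!r} interval [{a},{b}) outside {chrom} bounds"
            )
        for cls, bp in view.overlap_by_class(a, b).items():
            if cls == SegClass.ALIGNABLE.value:
                alignable += bp
            elif cls == sv_own.value:
                sv += bp
            else:  # UNALIGNABLE, MISSING, and the other lineage's SV class
                unalign += bp
    covered = alignable + sv + unalign
    if covered != total:
        # uncovered bases can only arise from malformed partitions
        unalign += total - covered

    if Fraction(alignable, total) >= thr:
        status = Status.SHARED
    elif Fraction(sv, total) >= thr:
        status = Status.POLYMORPHIC
    else:
        status = Status.AMBIGUOUS
    return FeatureCall(
        feature_id=feature_id,
        comparison_id=partition.comparison_id,
        lineage=lineage,
        status=status,
        frac_alignable=Fraction(alignable, total),
        frac_sv_own=Fraction(sv, total),
        frac_unalignable=Fraction(unalign, total),
    )


def classify_tes(
    tes: list[TEAnnotation],
    partition: PairPartition,
    lineage: str,
    threshold: float | Fraction = Fraction(19, 20),
) -> list[FeatureCall]:
    return [
        classify_feature(
            [(t.start, t.end)],
            partition,
            lineage,
            t.chrom,
            feature_id=t.te_id,
            threshold=threshold,
        )
        for t in tes
    ]


def classify_genes(
    genes: list[GeneAnnotation],
    partition: PairPartition,
    lineage: str,
    exon_only: bool = False,
    threshold: float | Fraction = Fraction(19, 20),
) -> list[FeatureCall]:
    """Classify genes on their full span or (``exon_only=True``) merged exons."""
    return [
        classify_feature(
            g.exon_intervals if exon_only else g.span_intervals,
            partition,
            lineage,
            g.chrom,
            feature_id=g.gene_id,
            threshold=threshold,
        )
        for g in genes
    ]


def bin_consistency(calls: list[FeatureCall]) -> ConsistencyBin:
    """Aggregate one feature's calls across comparisons into a pangenome bin.

    With n comparisons: CORE = shared in all n; NEAR_CORE = shared in
    n-1 or n-2; PRIVATE = shared in none; VARIABLE otherwise.  With the
    study design of 25 comparisons this is exactly core 25, near-core
    23-24, variable 1-22, private 0.
    """
    if not calls:
        raise ValueError("no calls supplied")
    seen = set()
    for c in calls:
        if c.comparison_id in seen:
            raise ValueError(f"duplicate comparison id {c.comparison_id!r}")
        seen.add(c.comparison_id)
    n = len(calls)
    n_shared = sum(c.status is Status.SHARED for c in calls)
    if n_shared == n:
        b = Bin.CORE
    elif n_shared == 0:
        b = Bin.PRIVATE
    elif n_shared >= n - 2:
        b = Bin.NEAR_CORE
    else:
        b = Bin.VARIABLE
    return ConsistencyBin(
        feature_id=calls[0].feature_id, n_comparisons=n, n_shared=n_shared, bin=b
    )


def bin_ltr_age(ltr_identity: float) -> LTRAgeBin:
    """Bin LTR-LTR percent identity (an insertion-age proxy) into age classes.

    very young: identity = 1; young: [0.95, 1); moderate: [0.9, 0.95);
    old: [0.8, 0.9); below 0.8: unbinned.
    """
    if not (0 <= ltr_identity <= 1):
        raise ValueError(f"ltr_identity {ltr_identity} outside [0, 1]")
    if ltr_identity == 1:
        return LTRAgeBin.VERY_YOUNG
    if ltr_identity >= 0.95:
        return LTRAgeBin.YOUNG
    if ltr_identity >= 0.9:
        return LTRAgeBin.MODERATE
    if ltr_identity >= 0.8:
        return LTRAgeBin.OLD
    return LTRAgeBin.UNBINNED


def calls_to_frame(calls: list[FeatureCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.feature_id,
                c.comparison_id,
                c.lineage,
                c.status.value,
                float(c.frac_alignable),
                float(c.frac_sv_own),
                float(c.frac_unalignable),
            )
            for c in calls
        ],
        columns=[
            "feature_id",
            "comparison_id",
            "lineage",
            "status",
            "frac_alignable",
            "frac_sv_own",
            "frac_unalignable",
        ],
    )


def bins_to_frame(bins: list[ConsistencyBin]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.feature_id, b.n_comparisons, b.n_shared, b.bin.value) for b in bins],
        columns=["feature_id", "n_comparisons", "n_shared", "bin"],
    )
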
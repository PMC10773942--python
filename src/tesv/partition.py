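"""Condense pairwise whole-genome alignment GVCFs into a genome partition.

A pairwise whole-genome alignment expressed as a GVCF (a VCF with
non-variant reference blocks) is condensed into an ordered set of
segments that assign every base of both genomes to exactly one class:

* ``ALIGNABLE``   — non-variant blocks, SNVs and small (<= ``min_sv_len``)
  insertion/deletion variants, pooled into one class of aligned sequence.
* ``SV_REF``      — sequence > ``min_sv_len`` bp present in the reference
  with 0 bp in the query (a one-sided indel: the structural-variant
  definition used throughout the package).
* ``SV_QUERY``    — the reciprocal: query-only sequence anchored at a
  zero-length reference point.
* ``UNALIGNABLE`` — records with at least one unmatched base pair on each
  side (neither a clean substitution nor a one-sided indel).
* ``MISSING``     — alignment gaps with no record coverage; kept distinct
  but pooled with UNALIGNABLE in all downstream fractions.

Coordinates are 0-based half-open internally; VCF 1-based coordinates are
converted at I/O.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import pysam


class SegClass(str, enum.Enum):
    """Classification of one segment of a pairwise alignment."""

    ALIGNABLE = "ALIGNABLE"
    SV_REF = "SV_REF"
    SV_QUERY = "SV_QUERY"
    UNALIGNABLE = "UNALIGNABLE"
    MISSING = "MISSING"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Segment:
    """One contiguous piece of the pairwise alignment in both coordinate systems.

    Either side may be zero-length (insertion points); ``ALIGNABLE``
    segments may have unequal side lengths because sub-threshold indels
    are absorbed into them.
    """

    chrom_ref: str
    ref_start: int
    ref_end: int
    chrom_query: str
    query_start: int
    query_end: int
    seg_class: SegClass

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def query_len(self) -> int:
        return self.query_end - self.query_start


@dataclass
class PairPartition:
    """The condensed two-genome alignment for one pairwise comparison.

    ``segments`` maps each reference chromosome to its ordered,
    non-overlapping segments; per reference chromosome the segment
    reference lengths sum to the chromosome length (MISSING fills gaps),
    and likewise on the query side.  SNP positions are kept on both
    coordinate systems and always fall inside ALIGNABLE segments.
    """

    comparison_id: str
    segments: dict[str, list[Segment]]
    snp_positions_ref: dict[str, np.ndarray]
    snp_positions_query: dict[str, np.ndarray]
    chrom_lengths_ref: dict[str, int]
    chrom_lengths_query: dict[str, int]

    # ---- derived views -------------------------------------------------
    def side_intervals(self, side: str) -> dict[str, "SideView"]:
        """Per-chromosome (start, end, class) arrays on one genome's coordinates.

        Zero-length intervals on that side are dropped, so the returned
        intervals tile the chromosome.
        """
        _check_side(side)
        out: dict[str, SideView] = {}
        for chrom_ref, segs in self.segments.items():
            starts, ends, classes = [], [], []
            chrom_name = chrom_ref
            for s in segs:
                if side == "ref":
                    a, b = s.ref_start, s.ref_end
                else:
                    a, b = s.query_start, s.query_end
                    chrom_name = s.chrom_query
                if b > a:
                    starts.append(a)
                    ends.append(b)
                    classes.append(s.seg_class)
            view = SideView(
                chrom=chrom_name,
                starts=np.asarray(starts, dtype=np.int64),
                ends=np.asarray(ends, dtype=np.int64),
                classes=np.asarray([c.value for c in classes], dtype=object),
            )
            out[view.chrom] = view
        return out

    def snp_positions(self, side: str) -> dict[str, np.ndarray]:
        _check_side(side)
        return self.snp_positions_ref if side == "ref" else self.snp_positions_query

    def chrom_lengths(self, side: str) -> dict[str, int]:
        _check_side(side)
        return self.chrom_lengths_ref if side == "ref" else self.chrom_lengths_query

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        for chrom, segs in self.segments.items():
            ref_cursor = 0
            q_cursor = 0
            for s in segs:
                if s.ref_start != ref_cursor or s.query_start != q_cursor:
                    raise ValueError(
                        f"segments not contiguous on {chrom} at ref {s.ref_start}"
                    )
                if s.ref_end < s.ref_start or s.query_end < s.query_start:
                    raise ValueError(f"negative-length segment on {chrom}")
                if s.seg_class is SegClass.SV_REF and not (
                    s.ref_len > 0 and s.query_len == 0
                ):
                    raise ValueError(f"bad SV_REF segment on {chrom}: {s}")
                if s.seg_class is SegClass.SV_QUERY and not (
                    s.query_len > 0 and s.ref_len == 0
                ):
                    raise ValueError(f"bad SV_QUERY segment on {chrom}: {s}")
                ref_cursor = s.ref_end
                q_cursor = s.query_end
            if ref_cursor != self.chrom_lengths_ref[chrom]:
                raise ValueError(
                    f"segments cover {ref_cursor} bp of {chrom}; chromosome is "
                    f"{self.chrom_lengths_ref[chrom]} bp"
                )
        for chrom, pos in self.snp_positions_ref.items():
            view = self.side_intervals("ref")[chrom]
            labels = view.label_positions(pos)
            if len(pos) and not (labels == SegClass.ALIGNABLE.value).all():
                raise ValueError(f"SNP outside ALIGNABLE segment on {chrom}")


@dataclass
class SideView:
    """Sorted tiling intervals of one genome side with their classes."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    classes: np.ndarray

    def overlap_by_class(self, start: int, end: int) -> dict[str, int]:
        """Integer bp of [start, end) overlapping each segment class."""
        out: dict[str, int] = {}
        if end <= start or len(self.starts) == 0:
            return out
        i = int(np.searchsorted(self.ends, start, side="right"))
        j = int(np.searchsorted(self.starts, end, side="left"))
        for k in range(i, j):
            ov = min(end, int(self.ends[k])) - max(start, int(self.starts[k]))
            if ov > 0:
                cls = str(self.classes[k])
                out[cls] = out.get(cls, 0) + ov
        return out

    def label_positions(self, positions: np.ndarray) -> np.ndarray:
        """Class label of the interval containing each position."""
        idx = np.searchsorted(self.ends, np.asarray(positions), side="right")
        idx = np.clip(idx, 0, max(len(self.starts) - 1, 0))
        return self.classes[idx] if len(self.classes) else np.asarray([])

    def class_coverage(self, seg_class: SegClass) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) of intervals of one class, for windowed coverage sums."""
        mask = self.classes == seg_class.value
        return self.starts[mask], self.ends[mask]


def _check_side(side: str) -> None:
    if side not in ("ref", "query"):
        raise ValueError(f"side must be 'ref' or 'query', got {side!r}")


# ---------------------------------------------------------------------------
# GVCF condensation
# ---------------------------------------------------------------------------


class _ChromBuilder:
    """Accumulates per-record pieces and merges adjacent same-class segments."""

    def __init__(self, chrom_ref: str, chrom_query: str):
        self.chrom_ref = chrom_ref
        self.chrom_query = chrom_query
        self.ref_pos = 0
        self.query_pos = 0
        self.segments: list[Segment] = []
        self.snps_ref: list[int] = []
        self.snps_query: list[int] = []

    def add(self, seg_class: SegClass, ref_len: int, query_len: int) -> None:
        if ref_len == 0 and query_len == 0:
            return
        last = self.segments[-1] if self.segments else None
        if last is not None and last.seg_class is seg_class:
            self.segments[-1] = replace(
                last,
                ref_end=last.ref_end + ref_len,
                query_end=last.query_end + query_len,
            )
        else:
            self.segments.append(
                Segment(
                    chrom_ref=self.chrom_ref,
                    ref_start=self.ref_pos,
                    ref_end=self.ref_pos + ref_len,
                    chrom_query=self.chrom_query,
                    query_start=self.query_pos,
                    query_end=self.query_pos + query_len,
                    seg_class=seg_class,
                )
            )
        self.ref_pos += ref_len
        self.query_pos += query_len

    def add_snp(self, ref_offset: int = 0) -> None:
        """Record a SNP at the current cursor + offset (call before add())."""
        self.snps_ref.append(self.ref_pos + ref_offset)
        self.snps_query.append(self.query_pos + ref_offset)


def _record_alleles(rec: pysam.VariantRecord) -> tuple[str, str | None]:
    """(ref allele, first alt allele or None for a non-variant block)."""
    alts = [a for a in (rec.alts or ()) if a not in ("<NON_REF>", ".")]
    if not alts:
        return rec.ref or "", None
    if len(alts) > 1:
        raise ValueError(
            f"multi-allelic record at {rec.chrom}:{rec.pos} not supported "
            f"(allele lengths {[len(rec.ref)] + [len(a) for a in alts]})"
        )
    alt = alts[0]
    if alt.startswith("<"):
        raise ValueError(
            f"symbolic allele {alt} at {rec.chrom}:{rec.pos} not supported"
        )
    return rec.ref or "", alt


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i].upper() == b[i].upper():
        i += 1
    return i


def condense_gvcf(
    gvcf_path: str,
    min_sv_len: int = 50,
    ref_name: str = "ref",
    query_name: str = "query",
    chrom_lengths_query: dict[str, int] | None = None,
) -> PairPartition:
    """Condense a pairwise-alignment GVCF into a :class:`PairPartition`.

    Record handling:

    * non-variant blocks (``END``-tagged, no concrete ALT) extend ALIGNABLE
      with equal lengths on both sides;
    * SNVs contribute 1 alignable bp and one SNP position;
    * equal-length multi-base substitutions are ALIGNABLE with one SNP per
      mismatching position;
    * one-sided indels with the longer side > ``min_sv_len`` become SV
      segments (strict: 51 bp qualifies at the default floor, 50 does not),
      smaller ones are absorbed into ALIGNABLE;
    * records with >= 1 unmatched bp on both sides become UNALIGNABLE over
      their full record span;
    * uncovered reference gaps become MISSING.

    Records must be sorted and non-overlapping on the reference; violations
    raise ``ValueError`` naming the offending record.
    """
    vcf = pysam.VariantFile(gvcf_path)
    chrom_lengths_ref = {c.name: c.length for c in vcf.header.contigs.values()}
    builders: dict[str, _ChromBuilder] = {}
    order: list[str] = []

    for rec in vcf:
        chrom = rec.chrom
        if chrom not in builders:
            builders[chrom] = _ChromBuilder(chrom, chrom)
            order.append(chrom)
        b = builders[chrom]
        start = rec.start  # 0-based
        if start < b.ref_pos:
            raise ValueError(
                f"record at {chrom}:{rec.pos} overlaps or precedes previous "
                f"record ending at {chrom}:{b.ref_pos} (unsorted input?)"
            )
        if start > b.ref_pos:
            b.add(SegClass.MISSING, start - b.ref_pos, 0)

        ref_allele, alt_allele = _record_alleles(rec)
        if alt_allele is None:
            end = rec.stop  # END tag (or pos + len(ref))
            span = end - start
            if span <= 0:
                raise ValueError(f"empty non-variant block at {chrom}:{rec.pos}")
            b.add(SegClass.ALIGNABLE, span, span)
            continue

        rlen, alen = len(ref_allele), len(alt_allele)
        if rlen == alen:
            # SNV or equal-length substitution: alignable, one SNP per mismatch
            for i, (x, y) in enumerate(zip(ref_allele, alt_allele)):
                if x.upper() != y.upper():
                    b.add_snp(i)
            b.add(SegClass.ALIGNABLE, rlen, alen)
            continue

        p = _common_prefix(ref_allele, alt_allele)
        r_extra, a_extra = rlen - p, alen - p
        if r_extra > 0 and a_extra > 0:
            # both sides carry unmatched sequence: whole record is unalignable
            b.add(SegClass.UNALIGNABLE, rlen, alen)
        elif r_extra > 0:
            b.add(SegClass.ALIGNABLE, p, p)
            if r_extra > min_sv_len:
                b.add(SegClass.SV_REF, r_extra, 0)
            else:
                b.add(SegClass.ALIGNABLE, r_extra, 0)
        elif a_extra > 0:
            b.add(SegClass.ALIGNABLE, p, p)
            if a_extra > min_sv_len:
                b.add(SegClass.SV_QUERY, 0, a_extra)
            else:
                b.add(SegClass.ALIGNABLE, 0, a_extra)
        else:  # pragma: no cover - rlen != alen guarantees an extra side
            raise ValueError(
                f"unrecognised record shape at {chrom}:{rec.pos} "
                f"(allele lengths {rlen}, {alen})"
            )
    vcf.close()

    segments: dict[str, list[Segment]] = {}
    snps_ref: dict[str, np.ndarray] = {}
    snps_query: dict[str, np.ndarray] = {}
    q_lengths: dict[str, int] = {}
    for chrom in order:
        b = builders[chrom]
        clen = chrom_lengths_ref.get(chrom)
        if clen is not None and b.ref_pos < clen:
            b.add(SegClass.MISSING, clen - b.ref_pos, 0)
        elif clen is None:
            chrom_lengths_ref[chrom] = b.ref_pos
        q_target = (chrom_lengths_query or {}).get(chrom)
        if q_target is not None and b.query_pos < q_target:
            b.add(SegClass.MISSING, 0, q_target - b.query_pos)
        segments[chrom] = b.segments
        snps_ref[chrom] = np.asarray(sorted(b.snps_ref), dtype=np.int64)
        snps_query[chrom] = np.asarray(sorted(b.snps_query), dtype=np.int64)
        q_lengths[chrom] = b.query_pos

    # drop header contigs with no records: no alignment information at all
    chrom_lengths_ref = {c: n for c, n in chrom_lengths_ref.items() if c in segments}
    return PairPartition(
        comparison_id=f"{ref_name}_vs_{query_name}",
        segments=segments,
        snp_positions_ref=snps_ref,
        snp_positions_query=snps_query,
        chrom_lengths_ref=chrom_lengths_ref,
        chrom_lengths_query=q_lengths,
    )


# ---------------------------------------------------------------------------
# Summaries and I/O
# ---------------------------------------------------------------------------


def partition_proportions(
    partition: PairPartition, side: str
) -> dict[str, tuple[int, float]]:
    """Per-class bp and genome fraction on one side of the partition.

    MISSING is pooled with UNALIGNABLE (missing data is treated as
    unalignable in all downstream analyses), so the report covers exactly
    three classes — ALIGNABLE, the side's own SV class, and UNALIGNABLE —
    whose fractions sum to 1.
    """
    _check_side(side)
    sv_class = SegClass.SV_REF if side == "ref" else SegClass.SV_QUERY
    bp = {SegClass.ALIGNABLE.value: 0, sv_class.value: 0, SegClass.UNALIGNABLE.value: 0}
    for segs in partition.segments.values():
        for s in segs:
            n = s.ref_len if side == "ref" else s.query_len
            if n == 0:
                continue
            cls = s.seg_class
            if cls is SegClass.MISSING:
                cls = SegClass.UNALIGNABLE
            if cls.value in bp:
                bp[cls.value] += n
    total = sum(partition.chrom_lengths(side).values())
    return {
        cls: (n, (n / total) if total else 0.0) for cls, n in bp.items()
    }


_SEG_COLUMNS = [
    "chrom_ref",
    "ref_start",
    "ref_end",
    "chrom_query",
    "query_start",
    "query_end",
    "class",
]


def segments_to_frame(partition: PairPartition) -> pd.DataFrame:
    rows = [
        (
            s.chrom_ref,
            s.ref_start,
            s.ref_end,
            s.chrom_query,
            s.query_start,
            s.query_end,
            s.seg_class.value,
        )
        for segs in partition.segments.values()
        for s in segs
    ]
    return pd.DataFrame(rows, columns=_SEG_COLUMNS)


def write_partition(partition: PairPartition, out_dir, prefix: str = "") -> dict:
    """Write segment TSV, SNP BEDs and a per-class summary TSV; return paths."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "segments": out_dir / f"{prefix}segments.tsv",
        "snps_ref": out_dir / f"{prefix}snps_ref.bed",
        "snps_query": out_dir / f"{prefix}snps_query.bed",
        "summary": out_dir / f"{prefix}partition_summary.tsv",
    }
    segments_to_frame(partition).to_csv(paths["segments"], sep="\t", index=False)
    for side, path in (("ref", paths["snps_ref"]), ("query", paths["snps_query"])):
        rows = []
        for chrom, pos in partition.snp_positions(side).items():
            for p in pos:
                rows.append((chrom, int(p), int(p) + 1))
        pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
            path, sep="\t", index=False, header=False
        )
    rows = []
    for side in ("ref", "query"):
        for cls, (n, frac) in partition_proportions(partition, side).items():
            rows.append((side, cls, n, frac))
    pd.DataFrame(rows, columns=["side", "class", "bp", "fraction"]).to_csv(
        paths["summary"], sep="\t", index=False
    )
    return paths


def read_segments(
    segments_tsv,
    comparison_id: str = "ref_vs_query",
    snps_ref: dict[str, np.ndarray] | None = None,
    snps_query: dict[str, np.ndarray] | None = None,
) -> PairPartition:
    """Re-read a segment TSV written by :func:`write_partition`."""
    df = pd.read_csv(segments_tsv, sep="\t", dtype={"chrom_ref": str, "chrom_query": str})
    segments: dict[str, list[Segment]] = {}
    for row in df.itertuples(index=False):
        seg = Segment(
            chrom_ref=row.chrom_ref,
            ref_start=int(row.ref_start),
            ref_end=int(row.ref_end),
            chrom_query=row.chrom_query,
            query_start=int(row.query_start),
            query_end=int(row.query_end),
            seg_class=SegClass(row[6]),
        )
        segments.setdefault(seg.chrom_ref, []).append(seg)
    for segs in segments.values():
        segs.sort(key=lambda s: s.ref_start)
    lengths_ref = {c: max(s.ref_end for s in segs) for c, segs in segments.items()}
    lengths_query = {c: max(s.query_end for s in segs) for c, segs in segments.items()}
    empty = {c: np.asarray([], dtype=np.int64) for c in segments}
    return PairPartition(
        comparison_id=comparison_id,
        segments=segments,
        snp_positions_ref=snps_ref if snps_ref is not None else dict(empty),
        snp_positions_query=snps_query if snps_query is not None else dict(empty),
        chrom_lengths_ref=lengths_ref,
        chrom_lengths_query=lengths_query,
    )


def read_snp_bed(path) -> dict[str, np.ndarray]:
    """Read a 3-column SNP BED into per-chromosome sorted position arrays."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], dtype={0: str})
    except pd.errors.EmptyDataError:
        return {}
    out = {}
    for chrom, sub in df.groupby(0, sort=False):
        out[str(chrom)] = np.sort(sub[1].to_numpy(dtype=np.int64))
    return out
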
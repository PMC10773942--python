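"""Detection of SNP-depleted (identity-by-state) regions.

Recently co-inherited haplotype blocks between two genomes show SNP
rates orders of magnitude below the genome-wide background.  They are
detected with a sliding-window scan: 1 Mb windows offset by 250 kb are
scored for SNP count and alignable bp; a window qualifies when it holds
more than 950,000 alignable bp and a normalised SNP rate (SNPs per
alignable bp) below 1 in 10,000; a run of at least five consecutive
qualifying windows (hence a span of at least 2 Mb) is reported as a
SNP-depleted region.  For downstream analyses each region is trimmed by
100 kb on both sides so that its boundaries stay inside the
identity-by-state block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tesv.partition import PairPartition, SegClass


@dataclass(frozen=True)
class Window:
    """One sliding window on the reference genome."""

    chrom: str
    start: int
    end: int
    snp_count: int
    alignable_bp: int

    @property
    def norm_rate(self) -> float:
        """SNPs per alignable bp; NaN when no sequence is alignable."""
        if self.alignable_bp == 0:
            return float("nan")
        return self.snp_count / self.alignable_bp

    def qualifies(self, alignable_floor: int = 950_000, rate_denom: int = 10_000) -> bool:
        # exact integer form of snp_count / alignable_bp < 1 / rate_denom
        return (
            self.alignable_bp > alignable_floor
            and self.snp_count * rate_denom < self.alignable_bp
        )


@dataclass(frozen=True)
class SNPDepletedRegion:
    chrom: str
    raw_start: int
    raw_end: int
    n_windows: int
    trim_bp: int = 100_000

    @property
    def trimmed_start(self) -> int:
        return self.raw_start + self.trim_bp

    @property
    def trimmed_end(self) -> int:
        return self.raw_end - self.trim_bp


def window_stats(
    partition: PairPartition,
    window_bp: int = 1_000_000,
    step_bp: int = 250_000,
) -> list[Window]:
    """Per-window SNP counts and alignable bp on the reference genome.

    Windows are anchored at position 0 of each chromosome and tile it at
    ``step_bp`` offsets; trailing partial windows are emitted (they can
    only qualify if they still exceed the alignable floor, which a
    partial window shorter than the floor cannot).
    """
    if step_bp > window_bp:
        raise ValueError(f"step ({step_bp}) exceeds window ({window_bp})")
    out: list[Window] = []
    views = partition.side_intervals("ref")
    for chrom, clen in partition.chrom_lengths_ref.items():
        snps = partition.snp_positions_ref.get(chrom, np.asarray([], dtype=np.int64))
        view = views[chrom]
        al_starts, al_ends = view.class_coverage(SegClass.ALIGNABLE)
        cum = np.concatenate([[0], np.cumsum(al_ends - al_starts)])

        def alignable_in(a: int, b: int) -> int:
            if len(al_starts) == 0:
                return 0
            i = int(np.searchsorted(al_ends, a, side="right"))
            j = int(np.searchsorted(al_starts, b, side="left"))
            if j <= i:
                return 0
            total = int(cum[j] - cum[i])
            total -= max(0, a - int(al_starts[i]))
            total -= max(0, int(al_ends[j - 1]) - b)
            return total

        for start in range(0, max(clen, 1), step_bp):
            if start >= clen:
                break
            end = min(start + window_bp, clen)
            n_snp = int(
                np.searchsorted(snps, start + window_bp, side="left")
                - np.searchsorted(snps, start, side="left")
            )
            out.append(
                Window(
                    chrom=chrom,
                    start=start,
                    end=end,
                    snp_count=n_snp,
                    alignable_bp=alignable_in(start, end),
                )
            )
    return out


def detect_regions(
    windows: list[Window],
    min_run: int = 5,
    window_bp: int = 1_000_000,
    step_bp: int = 250_000,
    alignable_floor: int = 950_000,
    rate_denom: int = 10_000,
    trim_bp: int = 100_000,
) -> list[SNPDepletedRegion]:
    """Maximal runs of >= ``min_run`` consecutive qualifying windows.

    Consecutive means window starts differ by exactly ``step_bp``.  The
    raw region spans the first window's start to the last window's start
    plus ``window_bp``; trimmed coordinates shrink both ends by
    ``trim_bp``.
    """
    regions: list[SNPDepletedRegion] = []
    by_chrom: dict[str, list[Window]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, ws in by_chrom.items():
        ws = sorted(ws, key=lambda w: w.start)
        run: list[Window] = []

        def flush(run):
            if len(run) >= min_run:
                regions.append(
                    SNPDepletedRegion(
                        chrom=chrom,
                        raw_start=run[0].start,
                        raw_end=run[-1].start + window_bp,
                        n_windows=len(run),
                        trim_bp=trim_bp,
                    )
                )

        for w in ws:
            ok = w.qualifies(alignable_floor, rate_denom)
            if ok and (not run or w.start == run[-1].start + step_bp):
                run.append(w)
            else:
                flush(run)
                run = [w] if ok else []
        flush(run)
    return regions


def regions_to_beds(regions: list[SNPDepletedRegion]) -> tuple[pd.DataFrame, pd.DataFrame]:
    raw = pd.DataFrame(
        [(r.chrom, r.raw_start, r.raw_end, r.n_windows) for r in regions],
        columns=["chrom", "start", "end", "n_windows"],
    )
    trimmed = pd.DataFrame(
        [(r.chrom, r.trimmed_start, r.trimmed_end, r.n_windows) for r in regions],
        columns=["chrom", "start", "end", "n_windows"],
    )
    return raw, trimmed


def windows_to_frame(
    windows: list[Window], alignable_floor: int = 950_000, rate_denom: int = 10_000
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                w.chrom,
                w.start,
                w.end,
                w.snp_count,
                w.alignable_bp,
                w.norm_rate,
                w.qualifies(alignable_floor, rate_denom),
            )
            for w in windows
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "snp_count",
            "alignable_bp",
            "norm_rate",
            "qualifies",
        ],
    )


def restrict_analysis(
    regions: list[SNPDepletedRegion],
    calls=None,
    svcs=None,
    features: dict[str, tuple[str, int, int]] | None = None,
) -> dict:
    """Region-scoped summaries of feature calls and SV classes.

    Membership uses trimmed region coordinates and the shared >= 50%-of-bp
    rule.  ``features`` maps feature_id -> (chrom, start, end) for the
    calls' features (calls themselves carry no coordinates).  Returns
    pooled and per-region status / category counts plus the
    insertion-deletion bp tally inside the regions.
    """
    from tesv.svclass import in_regions, tally_indel_bp

    trimmed = [(r.chrom, r.trimmed_start, r.trimmed_end) for r in regions]
    region_map: dict[str, np.ndarray] = {}
    for chrom, a, b in trimmed:
        region_map.setdefault(chrom, []).append((a, b))
    region_map = {
        c: np.asarray(sorted(v), dtype=np.int64) for c, v in region_map.items()
    }

    status_counts: dict[str, int] = {}
    per_region: list[dict] = [
        {
            "chrom": r.chrom,
            "start": r.trimmed_start,
            "end": r.trimmed_end,
            "status_counts": {},
            "category_counts": {},
        }
        for r in regions
    ]
    if calls is not None:
        if features is None:
            raise ValueError("feature coordinates required to scope calls to regions")
        for c in calls:
            coords = features.get(c.feature_id)
            if coords is None:
                continue
            chrom, a, b = coords
            if not in_regions(a, b, region_map, chrom):
                continue
            status_counts[c.status.value] = status_counts.get(c.status.value, 0) + 1
            for r, pr in zip(regions, per_region):
                if r.chrom == chrom and in_regions(
                    a, b, {chrom: np.asarray([[r.trimmed_start, r.trimmed_end]])}, chrom
                ):
                    sc = pr["status_counts"]
                    sc[c.status.value] = sc.get(c.status.value, 0) + 1

    result: dict = {
        "status_counts": status_counts,
        "per_region": per_region,
        "category_counts": {},
        "insertion_bp": 0,
        "deletion_bp": 0,
    }
    if svcs is not None:
        ins_bp, del_bp, cat_counts = tally_indel_bp(svcs, regions=trimmed)
        result["insertion_bp"] = ins_bp
        result["deletion_bp"] = del_bp
        result["category_counts"] = cat_counts
        for s in svcs:
            r0 = s.sv_record
            for r, pr in zip(regions, per_region):
                if r.chrom == r0.chrom and in_regions(
                    r0.anchor_start,
                    r0.anchor_end,
                    {r0.chrom: np.asarray([[r.trimmed_start, r.trimmed_end]])},
                    r0.chrom,
                ):
                    cc = pr["category_counts"]
                    cc[s.category.value] = cc.get(s.category.value, 0) + 1
    return result


def plot_window_rates(windows: list[Window], regions: list[SNPDepletedRegion], path):
    """Per-window normalised SNP rate with detected regions shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({w.chrom for w in windows})
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 2.5 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes.ravel(), chroms):
        ws = [w for w in windows if w.chrom == chrom and w.alignable_bp > 0]
        ax.plot([w.start for w in ws], [w.norm_rate for w in ws], ".", ms=3)
        for r in regions:
            if r.chrom == chrom:
                ax.axvspan(r.raw_start, r.raw_end, color="gold", alpha=0.4)
        ax.set_yscale("symlog", linthresh=1e-5)
        ax.set_ylabel("SNPs / alignable bp")
        ax.set_title(chrom)
    axes.ravel()[-1].set_xlabel("window start (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
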
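"""Family- and superfamily-level polymorphism summaries and report tables.

These summaries follow the reference-genome TE set across all pairwise
comparisons: per-family percent-polymorphic distributions (families with
at least 20 copies), superfamily x annotation-method roll-ups, and the
per-family count of simple TE-presence/absence (TE = SV) events inside
SNP-depleted regions, used to flag candidate currently-active families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tesv.annotations import TEAnnotation
from tesv.classify import FeatureCall, Status
from tesv.svclass import SVCategory


@dataclass
class FamilySummary:
    family: str
    superfamily: str
    copy_number_ref: int
    pct_polymorphic: dict[str, float]  # comparison_id -> percent

    @property
    def pct_range(self) -> float:
        vals = list(self.pct_polymorphic.values())
        return (max(vals) - min(vals)) if vals else 0.0


def family_polymorphism(
    calls_by_comparison: dict[str, list[FeatureCall]],
    tes: list[TEAnnotation],
    min_copies: int = 20,
) -> list[FamilySummary]:
    """Per-family percent-polymorphic across comparisons.

    ``calls_by_comparison`` maps comparison id to the reference genome's
    feature calls; ``tes`` is the reference TE set the calls were made
    on.  Families with fewer than ``min_copies`` copies are excluded; the
    percentage denominator is the family's copy number in the classified
    genome.
    """
    fam_info: dict[str, tuple[str, list[str]]] = {}
    for t in tes:
        sf, members = fam_info.setdefault(t.family, (t.superfamily, []))
        members.append(t.te_id)
    te_family = {t.te_id: t.family for t in tes}

    out: list[FamilySummary] = []
    for family, (superfamily, members) in fam_info.items():
        n = len(members)
        if n < min_copies:
            continue
        pcts: dict[str, float] = {}
        for comp_id, calls in calls_by_comparison.items():
            n_poly = sum(
                1
                for c in calls
                if te_family.get(c.feature_id) == family
                and c.status is Status.POLYMORPHIC
            )
            pcts[comp_id] = 100.0 * n_poly / n
        out.append(
            FamilySummary(
                family=family,
                superfamily=superfamily,
                copy_number_ref=n,
                pct_polymorphic=pcts,
            )
        )
    out.sort(key=lambda f: (-f.copy_number_ref, f.family))
    return out


def family_summary_frame(summaries: list[FamilySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                f.family,
                f.superfamily,
                f.copy_number_ref,
                np.mean(list(f.pct_polymorphic.values())) if f.pct_polymorphic else 0.0,
                f.pct_range,
            )
            for f in summaries
        ],
        columns=["family", "superfamily", "copy_number", "mean_pct_polymorphic", "pct_range"],
    )


def superfamily_rollup(
    calls_by_comparison: dict[str, list[FeatureCall]],
    tes: list[TEAnnotation],
) -> pd.DataFrame:
    """Mean +/- sd of percent polymorphic per superfamily x method.

    Each comparison contributes one percentage per (superfamily, method)
    cell; the table reports the across-comparison mean and standard
    deviation.
    """
    te_meta = {t.te_id: (t.superfamily, t.method) for t in tes}
    rows = []
    for comp_id, calls in calls_by_comparison.items():
        counts: dict[tuple[str, str], list[int]] = {}
        for c in calls:
            meta = te_meta.get(c.feature_id)
            if meta is None:
                continue
            tot_poly = counts.setdefault(meta, [0, 0])
            tot_poly[0] += 1
            if c.status is Status.POLYMORPHIC:
                tot_poly[1] += 1
        for (sf, method), (tot, poly) in counts.items():
            rows.append((comp_id, sf, method, 100.0 * poly / tot if tot else 0.0))
    df = pd.DataFrame(rows, columns=["comparison_id", "superfamily", "method", "pct_polymorphic"])
    if df.empty:
        return pd.DataFrame(columns=["superfamily", "method", "mean_pct", "sd_pct", "n_comparisons"])
    g = df.groupby(["superfamily", "method"])["pct_polymorphic"]
    out = g.agg(mean_pct="mean", sd_pct="std", n_comparisons="count").reset_index()
    out["sd_pct"] = out["sd_pct"].fillna(0.0)
    return out.sort_values(["superfamily", "method"]).reset_index(drop=True)


def status_by_superfamily(
    calls: list[FeatureCall], tes: list[TEAnnotation]
) -> pd.DataFrame:
    """Per-comparison counts of shared/polymorphic/ambiguous by superfamily."""
    sf = {t.te_id: t.superfamily for t in tes}
    rows = [
        (c.comparison_id, sf.get(c.feature_id, "?"), c.status.value) for c in calls
    ]
    df = pd.DataFrame(rows, columns=["comparison_id", "superfamily", "status"])
    return (
        df.groupby(["comparison_id", "superfamily", "status"])
        .size()
        .rename("count")
        .reset_index()
    )


@dataclass
class ActiveFamilyCandidate:
    family: str
    superfamily: str
    event_count: int
    per_genome: dict[str, int]
    lengths: list[int] = field(default_factory=list)
    flagged: bool = False


def candidate_active_families(
    links_by_comparison: dict[str, dict[str, tuple[str | None, SVCategory | None]]],
    tes_by_comparison: dict[str, dict[str, TEAnnotation]],
    min_events: int = 10,
) -> list[ActiveFamilyCandidate]:
    """Families with many simple TE-presence/absence events in SNP-depleted regions.

    ``links_by_comparison`` maps comparison id to the region-restricted
    TE -> (sv_id, category) mapping; ``tes_by_comparison`` maps
    comparison id to te_id -> annotation (for family, superfamily and
    length).  Only TE = SV links count as events.  Families with strictly
    more than ``min_events`` events are flagged as candidate active
    families; the per-genome event balance and element-length list are
    reported for all families with at least one event.
    """
    agg: dict[str, ActiveFamilyCandidate] = {}
    for comp_id, links in links_by_comparison.items():
        te_map = tes_by_comparison.get(comp_id, {})
        for te_id, (sv_id, category) in links.items():
            if sv_id is None or category is not SVCategory.TE_EQ_SV:
                continue
            t = te_map.get(te_id)
            if t is None:
                continue
            cand = agg.setdefault(
                t.family,
                ActiveFamilyCandidate(
                    family=t.family,
                    superfamily=t.superfamily,
                    event_count=0,
                    per_genome={},
                ),
            )
            cand.event_count += 1
            cand.per_genome[comp_id] = cand.per_genome.get(comp_id, 0) + 1
            cand.lengths.append(t.length)
    for cand in agg.values():
        cand.flagged = cand.event_count > min_events
    return sorted(agg.values(), key=lambda c: (-c.event_count, c.family))


def active_families_frame(cands: list[ActiveFamilyCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.family,
                c.superfamily,
                c.event_count,
                c.flagged,
                int(np.median(c.lengths)) if c.lengths else 0,
                min(c.lengths) if c.lengths else 0,
                max(c.lengths) if c.lengths else 0,
            )
            for c in cands
        ],
        columns=["family", "superfamily", "event_count", "flagged", "median_len", "min_len", "max_len"],
    )
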
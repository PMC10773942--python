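"""Synthetic diverged-genome simulator with ground truth.

Simulates an ancestral chromosome set densely annotated with
transposable elements (optionally with nested homology fragments and
genes), then derives a reference genome and one or more query genomes by
planting mutational events:

* SNPs at a configurable background rate (default 1 per 44 bp, typical
  of diverged maize inbred pairs), suppressed inside designated
  identity-by-state (IBS) blocks that a query shares with the reference;
* TE insertions whose annotation exactly spans the inserted sequence
  (expected to classify as TE = SV putative insertions);
* deletions removing a single whole TE plus flanking sequence
  (TE-within-SV), several adjacent whole TEs (multi-TE SV), the interior
  of one TE (incomplete-TE SV), non-TE sequence (no-TE SV), or intronic
  gene sequence;
* optional sub-threshold (< 50 bp) indels, unalignable substitution
  blocks, and missing-data gaps.

Pairwise alignments are constructed analytically from the event history
(no sequence aligner), both as in-memory partitions and as GVCF files,
so the expected outcome of every downstream stage is known exactly and
recorded in a truth table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tesv.annotations import GeneAnnotation, TEAnnotation
from tesv.partition import PairPartition, SegClass, _ChromBuilder
from tesv.svclass import IndelCall, SVCategory

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilySpec:
    """One TE family in the simulated catalog."""

    family: str
    superfamily: str
    mean_len: int
    sd_len: int = 0
    weight: float = 1.0


def default_family_catalog() -> list[FamilySpec]:
    """A maize-like catalog: long LTR retrotransspons dominating genome
    space, smaller DNA/TIR families dominating counts."""
    return [
        FamilySpec("RLC_sim_opie", "RLC", 8000, 800, 3.0),
        FamilySpec("RLG_sim_huck", "RLG", 10000, 1000, 3.0),
        FamilySpec("RLG_sim_cinful", "RLG", 7500, 400, 2.0),
        FamilySpec("RLX_sim_unknown", "RLX", 5000, 600, 2.0),
        FamilySpec("RIL_sim_L1", "RIL", 4000, 500, 1.0),
        FamilySpec("DTA_sim_hbr", "DTA", 400, 40, 1.5),
        FamilySpec("DTC_sim_zeon", "DTC", 3000, 300, 1.0),
        FamilySpec("DTH_sim_pif", "DTH", 500, 50, 1.0),
        FamilySpec("DTM_sim_mu", "DTM", 2000, 200, 1.0),
        FamilySpec("DTT_sim_tourist", "DTT", 300, 30, 1.5),
    ]


@dataclass(frozen=True)
class IBSBlock:
    """An ancestral interval inherited identically by the reference and a
    subset of queries (no SNPs planted for those pairs)."""

    chrom: str
    start: int
    end: int
    queries: tuple[str, ...]


@dataclass
class SimConfig:
    seed: int = 0
    genome_bp: int = 1_000_000
    n_chromosomes: int = 1
    te_density: float = 0.77
    family_catalog: list[FamilySpec] = field(default_factory=default_family_catalog)
    frag_prob: float = 0.4  # probability a placed TE is a homology fragment
    nested_frag_prob: float = 0.1  # structural TE carries a nested fragment
    snp_rate: float = 1.0 / 44.0
    n_queries: int = 1
    n_te_insertions: int = 0
    insertion_family: str | None = None  # force all insertions to one family
    # deletion counts by subtype
    n_del_single_te: int = 0
    n_del_multi_te: int = 0
    n_del_internal_te: int = 0
    n_del_non_te: int = 0
    n_del_intron: int = 0
    n_small_indels: int = 0  # sub-threshold (< 50 bp), absorbed into ALIGNABLE
    n_unalignable: int = 0
    n_missing: int = 0
    ibs_blocks: list[IBSBlock] = field(default_factory=list)
    n_genes: int = 0
    min_gap: int = 30  # bp between placed annotations (> 5 bp boundary rule)
    edge_margin: int = 1000  # no events this close to chromosome ends
    event_pad: int = 12  # enforced alignable spacer between planted events
    max_retries: int = 200

    def __post_init__(self):
        if not (0 <= self.te_density < 1):
            raise ValueError("te_density must be in [0, 1)")
        if not (0 <= self.snp_rate <= 1):
            raise ValueError("snp_rate must be in [0, 1]")
        for b in self.ibs_blocks:
            if b.start < 0 or b.end > self.genome_bp // self.n_chromosomes:
                raise ValueError(f"IBS block {b} outside chromosome bounds")

    @property
    def query_names(self) -> list[str]:
        return [f"q{i + 1}" for i in range(self.n_queries)]


class EventType(str, enum.Enum):
    SNP = "SNP"
    TE_INSERTION = "TE_INSERTION"
    DELETION = "DELETION"
    SMALL_INDEL = "SMALL_INDEL"
    UNALIGNABLE = "UNALIGNABLE"
    MISSING = "MISSING"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass
class TruthEvent:
    """Ground truth for one planted event.

    ``anc_start``/``anc_end`` are on ancestor coordinates (equal for
    insertion points); ``derived_start``/``derived_end`` on the carrier
    genome; ``sv_lineage``/``sv_start``/``sv_end`` locate the expected SV
    segment in the ref-vs-carrier comparison (SV coordinates are on the
    lineage that retains the sequence).
    """

    event_id: str
    event_type: EventType
    subtype: str
    lineage: str  # carrier of the derived allele: "ref" or a query name
    chrom: str
    anc_start: int
    anc_end: int
    derived_start: int = -1
    derived_end: int = -1
    sv_lineage: str = ""
    sv_start: int = -1
    sv_end: int = -1
    # reference-coordinate anchor of the expected SV (equals the SV span
    # for reference-carried sequence; a zero-length point for query-carried)
    anchor_start: int = -1
    anchor_end: int = -1
    affected_te_ids: tuple[str, ...] = ()
    inserted_len: int = 0
    query_len: int = 0  # for unalignable events
    expected_sv_category: SVCategory | None = None
    expected_indel_call: IndelCall | None = None
    family: str = ""


# ---------------------------------------------------------------------------
# Ancestor simulation
# ---------------------------------------------------------------------------


@dataclass
class Ancestor:
    chrom_lengths: dict[str, int]
    tes: list[TEAnnotation]  # top-level + nested fragments
    nested_host_ids: set[str]  # hosts carrying a nested fragment
    nested_frag_ids: set[str]
    genes: list[GeneAnnotation] = field(default_factory=list)

    def top_level(self, chrom: str) -> list[TEAnnotation]:
        return [
            t
            for t in self.tes
            if t.chrom == chrom and t.te_id not in self.nested_frag_ids
        ]


def _sample_length(rng, spec: FamilySpec, min_len: int = 80) -> int:
    n = int(round(rng.normal(spec.mean_len, spec.sd_len))) if spec.sd_len else spec.mean_len
    return max(n, min_len)


def simulate_ancestor(cfg: SimConfig) -> Ancestor:
    """Place non-overlapping TE annotations covering ~``te_density`` of the
    genome, deterministic under the config seed.

    Left-to-right placement: TE lengths come from the family catalog and
    gap lengths from an exponential law whose mean makes the expected
    coverage equal the target density.  Structural LTR elements carry an
    LTR-identity attribute; a fraction of structural elements host one
    nested homology fragment (fully contained, clear of the host's
    edges), mirroring the containment exemption of the annotation
    filter.  Genes (if requested) go into TE-free gaps afterwards.
    """
    rng = np.random.default_rng(cfg.seed)
    clen = cfg.genome_bp // cfg.n_chromosomes
    chrom_lengths = {f"chr{i + 1}": clen for i in range(cfg.n_chromosomes)}

    catalog = cfg.family_catalog
    weights = np.asarray([f.weight for f in catalog], dtype=float)
    weights /= weights.sum()
    mean_te_len = float(sum(f.mean_len * w for f, w in zip(catalog, weights)))
    if cfg.te_density > 0:
        mean_gap = mean_te_len * (1 - cfg.te_density) / cfg.te_density
        if mean_gap < cfg.min_gap:
            raise ValueError(
                f"te_density {cfg.te_density} infeasible with min_gap {cfg.min_gap} "
                f"and mean TE length {mean_te_len:.0f}"
            )
    tes: list[TEAnnotation] = []
    nested_hosts: set[str] = set()
    nested_frags: set[str] = set()
    counter = 0
    for chrom in chrom_lengths:
        pos = cfg.min_gap
        while cfg.te_density > 0:
            gap = cfg.min_gap + int(rng.exponential(max(mean_gap - cfg.min_gap, 1)))
            start = pos + gap
            spec = catalog[int(rng.choice(len(catalog), p=weights))]
            is_frag = rng.random() < cfg.frag_prob
            if is_frag:
                length = max(80, int(_sample_length(rng, spec) * rng.uniform(0.05, 0.4)))
                method = "homology"
            else:
                length = _sample_length(rng, spec)
                method = "structural"
            end = start + length
            if end > clen - cfg.min_gap:
                break
            counter += 1
            te_id = f"anc_te{counter:06d}"
            ltr_identity = None
            if method == "structural" and spec.superfamily in {"RLC", "RLG", "RLX"}:
                ltr_identity = float(np.clip(1.0 - rng.exponential(0.03), 0.8, 1.0))
            te = TEAnnotation(
                te_id=te_id,
                chrom=chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                superfamily=spec.superfamily,
                family=spec.family,
                method=method,
                ltr_identity=ltr_identity,
            )
            tes.append(te)
            # optional single nested homology fragment, clear of host edges
            if (
                method == "structural"
                and length >= 1000
                and rng.random() < cfg.nested_frag_prob
            ):
                fspec = catalog[int(rng.choice(len(catalog), p=weights))]
                flen = int(rng.integers(100, min(1000, length - 40)))
                fstart = start + int(rng.integers(10, length - flen - 10))
                counter += 1
                fid = f"anc_te{counter:06d}"
                tes.append(
                    TEAnnotation(
                        te_id=fid,
                        chrom=chrom,
                        start=fstart,
                        end=fstart + flen,
                        strand=te.strand,
                        superfamily=fspec.superfamily,
                        family=fspec.family,
                        method="homology",
                    )
                )
                nested_hosts.add(te_id)
                nested_frags.add(fid)
            pos = end

    genes: list[GeneAnnotation] = []
    if cfg.n_genes:
        genes = _place_genes(rng, cfg, chrom_lengths, tes)
    anc = Ancestor(
        chrom_lengths=chrom_lengths,
        tes=tes,
        nested_host_ids=nested_hosts,
        nested_frag_ids=nested_frags,
        genes=genes,
    )
    return anc


def _place_genes(rng, cfg, chrom_lengths, tes) -> list[GeneAnnotation]:
    """Place multi-exon genes in TE-free gaps (large gaps required)."""
    genes = []
    by_chrom: dict[str, list[TEAnnotation]] = {}
    for t in tes:
        by_chrom.setdefault(t.chrom, []).append(t)
    gap_pool: list[tuple[str, int, int]] = []
    for chrom, clen in chrom_lengths.items():
        ts = sorted(by_chrom.get(chrom, []), key=lambda t: t.start)
        # top-level gaps only
        cursor = 0
        for t in ts:
            if t.start > cursor:
                gap_pool.append((chrom, cursor, t.start))
            cursor = max(cursor, t.end)
        if cursor < clen:
            gap_pool.append((chrom, cursor, clen))
    gap_pool = [g for g in gap_pool if g[2] - g[1] >= 2500]
    rng.shuffle(gap_pool)
    for i in range(cfg.n_genes):
        if not gap_pool:
            break
        chrom, a, b = gap_pool.pop()
        usable = b - a - 2 * cfg.min_gap
        n_exons = int(rng.integers(2, 5))
        exon_len = int(rng.integers(150, 400))
        max_intron = (usable - n_exons * exon_len) // max(n_exons - 1, 1)
        if max_intron < 200:
            continue
        intron_len = int(rng.integers(200, max_intron + 1))
        start = a + cfg.min_gap
        exons = []
        pos = start
        for _ in range(n_exons):
            exons.append((pos, pos + exon_len))
            pos += exon_len + intron_len
        gene_end = exons[-1][1]
        genes.append(
            GeneAnnotation(
                gene_id=f"gene{i + 1:04d}",
                chrom=chrom,
                gene_start=start,
                gene_end=gene_end,
                exons=tuple(exons),
                syntenic=bool(rng.random() < 0.7),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Event planting
# ---------------------------------------------------------------------------


class _Blocked:
    """Per-chromosome sorted interval registry for event collision checks."""

    def __init__(self):
        self.by_chrom: dict[str, list[tuple[int, int]]] = {}

    def conflicts(self, chrom: str, start: int, end: int) -> bool:
        for a, b in self.by_chrom.get(chrom, []):
            if start < b and a < end:
                return True
        return False

    def add(self, chrom: str, start: int, end: int) -> None:
        self.by_chrom.setdefault(chrom, []).append((start, end))


def _gaps(anc: Ancestor, chrom: str) -> list[tuple[int, int]]:
    """TE-free top-level gaps of a chromosome (gene spans excluded)."""
    blocked = [(t.start, t.end) for t in anc.top_level(chrom)]
    blocked += [(g.gene_start, g.gene_end) for g in anc.genes if g.chrom == chrom]
    blocked.sort()
    clen = anc.chrom_lengths[chrom]
    gaps, cursor = [], 0
    for a, b in blocked:
        if a > cursor:
            gaps.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < clen:
        gaps.append((cursor, clen))
    return gaps


@dataclass
class SimResult:
    config: SimConfig
    ancestor: Ancestor
    truth: list[TruthEvent]
    partitions: dict[str, PairPartition]  # query name -> ref-vs-query partition
    tes_by_genome: dict[str, list[TEAnnotation]]  # "ref" and query names
    genes_by_genome: dict[str, list[GeneAnnotation]]
    chrom_lengths: dict[str, dict[str, int]]  # genome -> chrom -> bp
    snps_by_query: dict[str, dict[str, np.ndarray]]  # ancestral coordinates
    tokens: dict[str, dict[str, list[tuple[SegClass, int, int]]]]


def derive_haplotypes(anc: Ancestor, cfg: SimConfig) -> SimResult:
    """Plant events on the ancestor and derive all pairwise alignments.

    Event locations are rejection-sampled to be mutually disjoint (with an
    alignable spacer of ``event_pad`` bp) across all genomes, so every
    planted event maps to exactly one SV segment whose category is known
    in advance.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    blocked = _Blocked()
    truth: list[TruthEvent] = []
    chroms = list(anc.chrom_lengths)
    clens = np.asarray([anc.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_w = clens / clens.sum()
    carriers = ["ref"] + cfg.query_names
    eid = 0

    def new_id(prefix):
        nonlocal eid
        eid += 1
        return f"{prefix}{eid:05d}"

    def pick_chrom() -> str:
        return chroms[int(rng.choice(len(chroms), p=chrom_w))]

    def in_margin(chrom, a, b) -> bool:
        clen = anc.chrom_lengths[chrom]
        return a >= cfg.edge_margin and b <= clen - cfg.edge_margin

    def try_place(chrom, a, b) -> bool:
        pad = cfg.event_pad
        if not in_margin(chrom, a, b):
            return False
        if blocked.conflicts(chrom, a - pad, b + pad):
            return False
        blocked.add(chrom, a - pad, b + pad)
        return True

    catalog = {f.family: f for f in cfg.family_catalog}
    weights = np.asarray([f.weight for f in cfg.family_catalog], dtype=float)
    weights /= weights.sum()

    # --- TE insertions -------------------------------------------------
    for _ in range(cfg.n_te_insertions):
        placed = False
        for _attempt in range(cfg.max_retries):
            chrom = pick_chrom()
            gaps = [g for g in _gaps(anc, chrom) if g[1] - g[0] >= 2 * cfg.min_gap]
            if not gaps:
                continue
            a, b = gaps[int(rng.integers(len(gaps)))]
            point = int(rng.integers(a + cfg.min_gap // 2, b - cfg.min_gap // 2))
            if not try_place(chrom, point, point):
                continue
            if cfg.insertion_family is not None:
                spec = catalog[cfg.insertion_family]
            else:
                spec = cfg.family_catalog[int(rng.choice(len(weights), p=weights))]
            length = _sample_length(rng, spec, min_len=100)
            carrier = carriers[int(rng.integers(len(carriers)))]
            truth.append(
                TruthEvent(
                    event_id=new_id("ins"),
                    event_type=EventType.TE_INSERTION,
                    subtype="te_insertion",
                    lineage=carrier,
                    chrom=chrom,
                    anc_start=point,
                    anc_end=point,
                    inserted_len=length,
                    family=spec.family,
                    expected_sv_category=SVCategory.TE_EQ_SV,
                    expected_indel_call=IndelCall.PUTATIVE_INSERTION,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place TE insertion after max retries")

    # --- deletions -----------------------------------------------------
    def queries_only() -> str:
        if not cfg.query_names:
            raise ValueError("deletions require at least one query genome")
        return cfg.query_names[int(rng.integers(cfg.n_queries))]

    def plant_deletion(subtype: str) -> None:
        for _attempt in range(cfg.max_retries):
            chrom = pick_chrom()
            top = anc.top_level(chrom)
            if subtype == "single_te":
                eligible = [
                    (i, t)
                    for i, t in enumerate(top)
                    if t.te_id not in anc.nested_host_ids and t.length >= 120
                ]
                if not eligible:
                    continue
                i, t = eligible[int(rng.integers(len(eligible)))]
                flank_total = max(t.length // 15 + 10, 24)
                fl, fr = flank_total // 2, flank_total - flank_total // 2
                a, b = t.start - fl, t.end + fr
                prev_end = top[i - 1].end if i > 0 else 0
                next_start = (
                    top[i + 1].start if i + 1 < len(top) else anc.chrom_lengths[chrom]
                )
                if a <= prev_end + cfg.min_gap // 2 or b >= next_start - cfg.min_gap // 2:
                    continue
                if not try_place(chrom, a, b):
                    continue
                affected = (t.te_id,)
                cat = SVCategory.TE_WITHIN_SV
            elif subtype == "multi_te":
                if len(top) < 2:
                    continue
                k = int(rng.integers(2, 5))
                i = int(rng.integers(max(len(top) - k, 1)))
                run = top[i : i + k]
                if len(run) < 2:
                    continue
                a, b = run[0].start, run[-1].end
                if max(t.length for t in run) > 0.94 * (b - a):
                    continue
                if not try_place(chrom, a, b):
                    continue
                affected = tuple(t.te_id for t in run)
                cat = SVCategory.MULTI_TE
            elif subtype == "internal_te":
                eligible = [
                    t
                    for t in top
                    if t.te_id not in anc.nested_host_ids and t.length >= 200
                ]
                if not eligible:
                    continue
                t = eligible[int(rng.integers(len(eligible)))]
                d_max = min(t.length - 40, int(0.94 * t.length))
                if d_max < 60:
                    continue
                d = int(rng.integers(60, d_max + 1))
                m1 = int(rng.integers(20, t.length - d - 20 + 1))
                a, b = t.start + m1, t.start + m1 + d
                if not try_place(chrom, a, b):
                    continue
                affected = (t.te_id,)
                cat = SVCategory.INCOMPLETE_TE
            elif subtype == "non_te":
                gaps = [
                    g
                    for g in _gaps(anc, chrom)
                    if g[1] - g[0] >= 60 + 2 * (cfg.min_gap // 2)
                ]
                if not gaps:
                    continue
                ga, gb = gaps[int(rng.integers(len(gaps)))]
                lo, hi = ga + cfg.min_gap // 2, gb - cfg.min_gap // 2
                d = int(rng.integers(60, min(hi - lo, 5000) + 1))
                a = int(rng.integers(lo, hi - d + 1))
                b = a + d
                if not try_place(chrom, a, b):
                    continue
                affected = ()
                cat = SVCategory.NO_TE
            elif subtype == "intron":
                genes = [g for g in anc.genes if len(g.exons) >= 2]
                if not genes:
                    raise ValueError("intron deletions require simulated genes")
                g = genes[int(rng.integers(len(genes)))]
                introns = [
                    (g.exons[j][1], g.exons[j + 1][0])
                    for j in range(len(g.exons) - 1)
                    if g.exons[j + 1][0] - g.exons[j][1] >= 100
                ]
                if not introns:
                    continue
                ia, ib = introns[int(rng.integers(len(introns)))]
                d = int(rng.integers(60, ib - ia - 20 + 1))
                a = int(rng.integers(ia + 10, ib - 10 - d + 1))
                b = a + d
                chrom = g.chrom
                if not try_place(chrom, a, b):
                    continue
                affected = ()
                cat = SVCategory.NO_TE
            else:  # pragma: no cover
                raise ValueError(f"unknown deletion subtype {subtype!r}")
            truth.append(
                TruthEvent(
                    event_id=new_id("del"),
                    event_type=EventType.DELETION,
                    subtype=subtype,
                    lineage=queries_only(),
                    chrom=chrom,
                    anc_start=a,
                    anc_end=b,
                    affected_te_ids=affected,
                    expected_sv_category=cat,
                    expected_indel_call=(
                        IndelCall.PUTATIVE_DELETION
                        if cat
                        not in (SVCategory.NO_TE, SVCategory.TE_EQ_SV)
                        else IndelCall.UNASSIGNED
                        if cat is SVCategory.NO_TE
                        else IndelCall.PUTATIVE_INSERTION
                    ),
                )
            )
            return
        raise RuntimeError(f"could not place {subtype} deletion after max retries")

    for subtype, n in (
        ("single_te", cfg.n_del_single_te),
        ("multi_te", cfg.n_del_multi_te),
        ("internal_te", cfg.n_del_internal_te),
        ("non_te", cfg.n_del_non_te),
        ("intron", cfg.n_del_intron),
    ):
        for _ in range(n):
            plant_deletion(subtype)

    # --- small indels, unalignable blocks, missing gaps ---------------
    def plant_simple(event_type: EventType, n: int, len_lo: int, len_hi: int):
        for _ in range(n):
            for _attempt in range(cfg.max_retries):
                chrom = pick_chrom()
                gaps = [g for g in _gaps(anc, chrom) if g[1] - g[0] >= len_hi + 40]
                if not gaps:
                    continue
                ga, gb = gaps[int(rng.integers(len(gaps)))]
                if event_type is EventType.SMALL_INDEL and rng.random() < 0.5:
                    # insertion flavour: zero ancestral footprint
                    d = 0
                    qlen = int(rng.integers(len_lo, len_hi + 1))
                else:
                    d = int(rng.integers(len_lo, len_hi + 1))
                    qlen = 0
                if event_type is EventType.UNALIGNABLE:
                    qlen = d + int(rng.integers(1, 30)) * (1 if rng.random() < 0.5 else -1)
                    qlen = max(qlen, 1)
                    if qlen == d:
                        qlen = d + 1
                a = int(rng.integers(ga + 20, gb - 20 - max(d, 1) + 1))
                b = a + d
                if not try_place(chrom, a, b):
                    continue
                truth.append(
                    TruthEvent(
                        event_id=new_id("evt"),
                        event_type=event_type,
                        subtype=event_type.value.lower(),
                        lineage=(
                            "ref"
                            if event_type is EventType.MISSING
                            else queries_only()
                        ),
                        chrom=chrom,
                        anc_start=a,
                        anc_end=b,
                        query_len=qlen,
                    )
                )
                break
            else:
                raise RuntimeError(f"could not place {event_type} after max retries")

    plant_simple(EventType.SMALL_INDEL, cfg.n_small_indels, 1, 50)
    plant_simple(EventType.UNALIGNABLE, cfg.n_unalignable, 60, 400)
    plant_simple(EventType.MISSING, cfg.n_missing, 100, 1000)

    # --- SNPs ----------------------------------------------------------
    snps_by_query: dict[str, dict[str, np.ndarray]] = {}
    for q in cfg.query_names:
        snps_by_query[q] = {}
        for chrom, clen in anc.chrom_lengths.items():
            mask = rng.random(clen) < cfg.snp_rate
            # no SNPs inside or adjacent to planted events of this pair
            for ev in truth:
                if ev.chrom != chrom:
                    continue
                if ev.lineage in (q, "ref") or ev.event_type is EventType.MISSING:
                    mask[max(ev.anc_start - 2, 0) : ev.anc_end + 2] = False
            for blk in cfg.ibs_blocks:
                if blk.chrom == chrom and q in blk.queries:
                    mask[blk.start : blk.end] = False
            mask[: cfg.edge_margin] = False
            mask[clen - cfg.edge_margin :] = False
            snps_by_query[q][chrom] = np.flatnonzero(mask).astype(np.int64)

    return _assemble(anc, cfg, truth, snps_by_query)


# ---------------------------------------------------------------------------
# Assembly of per-pair alignments, annotations and truth coordinates
# ---------------------------------------------------------------------------


def _offset_maps(events: list[TruthEvent], lineage: str):
    """Per-chromosome breakpoints for mapping ancestor -> derived coordinates.

    Returns chrom -> (positions, cumulative offset after each position):
    the derived coordinate of ancestral position x (not deleted) is
    x + offset, with offset constant between breakpoints.  Query
    coordinates follow the aligned-bases convention of the GVCF
    condenser, so missing-data gaps (which carry no query coordinates)
    subtract from every query genome's coordinate system.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[TruthEvent]] = {}
    for ev in events:
        if ev.event_type is EventType.MISSING:
            if lineage == "ref":
                continue  # the reference keeps (and counts) its gap bases
        elif ev.lineage != lineage:
            continue
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda e: e.anc_start)
        pos, off = [], []
        delta = 0
        for ev in evs:
            if ev.event_type is EventType.TE_INSERTION:
                delta += ev.inserted_len
                pos.append(ev.anc_start)
            elif ev.event_type is EventType.DELETION:
                delta -= ev.anc_end - ev.anc_start
                pos.append(ev.anc_end)
            elif ev.event_type is EventType.SMALL_INDEL:
                delta += ev.query_len - (ev.anc_end - ev.anc_start)
                pos.append(ev.anc_end)
            elif ev.event_type is EventType.UNALIGNABLE:
                delta += ev.query_len - (ev.anc_end - ev.anc_start)
                pos.append(ev.anc_end)
            elif ev.event_type is EventType.MISSING:
                delta -= ev.anc_end - ev.anc_start
                pos.append(ev.anc_end)
            else:
                continue
            off.append(delta)
        out[chrom] = (np.asarray(pos, dtype=np.int64), np.asarray(off, dtype=np.int64))
    return out


def _map_pos(maps, chrom: str, x: int) -> int:
    if chrom not in maps:
        return x
    pos, off = maps[chrom]
    i = int(np.searchsorted(pos, x, side="right"))
    return x + (int(off[i - 1]) if i > 0 else 0)


def _assemble(anc, cfg, truth, snps_by_query) -> SimResult:
    ref_events = [e for e in truth if e.lineage == "ref"]
    ref_maps = _offset_maps(truth, "ref")

    # derived coordinates for every event on its carrier genome
    maps_by_genome = {"ref": ref_maps}
    for q in cfg.query_names:
        maps_by_genome[q] = _offset_maps(truth, q)
    for ev in truth:
        m = maps_by_genome[ev.lineage]
        if ev.event_type is EventType.TE_INSERTION:
            ev.derived_start = _map_pos(m, ev.chrom, ev.anc_start - 1) + 1
            ev.derived_end = ev.derived_start + ev.inserted_len
        elif ev.event_type is EventType.DELETION:
            ev.derived_start = ev.derived_end = _map_pos(m, ev.chrom, ev.anc_end)
        # SV coordinates: on the lineage retaining the sequence
        if ev.event_type is EventType.TE_INSERTION:
            ev.sv_lineage = "ref" if ev.lineage == "ref" else "query"
            ev.sv_start, ev.sv_end = ev.derived_start, ev.derived_end
            if ev.lineage == "ref":
                ev.anchor_start, ev.anchor_end = ev.sv_start, ev.sv_end
            else:
                point = _map_pos(ref_maps, ev.chrom, ev.anc_start)
                ev.anchor_start = ev.anchor_end = point
        elif ev.event_type is EventType.DELETION:
            # sequence retained by the reference (deletions are planted in queries)
            ev.sv_lineage = "ref"
            ev.sv_start = _map_pos(ref_maps, ev.chrom, ev.anc_start)
            ev.sv_end = ev.sv_start + (ev.anc_end - ev.anc_start)
            ev.anchor_start, ev.anchor_end = ev.sv_start, ev.sv_end

    # --- per-genome chromosome lengths and annotations -----------------
    chrom_lengths: dict[str, dict[str, int]] = {}
    for genome in ["ref"] + cfg.query_names:
        m = maps_by_genome[genome]
        chrom_lengths[genome] = {
            chrom: _map_pos(m, chrom, clen) for chrom, clen in anc.chrom_lengths.items()
        }

    tes_by_genome: dict[str, list[TEAnnotation]] = {}
    genes_by_genome: dict[str, list[GeneAnnotation]] = {}
    for genome in ["ref"] + cfg.query_names:
        m = maps_by_genome[genome]
        own_events = [e for e in truth if e.lineage == genome]
        del_spans = {
            c: sorted(
                (e.anc_start, e.anc_end)
                for e in own_events
                if e.event_type is EventType.DELETION and e.chrom == c
            )
            for c in anc.chrom_lengths
        }

        def surviving_span(chrom, start, end):
            """Remnant of [start, end) after this genome's deletions; None if gone."""
            lost_lead = lost_total = 0
            for a, b in del_spans.get(chrom, []):
                ov = min(b, end) - max(a, start)
                if ov > 0:
                    lost_total += ov
                    if a <= start:
                        lost_lead += ov
            if end - start - lost_total <= 0:
                return None
            s = _map_pos(m, chrom, start) if lost_lead == 0 else _map_pos(m, chrom, start + lost_lead)
            return (s, s + (end - start - lost_total))

        out_tes = []
        for t in anc.tes:
            span = surviving_span(t.chrom, t.start, t.end)
            if span is None:
                continue
            out_tes.append(
                TEAnnotation(
                    te_id=t.te_id,
                    chrom=t.chrom,
                    start=span[0],
                    end=span[1],
                    strand=t.strand,
                    superfamily=t.superfamily,
                    family=t.family,
                    method=t.method,
                    ltr_identity=t.ltr_identity,
                )
            )
        # inserted TEs exactly span their insertion
        catalog = {f.family: f for f in cfg.family_catalog}
        for ev in own_events:
            if ev.event_type is not EventType.TE_INSERTION:
                continue
            spec = catalog[ev.family]
            ident = 1.0 if spec.superfamily in {"RLC", "RLG", "RLX"} else None
            out_tes.append(
                TEAnnotation(
                    te_id=f"{genome}_{ev.event_id}",
                    chrom=ev.chrom,
                    start=ev.derived_start,
                    end=ev.derived_end,
                    strand="+",
                    superfamily=spec.superfamily,
                    family=spec.family,
                    method="structural",
                    ltr_identity=ident,
                )
            )
        out_tes.sort(key=lambda t: (t.chrom, t.start))
        tes_by_genome[genome] = out_tes

        out_genes = []
        for g in anc.genes:
            span = surviving_span(g.chrom, g.gene_start, g.gene_end)
            if span is None:
                continue
            exons = []
            for a, b in g.exons:
                es = surviving_span(g.chrom, a, b)
                if es is not None:
                    exons.append(es)
            if not exons:
                continue
            out_genes.append(
                GeneAnnotation(
                    gene_id=g.gene_id,
                    chrom=g.chrom,
                    gene_start=span[0],
                    gene_end=span[1],
                    exons=tuple(exons),
                    syntenic=g.syntenic,
                    strand=g.strand,
                )
            )
        genes_by_genome[genome] = out_genes

    # --- per-pair token streams and partitions -------------------------
    tokens: dict[str, dict[str, list[tuple[SegClass, int, int]]]] = {}
    partitions: dict[str, PairPartition] = {}
    for q in cfg.query_names:
        pair_events = [
            e
            for e in truth
            if e.lineage in ("ref", q)
            and e.event_type
            in (
                EventType.TE_INSERTION,
                EventType.DELETION,
                EventType.SMALL_INDEL,
                EventType.UNALIGNABLE,
                EventType.MISSING,
            )
        ]
        tok: dict[str, list[tuple[SegClass, int, int]]] = {}
        snps_ref: dict[str, np.ndarray] = {}
        snps_query: dict[str, np.ndarray] = {}
        segments: dict[str, list] = {}
        q_maps = maps_by_genome[q]
        for chrom, clen in anc.chrom_lengths.items():
            evs = sorted(
                (e for e in pair_events if e.chrom == chrom),
                key=lambda e: (e.anc_start, e.anc_end),
            )
            stream: list[tuple[SegClass, int, int]] = []
            cursor = 0
            for ev in evs:
                if ev.anc_start > cursor:
                    n = ev.anc_start - cursor
                    stream.append((SegClass.ALIGNABLE, n, n))
                span = ev.anc_end - ev.anc_start
                if ev.event_type is EventType.TE_INSERTION:
                    if ev.lineage == "ref":
                        stream.append((SegClass.SV_REF, ev.inserted_len, 0))
                    else:
                        stream.append((SegClass.SV_QUERY, 0, ev.inserted_len))
                elif ev.event_type is EventType.DELETION:
                    stream.append((SegClass.SV_REF, span, 0))
                elif ev.event_type is EventType.SMALL_INDEL:
                    stream.append((SegClass.ALIGNABLE, span, ev.query_len))
                elif ev.event_type is EventType.UNALIGNABLE:
                    stream.append((SegClass.UNALIGNABLE, span, ev.query_len))
                elif ev.event_type is EventType.MISSING:
                    stream.append((SegClass.MISSING, span, 0))
                cursor = ev.anc_end
            if cursor < clen:
                n = clen - cursor
                stream.append((SegClass.ALIGNABLE, n, n))
            tok[chrom] = stream

            b = _ChromBuilder(chrom, chrom)
            for cls, rl, ql in stream:
                b.add(cls, rl, ql)
            segments[chrom] = b.segments
            anc_snps = snps_by_query[q][chrom]
            snps_ref[chrom] = np.asarray(
                [_map_pos(ref_maps, chrom, int(s)) for s in anc_snps], dtype=np.int64
            )
            snps_query[chrom] = np.asarray(
                [_map_pos(q_maps, chrom, int(s)) for s in anc_snps], dtype=np.int64
            )
        tokens[q] = tok
        partitions[q] = PairPartition(
            comparison_id=f"ref_vs_{q}",
            segments=segments,
            snp_positions_ref=snps_ref,
            snp_positions_query=snps_query,
            chrom_lengths_ref=chrom_lengths["ref"],
            chrom_lengths_query=chrom_lengths[q],
        )

    return SimResult(
        config=cfg,
        ancestor=anc,
        truth=truth,
        partitions=partitions,
        tes_by_genome=tes_by_genome,
        genes_by_genome=genes_by_genome,
        chrom_lengths=chrom_lengths,
        snps_by_query=snps_by_query,
        tokens=tokens,
    )


def simulate(cfg: SimConfig) -> SimResult:
    """Convenience wrapper: ancestor simulation plus haplotype derivation."""
    return derive_haplotypes(simulate_ancestor(cfg), cfg)


# ---------------------------------------------------------------------------
# GVCF emission (pairwise alignment as a VCF with non-variant blocks)
# ---------------------------------------------------------------------------


def write_gvcf(sim: SimResult, query: str, path) -> None:
    """Write the ref-vs-query alignment of a simulation as a GVCF.

    Allele strings are length-correct placeholders (reference bases 'A',
    alternate bases 'C', SNP alternates 'G'); no analysis stage depends
    on base content.  Non-variant blocks carry END tags; indel records
    are anchored one base left of the event, VCF-style; missing-data
    gaps are simply uncovered.
    """
    tok = sim.tokens[query]
    snps_ref = sim.partitions[query].snp_positions_ref
    ref_lengths = sim.chrom_lengths["ref"]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##ALT=<ID=NON_REF,Description="Non-reference block">\n')
        for chrom, clen in ref_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={clen}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, stream in tok.items():
            snps = snps_ref.get(chrom, np.asarray([], dtype=np.int64))
            ref_pos = 0

            def write_block(a: int, b: int):
                """Non-variant block [a, b) split at SNPs (ref coords)."""
                i = np.searchsorted(snps, a, side="left")
                j = np.searchsorted(snps, b, side="left")
                cur = a
                for s in snps[i:j]:
                    s = int(s)
                    if s > cur:
                        fh.write(f"{chrom}\t{cur + 1}\t.\tA\t<NON_REF>\t.\t.\tEND={s}\n")
                    fh.write(f"{chrom}\t{s + 1}\t.\tA\tG\t.\t.\t.\n")
                    cur = s + 1
                if b > cur:
                    fh.write(f"{chrom}\t{cur + 1}\t.\tA\t<NON_REF>\t.\t.\tEND={b}\n")

            def is_indel(token) -> bool:
                cls, rl, ql = token
                return cls in (SegClass.SV_REF, SegClass.SV_QUERY) or (
                    cls is SegClass.ALIGNABLE and rl != ql
                )

            for idx, (cls, rl, ql) in enumerate(stream):
                if cls is SegClass.ALIGNABLE and rl == ql:
                    end = ref_pos + rl
                    # leave the last base to anchor a following indel record
                    if idx + 1 < len(stream) and is_indel(stream[idx + 1]):
                        end -= 1
                    write_block(ref_pos, end)
                elif cls in (SegClass.ALIGNABLE, SegClass.SV_REF, SegClass.SV_QUERY):
                    # one-sided indel anchored at the previous reference base
                    if ql == 0:
                        ref_allele = "A" * (rl + 1)
                        alt_allele = "A"
                    elif rl == 0:
                        ref_allele = "A"
                        alt_allele = "A" + "C" * ql
                    else:  # pragma: no cover - simulator emits one-sided only
                        raise ValueError("two-sided ALIGNABLE token cannot be written")
                    fh.write(
                        f"{chrom}\t{ref_pos}\t.\t{ref_allele}\t{alt_allele}\t.\t.\t.\n"
                    )
                elif cls is SegClass.UNALIGNABLE:
                    fh.write(
                        f"{chrom}\t{ref_pos + 1}\t.\t{'A' * rl}\t{'C' * ql}\t.\t.\t.\n"
                    )
                elif cls is SegClass.MISSING:
                    pass  # uncovered gap
                ref_pos += rl


def truth_to_frame(truth: list[TruthEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                e.event_id,
                e.event_type.value,
                e.subtype,
                e.lineage,
                e.chrom,
                e.anc_start,
                e.anc_end,
                e.derived_start,
                e.derived_end,
                e.sv_lineage,
                e.sv_start,
                e.sv_end,
                e.anchor_start,
                e.anchor_end,
                ",".join(e.affected_te_ids),
                e.inserted_len,
                e.expected_sv_category.value if e.expected_sv_category else "",
                e.expected_indel_call.value if e.expected_indel_call else "",
                e.family,
            )
            for e in truth
        ],
        columns=[
            "event_id",
            "event_type",
            "subtype",
            "lineage",
            "chrom",
            "anc_start",
            "anc_end",
            "derived_start",
            "derived_end",
            "sv_lineage",
            "sv_start",
            "sv_end",
            "anchor_start",
            "anchor_end",
            "affected_te_ids",
            "inserted_len",
            "expected_sv_category",
            "expected_indel_call",
            "family",
        ],
    )
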
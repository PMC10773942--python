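"""TE and gene annotation handling: GFF3 I/O and quality-control filtering.

The filtering reproduces the cleanup a pan-genome TE annotation
(panEDTA-style, mixing structural and homology-based calls) needs before
presence/absence analysis: drop helitrons and non-TE repeats, drop the
LTR sub-features so only the full-length element span remains, collapse
coordinate-identical duplicates, and resolve biologically unfeasible
overlaps between annotations with a fixed, seeded rule set.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# superfamily codes: class I retrotransposons (RL* LTR, RIL LINE) and
# class II DNA/TIR transposons (DT*)
CLASS_I = {"RLC", "RLG", "RLX", "RIL"}
CLASS_II = {"DTA", "DTC", "DTH", "DTM", "DTT"}
SUPERFAMILIES = CLASS_I | CLASS_II

# panEDTA "Classification" attribute -> superfamily code
CLASSIFICATION_MAP = {
    "LTR/Copia": "RLC",
    "LTR/Gypsy": "RLG",
    "LTR/unknown": "RLX",
    "LTR/Unknown": "RLX",
    "LINE/L1": "RIL",
    "LINE/unknown": "RIL",
    "DNA/DTA": "DTA",
    "DNA/DTC": "DTC",
    "DNA/DTH": "DTH",
    "DNA/DTM": "DTM",
    "DNA/DTT": "DTT",
    "MITE/DTA": "DTA",
    "MITE/DTC": "DTC",
    "MITE/DTH": "DTH",
    "MITE/DTM": "DTM",
    "MITE/DTT": "DTT",
}

HELITRON_CLASSIFICATIONS = {"DNA/Helitron", "RC/Helitron"}
# structural LTR sub-features annotated alongside the full-length element
LTR_SUBFEATURE_TYPES = {
    "long_terminal_repeat",
    "target_site_duplication",
    "LTR_retrotransposon_ltr",
}


def _te_class(superfamily: str) -> str:
    return "I" if superfamily in CLASS_I else "II"


@dataclass(frozen=True)
class TEAnnotation:
    """A transposable-element annotation (0-based half-open coordinates)."""

    te_id: str
    chrom: str
    start: int
    end: int
    strand: str
    superfamily: str
    family: str
    method: str  # "structural" | "homology"
    ltr_identity: float | None = None
    feature_type: str = "transposable_element"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.te_id}: end ({self.end}) <= start ({self.start})")
        if self.superfamily in SUPERFAMILIES:
            if self.ltr_identity is not None and (
                self.method != "structural"
                or self.superfamily not in {"RLC", "RLG", "RLX"}
            ):
                raise ValueError(
                    f"{self.te_id}: ltr_identity only valid for structural LTR elements"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def te_class(self) -> str:
        return _te_class(self.superfamily)

    @property
    def is_structural(self) -> bool:
        return self.method == "structural"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with merged exon intervals and a synteny flag."""

    gene_id: str
    chrom: str
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...]
    syntenic: bool
    strand: str = "+"

    def __post_init__(self):
        for a, b in self.exons:
            if not (self.gene_start <= a < b <= self.gene_end):
                raise ValueError(f"{self.gene_id}: exon [{a},{b}) outside gene span")

    @property
    def exon_intervals(self) -> list[tuple[int, int]]:
        return merge_intervals(list(self.exons))

    @property
    def span_intervals(self) -> list[tuple[int, int]]:
        return [(self.gene_start, self.gene_end)]


def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent intervals into a sorted disjoint set."""
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


# ---------------------------------------------------------------------------
# GFF3 I/O (panEDTA attribute dialect)
# ---------------------------------------------------------------------------


def _parse_attributes(s: str) -> dict[str, str]:
    out = {}
    for item in s.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


@dataclass
class RawFeature:
    """One GFF3 line prior to TE interpretation (kept for filtering decisions)."""

    chrom: str
    source: str
    ftype: str
    start: int  # 0-based half-open
    end: int
    strand: str
    attributes: dict[str, str]


def read_gff3_features(path) -> list[RawFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            feats.append(
                RawFeature(
                    chrom=f[0],
                    source=f[1],
                    ftype=f[2],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    strand=f[6],
                    attributes=_parse_attributes(f[8]),
                )
            )
    return feats


def _feature_superfamily(f: RawFeature) -> str | None:
    attrs = f.attributes
    if "Superfamily" in attrs:
        sf = attrs["Superfamily"]
        return sf if sf in SUPERFAMILIES else None
    cls = attrs.get("Classification", "")
    return CLASSIFICATION_MAP.get(cls)


def _is_helitron(f: RawFeature) -> bool:
    return (
        f.attributes.get("Classification") in HELITRON_CLASSIFICATIONS
        or "helitron" in f.ftype.lower()
    )


def read_te_gff3(path) -> list[TEAnnotation]:
    """Read TE annotations, keeping every feature interpretable as a TE.

    Non-TE rows (helitrons, unknown repeats, LTR sub-features) are kept at
    this stage with ``superfamily`` placeholders so that :func:`prefilter`
    can remove them with explicit reason codes.
    """
    tes = []
    for i, f in enumerate(read_gff3_features(path)):
        sf = _feature_superfamily(f)
        te_id = f.attributes.get("ID") or f.attributes.get("Name") or f"te{i}"
        family = f.attributes.get("Name") or f.attributes.get("Family") or te_id
        method = f.attributes.get("Method", "homology")
        ident = f.attributes.get("Identity") or f.attributes.get("ltr_identity")
        if sf is None:
            # tagged for prefilter; keep the raw classification for logging
            sf = "HELITRON" if _is_helitron(f) else "NON_TE"
        ltr_identity = None
        if ident is not None and sf in {"RLC", "RLG", "RLX"} and method == "structural":
            ltr_identity = float(ident)
        tes.append(
            TEAnnotation(
                te_id=te_id,
                chrom=f.chrom,
                start=f.start,
                end=f.end,
                strand=f.strand,
                superfamily=sf,
                family=family,
                method=method,
                ltr_identity=ltr_identity,
                feature_type=f.ftype,
            )
        )
    return tes


def write_te_gff3(tes: list[TEAnnotation], path, source: str = "tesv") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in sorted(tes, key=lambda t: (t.chrom, t.start, t.end, t.te_id)):
            attrs = (
                f"ID={t.te_id};Name={t.family};Superfamily={t.superfamily};"
                f"Method={t.method}"
            )
            if t.ltr_identity is not None:
                attrs += f";Identity={t.ltr_identity:.4f}"
            fh.write(
                f"{t.chrom}\t{source}\t{t.feature_type}\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )


def read_gene_gff3(path, synteny_tsv=None) -> list[GeneAnnotation]:
    """Read gene + exon features; synteny comes from a two-column TSV
    (gene_id, syntenic yes/no) or a ``syntenic=`` attribute on the gene row."""
    synteny: dict[str, bool] = {}
    if synteny_tsv is not None:
        df = pd.read_csv(synteny_tsv, sep="\t", header=None, names=["gene_id", "flag"])
        synteny = {
            str(r.gene_id): str(r.flag).lower() in ("1", "true", "yes", "syntenic")
            for r in df.itertuples()
        }
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for f in read_gff3_features(path):
        if f.ftype == "gene":
            gid = f.attributes.get("ID", f"gene_{f.chrom}_{f.start}")
            genes[gid] = {
                "chrom": f.chrom,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "syntenic": f.attributes.get("syntenic", "").lower()
                in ("1", "true", "yes"),
            }
        elif f.ftype == "exon":
            parent = f.attributes.get("Parent", "")
            exons.setdefault(parent, []).append((f.start, f.end))
    out = []
    for gid, g in genes.items():
        ex = merge_intervals(exons.get(gid, [(g["start"], g["end"])]))
        out.append(
            GeneAnnotation(
                gene_id=gid,
                chrom=g["chrom"],
                gene_start=g["start"],
                gene_end=g["end"],
                exons=tuple(ex),
                syntenic=synteny.get(gid, g["syntenic"]),
                strand=g["strand"],
            )
        )
    return out


def write_gene_gff3(genes: list[GeneAnnotation], path, source: str = "tesv") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.gene_start)):
            syn = "yes" if g.syntenic else "no"
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.gene_start + 1}\t{g.gene_end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};syntenic={syn}\n"
            )
            for i, (a, b) in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


class RemovalReason(str, enum.Enum):
    HELITRON = "HELITRON"
    NON_TE = "NON_TE"
    LTR_SUBFEATURE = "LTR_SUBFEATURE"
    DROPPED_FAMILY = "DROPPED_FAMILY"
    DUPLICATE = "DUPLICATE"
    BOUNDARY_5BP = "BOUNDARY_5BP"
    HH_OVERLAP = "HH_OVERLAP"
    HS_OVERLAP = "HS_OVERLAP"
    SS_OVERLAP = "SS_OVERLAP"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass
class Removal:
    te_id: str
    reason: RemovalReason
    partner_id: str | None = None


def prefilter(
    annotations: list[TEAnnotation],
    drop_families: list[str] = ("DTA_ZM00081_consensus",),
) -> tuple[list[TEAnnotation], list[Removal]]:
    """Drop helitrons, non-TE repeats, LTR sub-features and listed families.

    Full-length structural LTR spans are retained; their
    long_terminal_repeat / target_site_duplication sub-feature records are
    removed so that each element is represented once by its full span.
    Features of unknown type that still carry a valid superfamily pass
    through with a logged warning.
    """
    drop_families = set(drop_families or ())
    kept: list[TEAnnotation] = []
    removed: list[Removal] = []
    for t in annotations:
        if t.feature_type in LTR_SUBFEATURE_TYPES:
            removed.append(Removal(t.te_id, RemovalReason.LTR_SUBFEATURE))
        elif t.superfamily == "HELITRON":
            removed.append(Removal(t.te_id, RemovalReason.HELITRON))
        elif t.superfamily == "NON_TE":
            removed.append(Removal(t.te_id, RemovalReason.NON_TE))
        elif t.family in drop_families:
            removed.append(Removal(t.te_id, RemovalReason.DROPPED_FAMILY))
        else:
            if t.feature_type not in (
                "transposable_element",
                "repeat_region",
            ) and not t.feature_type.endswith(("retrotransposon", "transposon", "TE")):
                logger.warning(
                    "unknown feature type %r for %s; passing through",
                    t.feature_type,
                    t.te_id,
                )
            kept.append(t)
    return kept, removed


def dedupe_identical(
    annotations: list[TEAnnotation], seed: int = 42
) -> tuple[list[TEAnnotation], list[Removal]]:
    """Collapse annotations with identical coordinates, superfamily and family.

    Structural annotations are preferred over homology ones; same-method
    ties are broken by a seeded RNG so runs are reproducible.
    """
    rng = np.random.default_rng(seed)
    groups: dict[tuple, list[TEAnnotation]] = {}
    order: list[tuple] = []
    for t in annotations:
        key = (t.chrom, t.start, t.end, t.superfamily, t.family)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(t)
    kept, removed = [], []
    for key in order:
        group = groups[key]
        if len(group) == 1:
            kept.append(group[0])
            continue
        structural = [t for t in group if t.is_structural]
        pool = structural if structural else group
        winner = pool[int(rng.integers(len(pool)))] if len(pool) > 1 else pool[0]
        kept.append(winner)
        for t in group:
            if t is not winner:
                removed.append(Removal(t.te_id, RemovalReason.DUPLICATE, winner.te_id))
    return kept, removed


def _overlap(a: TEAnnotation, b: TEAnnotation) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _contained(inner: TEAnnotation, outer: TEAnnotation) -> bool:
    return (
        inner.chrom == outer.chrom
        and outer.start <= inner.start
        and inner.end <= outer.end
    )


def _boundary_conflict(a: TEAnnotation, s: TEAnnotation, boundary_bp: int) -> bool:
    """True if any endpoint of ``a`` lies within ``boundary_bp`` (inclusive)
    of any endpoint of structural annotation ``s``."""
    if a.chrom != s.chrom:
        return False
    return any(
        abs(x - y) <= boundary_bp
        for x in (a.start, a.end)
        for y in (s.start, s.end)
    )


def resolve_overlaps(
    annotations: list[TEAnnotation],
    boundary_bp: int = 5,
    hh_frac: float = 0.10,
    hs_frac: float = 0.05,
    seed: int = 42,
    hh_keep_longer: bool = False,
) -> tuple[list[TEAnnotation], list[Removal]]:
    """Resolve biologically unfeasible overlapping annotations.

    Four rules, applied in order to the survivors of the previous rule:

    1. *Boundary rule* — any annotation with a start or end within
       ``boundary_bp`` of a structural annotation's start or end is
       removed; when two structural annotations trigger it against each
       other the larger is kept (seeded RNG on exact size ties).
    2. *Homology–homology* — a homology annotation overlapping another
       homology annotation by more than ``hh_frac`` of its own length is
       removed (containment counts; by default both members of a mutually
       violating pair drop, ``hh_keep_longer=True`` keeps the longer).
    3. *Homology–structural* — a homology annotation overlapping a
       structural annotation by more than ``hs_frac`` of its own length
       and not fully contained within it is removed; full containment
       exempts (nested fragments are real).
    4. *Structural–structural* — of two overlapping, non-nested structural
       annotations, class II wins over class I, then the longer; seeded
       RNG on full ties.

    Every removal carries a machine-readable reason code and the partner
    annotation that triggered it.
    """
    rng = np.random.default_rng(seed)
    removed: list[Removal] = []
    alive: list[TEAnnotation] = sorted(
        annotations, key=lambda t: (t.chrom, t.start, t.end, t.te_id)
    )

    def pairs_near(items, max_gap):
        """Yield index pairs within max_gap bp (sorted by chrom/start)."""
        for i in range(len(items)):
            a = items[i]
            for j in range(i + 1, len(items)):
                b = items[j]
                if b.chrom != a.chrom or b.start > a.end + max_gap:
                    break
                yield i, j

    # --- rule 1: boundary conflicts -----------------------------------
    structural = [t for t in alive if t.is_structural]
    drop_ids: set[str] = set()
    # structural-vs-structural conflicts first: keep the larger
    ss_partners: dict[str, str] = {}
    for i, j in pairs_near(structural, boundary_bp):
        a, b = structural[i], structural[j]
        if a.te_id in drop_ids or b.te_id in drop_ids:
            continue
        if _boundary_conflict(a, b, boundary_bp):
            if a.length > b.length:
                loser, winner = b, a
            elif b.length > a.length:
                loser, winner = a, b
            else:
                loser, winner = (a, b) if rng.integers(2) else (b, a)
            drop_ids.add(loser.te_id)
            ss_partners[loser.te_id] = winner.te_id
    surviving_structural = [t for t in structural if t.te_id not in drop_ids]
    for t in alive:
        if t.te_id in drop_ids or t.is_structural:
            continue
        for s in surviving_structural:
            if _boundary_conflict(t, s, boundary_bp):
                drop_ids.add(t.te_id)
                ss_partners[t.te_id] = s.te_id
                break
    for tid in sorted(drop_ids):
        removed.append(Removal(tid, RemovalReason.BOUNDARY_5BP, ss_partners.get(tid)))
    alive = [t for t in alive if t.te_id not in drop_ids]

    # --- rule 2: homology-homology overlap ----------------------------
    homology = [t for t in alive if not t.is_structural]
    hh_drop: dict[str, str] = {}
    for i, j in pairs_near(homology, 0):
        a, b = homology[i], homology[j]
        ov = _overlap(a, b)
        if ov == 0:
            continue
        a_viol = ov > hh_frac * a.length
        b_viol = ov > hh_frac * b.length
        if hh_keep_longer and a_viol and b_viol:
            loser = a if a.length < b.length else b
            winner = b if loser is a else a
            hh_drop.setdefault(loser.te_id, winner.te_id)
            continue
        if a_viol:
            hh_drop.setdefault(a.te_id, b.te_id)
        if b_viol:
            hh_drop.setdefault(b.te_id, a.te_id)
    for tid, partner in sorted(hh_drop.items()):
        removed.append(Removal(tid, RemovalReason.HH_OVERLAP, partner))
    alive = [t for t in alive if t.te_id not in hh_drop]

    # --- rule 3: homology-structural overlap --------------------------
    structural = [t for t in alive if t.is_structural]
    hs_drop: dict[str, str] = {}
    for t in alive:
        if t.is_structural:
            continue
        for s in structural:
            ov = _overlap(t, s)
            if ov > hs_frac * t.length and not _contained(t, s):
                hs_drop[t.te_id] = s.te_id
                break
    for tid, partner in sorted(hs_drop.items()):
        removed.append(Removal(tid, RemovalReason.HS_OVERLAP, partner))
    alive = [t for t in alive if t.te_id not in hs_drop]

    # --- rule 4: structural-structural overlap ------------------------
    structural = [t for t in alive if t.is_structural]
    ss_drop: dict[str, str] = {}
    for i, j in pairs_near(structural, 0):
        a, b = structural[i], structural[j]
        if a.te_id in ss_drop or b.te_id in ss_drop:
            continue
        if _overlap(a, b) == 0 or _contained(a, b) or _contained(b, a):
            continue
        # class II preferred, then longer, then seeded random
        def rank(t):
            return (t.te_class == "II", t.length)

        if rank(a) > rank(b):
            loser, winner = b, a
        elif rank(b) > rank(a):
            loser, winner = a, b
        else:
            loser, winner = (a, b) if rng.integers(2) else (b, a)
        ss_drop[loser.te_id] = winner.te_id
    for tid, partner in sorted(ss_drop.items()):
        removed.append(Removal(tid, RemovalReason.SS_OVERLAP, partner))
    alive = [t for t in alive if t.te_id not in ss_drop]

    return alive, removed


def filter_annotations(
    annotations: list[TEAnnotation],
    drop_families: list[str] = ("DTA_ZM00081_consensus",),
    boundary_bp: int = 5,
    hh_frac: float = 0.10,
    hs_frac: float = 0.05,
    seed: int = 42,
    hh_keep_longer: bool = False,
) -> tuple[list[TEAnnotation], list[Removal]]:
    """Full pipeline: prefilter -> dedupe -> overlap resolution."""
    kept, r1 = prefilter(annotations, drop_families)
    kept, r2 = dedupe_identical(kept, seed=seed)
    kept, r3 = resolve_overlaps(
        kept,
        boundary_bp=boundary_bp,
        hh_frac=hh_frac,
        hs_frac=hs_frac,
        seed=seed,
        hh_keep_longer=hh_keep_longer,
    )
    return kept, r1 + r2 + r3


def removals_to_frame(removals: list[Removal]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.te_id, r.reason.value, r.partner_id or "") for r in removals],
        columns=["te_id", "reason", "partner_id"],
    )
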
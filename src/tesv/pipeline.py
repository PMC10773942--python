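"""End-to-end orchestration of one pairwise comparison.

partition -> filter annotations -> classify features -> classify SVs ->
detect SNP-depleted regions -> region-scoped summaries, with every table
written to a run directory and a manifest recording the configuration
hash, input checksums and package version.  One comparison per
invocation; :func:`aggregate_consistency` fans results from many
comparisons into pangenome bins.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from tesv import __version__
from tesv.annotations import (
    filter_annotations,
    read_gene_gff3,
    read_te_gff3,
    removals_to_frame,
    write_te_gff3,
)
from tesv.classify import (
    bin_consistency,
    bins_to_frame,
    calls_to_frame,
    classify_genes,
    classify_tes,
)
from tesv.config import RunConfig
from tesv.partition import condense_gvcf, read_segments, read_snp_bed, write_partition
from tesv.snp_depleted import (
    detect_regions,
    regions_to_beds,
    restrict_analysis,
    window_stats,
    windows_to_frame,
)
from tesv.summaries import status_by_superfamily
from tesv.svclass import (
    classify_svs,
    extract_svs,
    link_polymorphic_tes,
    svclasses_to_frame,
    tally_indel_bp,
)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    cfg: RunConfig,
    out_dir,
    gvcf: str | None = None,
    segments_tsv: str | None = None,
    snps_ref_bed: str | None = None,
    te_gff_ref: str | None = None,
    te_gff_query: str | None = None,
    gene_gff_ref: str | None = None,
    synteny_tsv: str | None = None,
    ref_name: str = "ref",
    query_name: str = "query",
    exon_only: bool = False,
) -> dict:
    """Run one pairwise comparison end to end; returns the manifest dict.

    Inputs: either a GVCF or a pre-condensed segment TSV (+ SNP BED), and
    per-genome TE GFF3s (optionally a gene GFF3 for the reference).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = {
        k: v
        for k, v in {
            "gvcf": gvcf,
            "segments_tsv": segments_tsv,
            "snps_ref_bed": snps_ref_bed,
            "te_gff_ref": te_gff_ref,
            "te_gff_query": te_gff_query,
            "gene_gff_ref": gene_gff_ref,
            "synteny_tsv": synteny_tsv,
        }.items()
        if v is not None
    }
    for name, path in inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {name!r} not found: {path}")

    # --- stage 1: alignment partition ----------------------------------
    if gvcf is not None:
        partition = condense_gvcf(
            gvcf, min_sv_len=cfg.min_sv_len, ref_name=ref_name, query_name=query_name
        )
    elif segments_tsv is not None:
        snps = read_snp_bed(snps_ref_bed) if snps_ref_bed else None
        partition = read_segments(
            segments_tsv,
            comparison_id=f"{ref_name}_vs_{query_name}",
            snps_ref=snps,
        )
    else:
        raise ValueError("either a GVCF or a segment TSV is required")
    write_partition(partition, out_dir)

    # --- stage 2: annotation filtering ---------------------------------
    tes = {}
    for lineage, path in (("ref", te_gff_ref), ("query", te_gff_query)):
        if path is None:
            continue
        raw = read_te_gff3(path)
        kept, removed = filter_annotations(
            raw,
            boundary_bp=cfg.boundary_bp,
            hh_frac=cfg.hh_frac,
            hs_frac=cfg.hs_frac,
            seed=cfg.seed,
            hh_keep_longer=cfg.hh_keep_longer,
        )
        tes[lineage] = kept
        write_te_gff3(kept, out_dir / f"te_filtered_{lineage}.gff3")
        removals_to_frame(removed).to_csv(
            out_dir / f"te_removed_{lineage}.tsv", sep="\t", index=False
        )

    # --- stage 3: feature classification -------------------------------
    calls = {}
    for lineage, te_set in tes.items():
        calls[lineage] = classify_tes(
            te_set, partition, lineage, threshold=cfg.share_threshold
        )
        calls_to_frame(calls[lineage]).to_csv(
            out_dir / f"te_calls_{lineage}.tsv", sep="\t", index=False
        )
        status_by_superfamily(calls[lineage], te_set).to_csv(
            out_dir / f"te_status_by_superfamily_{lineage}.tsv", sep="\t", index=False
        )
    if gene_gff_ref is not None:
        genes = read_gene_gff3(gene_gff_ref, synteny_tsv)
        gene_calls = classify_genes(
            genes, partition, "ref", exon_only=exon_only, threshold=cfg.share_threshold
        )
        calls_to_frame(gene_calls).to_csv(
            out_dir / "gene_calls_ref.tsv", sep="\t", index=False
        )

    # --- stage 4: SV classification ------------------------------------
    svcs = []
    for lineage, te_set in tes.items():
        svs = extract_svs(partition, lineage=lineage)
        svcs.extend(classify_svs(svs, te_set, threshold=cfg.sv_te_threshold))
    svclasses_to_frame(svcs).to_csv(out_dir / "sv_classes.tsv", sep="\t", index=False)
    ins_bp, del_bp, counts = tally_indel_bp(svcs)
    with open(out_dir / "indel_tally.json", "w") as fh:
        json.dump(
            {"insertion_bp": ins_bp, "deletion_bp": del_bp, "category_counts": counts},
            fh,
            indent=2,
        )

    links = {}
    from tesv.classify import Status

    for lineage, te_set in tes.items():
        poly_ids = {
            c.feature_id for c in calls[lineage] if c.status is Status.POLYMORPHIC
        }
        poly_tes = [t for t in te_set if t.te_id in poly_ids]
        own_svcs = [s for s in svcs if s.sv_record.lineage == lineage]
        links[lineage] = link_polymorphic_tes(
            poly_tes, own_svcs, threshold=cfg.sv_te_threshold
        )
    link_rows = [
        (lineage, te_id, sv_id or "UNLINKED", cat.value if cat else "")
        for lineage, m in links.items()
        for te_id, (sv_id, cat) in m.items()
    ]
    pd.DataFrame(link_rows, columns=["lineage", "te_id", "sv_id", "category"]).to_csv(
        out_dir / "te_sv_links.tsv", sep="\t", index=False
    )

    # --- stage 5: SNP-depleted regions ---------------------------------
    windows = window_stats(partition, window_bp=cfg.window_bp, step_bp=cfg.step_bp)
    regions = detect_regions(
        windows,
        min_run=cfg.min_run,
        window_bp=cfg.window_bp,
        step_bp=cfg.step_bp,
        alignable_floor=cfg.alignable_floor,
        rate_denom=cfg.rate_denom,
        trim_bp=cfg.trim_bp,
    )
    windows_to_frame(windows, cfg.alignable_floor, cfg.rate_denom).to_csv(
        out_dir / "windows.tsv", sep="\t", index=False
    )
    raw_bed, trimmed_bed = regions_to_beds(regions)
    raw_bed.to_csv(out_dir / "snp_depleted_raw.bed", sep="\t", index=False, header=False)
    trimmed_bed.to_csv(
        out_dir / "snp_depleted_trimmed.bed", sep="\t", index=False, header=False
    )

    # --- stage 6: region-scoped summaries ------------------------------
    region_summary = {}
    if regions:
        feats = {
            t.te_id: (t.chrom, t.start, t.end)
            for te_set in tes.values()
            for t in te_set
        }
        all_calls = [c for cs in calls.values() for c in cs]
        ref_svcs = [s for s in svcs if s.sv_record.lineage == "ref"]
        region_summary = restrict_analysis(
            regions, calls=all_calls, svcs=ref_svcs, features=feats
        )
        with open(out_dir / "region_summary.json", "w") as fh:
            json.dump(region_summary, fh, indent=2, default=str)

    manifest = {
        "tool": "tesv",
        "version": __version__,
        "comparison_id": partition.comparison_id,
        "config": asdict(cfg),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
        "n_segments": sum(len(s) for s in partition.segments.values()),
        "n_svs": len(svcs),
        "n_snp_depleted_regions": len(regions),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def aggregate_consistency(calls_tsvs: list, out_path) -> pd.DataFrame:
    """Fan-in: bin features into core / near-core / variable / private
    across many per-comparison call tables (one genome's features
    against many queries)."""
    from tesv.classify import FeatureCall, Status
    from fractions import Fraction

    per_feature: dict[str, list[FeatureCall]] = {}
    for path in calls_tsvs:
        df = pd.read_csv(path, sep="\t")
        for r in df.itertuples(index=False):
            per_feature.setdefault(r.feature_id, []).append(
                FeatureCall(
                    feature_id=r.feature_id,
                    comparison_id=r.comparison_id,
                    lineage=r.lineage,
                    status=Status(r.status),
                    frac_alignable=Fraction(str(r.frac_alignable)),
                    frac_sv_own=Fraction(str(r.frac_sv_own)),
                    frac_unalignable=Fraction(str(r.frac_unalignable)),
                )
            )
    bins = [bin_consistency(calls) for calls in per_feature.values()]
    df = bins_to_frame(bins)
    df.to_csv(out_path, sep="\t", index=False)
    return df
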
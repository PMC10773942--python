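# tesv — TE and structural variation between pairwise-aligned genomes

Plant pangenomes — maize above all — differ from one another mostly
through transposable elements (TEs): in any comparison of two maize
inbreds, hundreds of thousands of annotated TEs present in one genome
are absent from the other. Deciding *which* elements are shared and
which are polymorphic, and whether a given structural variant is a
simple TE insertion or a deletion that swept away several ancestral
elements, requires combining a base-resolved whole-genome alignment
with curated TE annotations. `tesv` is a library and command-line tool
for exactly that analysis. It is aimed at researchers who already have
pairwise whole-genome alignments in GVCF form (e.g. AnchorWave
alignments converted with tassel's `MAFToGVCF`) and per-genome TE/gene
annotations in GFF3 (panEDTA-style).

## What it computes

Given one reference-vs-query alignment, `tesv`:

1. **Partitions both genomes** into *alignable* sequence (non-variant
   blocks, SNVs, indels ≤ 50 bp), *structural-variant* sequence
   (one-sided indels > 50 bp: present in one genome, 0 bp in the
   other), and *unalignable/missing* sequence.
2. **Filters TE annotations** with reproducible QC rules: helitrons,
   non-TE repeats and LTR sub-features dropped; coordinate-identical
   duplicates collapsed (structural preferred); boundary artifacts
   (endpoints within 5 bp of a structural element's endpoints) and
   excessive homology overlaps (> 10% vs homology, > 5% vs structural
   unless fully nested) removed with machine-readable reasons.
3. **Calls each feature** shared (≥ 95% of its bases alignable),
   polymorphic (≥ 95% in own-lineage SV sequence) or ambiguous —
   thresholds evaluated in exact integer arithmetic — and aggregates
   calls across many comparisons into core / near-core / variable /
   private bins; LTR ages bin by terminal-repeat identity.
4. **Classifies every SV by its TE content** into five categories
   (No-TE, Incomplete-TE, TE = SV, Multi-TE, TE-within-SV; the 95%
   tests here are strict) and maps them to putative insertions
   (TE = SV) versus putative deletions (the other TE-containing
   classes), with base-pair tallies.
5. **Detects SNP-depleted regions** — ≥ 2 Mb identity-by-state blocks
   from shared pedigree — by scanning 1 Mb windows at 250 kb offsets
   for > 950 kb alignable sequence and a SNP rate below 1/10,000, then
   requiring ≥ 5 consecutive qualifying windows; regions are trimmed by
   100 kb per side for all scoped analyses, including per-family counts
   of TE = SV events that flag candidate currently-active families.
6. **Simulates** diverged genomes end to end — ancestral TE landscape,
   planted SNPs/insertions/deletions, identity-by-state blocks, GVCF
   and GFF3 emission — with a ground-truth table, so every stage can be
   validated against known answers.

See `docs/methods.md` for the precise definitions and numerical
conventions.

## Worked example

Simulate a 500 kb comparison with 5 planted TE insertions and 3
deletions of each kind, then run the full pipeline on the emitted files:

```bash
tesv simulate --seed 7 --genome-bp 500000 --n-queries 1 \
     --n-te-insertions 5 --n-deletions 3 --out-dir sim
# simulated 17 events over 1 queries

tesv run --gvcf sim/ref_vs_q1.gvcf --te-ref sim/te_ref.gff3 \
     --te-query sim/te_q1.gff3 --query-name q1 --out-dir out
# ref_vs_q1: 17 SVs, 0 SNP-depleted regions
```

`out/te_calls_ref.tsv` holds one row per reference TE with its status
and exact overlap fractions:

```
feature_id      comparison_id  lineage  status       frac_alignable  frac_sv_own  frac_unalignable
anc_te000001    ref_vs_q1      ref      SHARED       1.0             0.0          0.0
anc_te000002    ref_vs_q1      ref      POLYMORPHIC  0.0             1.0          0.0
```

In this run 79 reference TEs are SHARED, 16 POLYMORPHIC and 3 AMBIGUOUS:
the polymorphic ones sit inside the planted deletions (their sequence
exists in the reference but not the query), and the ambiguous ones are
the deletion-edge TEs whose internal fragment was removed.
`out/sv_classes.tsv` categorises each of the 17 SVs:

```
lineage  chrom  start  end    length  category      indel_call
ref      chr1   2999   3509   510     TE_WITHIN_SV  PUTATIVE_DELETION
ref      chr1   44985  56553  11568   MULTI_TE      PUTATIVE_DELETION
```

and `out/indel_tally.json` sums them by direction — the 5 planted
insertions (41,104 bp of TE = SV sequence) against 71,010 bp of
putative deletions:

```json
{"insertion_bp": 41104, "deletion_bp": 71010,
 "category_counts": {"NO_TE": 3, "INCOMPLETE_TE": 3, "TE_EQ_SV": 5,
                     "MULTI_TE": 3, "TE_WITHIN_SV": 3}}
```

Every planted event lands in its expected category: insertions as
TE = SV, multi-element deletions as Multi-TE, whole-element-plus-flank
deletions as TE-within-SV, internal truncations as Incomplete-TE, and
deletions of TE-free sequence as No-TE (left unassigned, since nothing
ties them to an insertion or deletion mechanism).

The same stages are available piecemeal (`tesv partition`,
`tesv filter-annotations`, `tesv classify`, `tesv classify-sv`,
`tesv snp-depleted`, `tesv report` for core/near-core/variable/private
aggregation) and as library functions (`tesv.condense_gvcf`,
`tesv.classify_feature`, `tesv.classify_sv`, ...).

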
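# Methods

`tesv` classifies transposable-element (TE) and structural variation
between pairs of whole-genome-aligned plant genomes — the setting is a
maize-style pangenome in which one reference inbred is compared against
many other assemblies — and ships a synthetic diverged-genome simulator
that provides exact ground truth for every stage. This note records the
model, the parameters that matter, the numerical choices, and what the
simulator does and does not emulate.

## The alignment partition

The input to everything is a pairwise whole-genome alignment expressed
as a GVCF: a VCF with `END`-tagged non-variant blocks, SNVs and indel
records, sorted on the reference. `condense_gvcf` folds these records
into segments that assign every base of both genomes to exactly one of
three analysis classes (plus a bookkeeping class):

* **alignable** — non-variant blocks, SNVs, equal-length substitutions
  and small (≤ 50 bp) one-sided indels. Sub-threshold indels are
  *absorbed*: an alignable segment may therefore have unequal reference
  and query lengths.
* **SV** — a one-sided indel with more than `min_sv_len` (default 50) bp
  on one side and 0 bp on the other. The floor is strict: a 51 bp
  one-sided indel is an SV, a 50 bp one is alignable. Query-carried SVs
  anchor at a zero-length reference point.
* **unalignable** — any record with at least one unmatched base pair on
  each side after stripping the common allele prefix; the whole record
  span is unalignable on both sides.
* **missing** — reference positions covered by no record (alignment
  gaps). Stored distinctly, pooled with unalignable in every downstream
  fraction. Missing spans carry no query coordinates, so the query
  coordinate system of a partition covers aligned query bases only.

Coordinates are 0-based half-open internally; GFF3/VCF 1-based
coordinates are converted at I/O. Equal-length multi-base substitutions
become alignable sequence with one SNP per mismatching position. SNP
positions are retained on both coordinate systems and always fall inside
alignable segments (a validated invariant). Unsorted or overlapping
records, multi-allelic sites and symbolic (non-block) alleles are hard
errors naming the offending record: this pipeline consumes one
haplotype-vs-haplotype alignment, not a population VCF.

## Feature classification

A feature (TE annotation, gene span, or merged exon set) on one lineage
is intersected with that lineage's segments. With at least 95% of its
bases alignable it is **shared** with the other genome; with at least
95% in own-lineage SV sequence it is **polymorphic** (present here,
absent there); anything else — partial overlaps, unalignable or missing
context — is **ambiguous**. The threshold is inclusive ("at least") and
evaluated in exact rational arithmetic on integer base-pair counts
(`Fraction(overlap, length) >= Fraction(19, 20)`), so a feature at
exactly 95.000% is classified without floating-point boundary artifacts.
Overlap accumulates across all segments of a class; strand is ignored.

Across many comparisons against the same reference, per-feature calls
aggregate into pangenome bins: **core** (shared in all n comparisons),
**near-core** (n−1 or n−2), **variable** (otherwise ≥ 1), **private**
(never shared). With the 25-comparison design this is core 25,
near-core 23–24, variable 1–22. LTR retrotransposon age uses the
identity between an element's two long terminal repeats: very young
(= 1), young [0.95, 1), moderate [0.90, 0.95), old [0.80, 0.90),
unbinned below.

## Annotation filtering

Pan-genome TE annotations of the panEDTA kind mix structural calls
(intact elements with terminal repeats and target-site duplications)
with homology fragments, and contain known artifacts. The filter chain
is: (i) drop helitrons, non-TE repeats, LTR sub-feature records (the
full-length element span is kept) and explicitly blacklisted families
(default `DTA_ZM00081_consensus`); (ii) collapse coordinate-identical
duplicates, preferring structural over homology and breaking same-method
ties with a seeded RNG; (iii) resolve unfeasible overlaps with four
rules applied in order:

1. **boundary** — an annotation whose start or end lies within 5 bp
   (inclusive) of a structural annotation's start or end is removed;
   two structural annotations triggering it against each other keep the
   larger (seeded RNG on exact ties). Homology annotations are judged
   against the structural survivors of this step.
2. **homology–homology** — overlap of more than 10% of the annotation's
   own length with another homology annotation removes it; a mutually
   violating pair loses both members (a `hh_keep_longer` switch keeps
   the longer instead, for the alternative reading).
3. **homology–structural** — more than 5% own-length overlap with a
   structural annotation removes the homology annotation *unless* it is
   fully contained (nested fragments are biologically real).
4. **structural–structural** — of two overlapping, non-nested structural
   annotations, class II (DNA/TIR) wins over class I (retrotransposon),
   then the longer; seeded RNG on full ties.

Both overlap denominators are the tested annotation's own length. Every
removal carries a machine-readable reason code and partner id, removals
partition the removed set, and an all-pairs brute-force checker verifies
in the test suite that no retained pair violates any rule.

## SV classification and insertion/deletion calling

Each SV is categorised by the filtered TE set of its own lineage. A TE
is *full* when more than 95% of its bases lie inside the SV (strict).
Decision order: no overlapping TE → **No-TE SV**; overlaps but no full
TE → **Incomplete-TE SV**; a full TE whose overlap also exceeds 95% of
the SV → **TE = SV** (the SV-side test uses the single best TE, and a
dominant TE with small nested fragments still counts as TE = SV);
two or more full TEs → **Multi-TE SV**; else **TE-within-SV**. Both
tests are strict: exactly 95.000% fails. TE = SV events are called
putative insertions (the element's boundaries explain the variant);
Incomplete/Multi/Within events are putative deletions of ancestral
sequence; No-TE SVs stay unassigned.

Polymorphic TEs link to the SV holding their largest overlap when it
exceeds 95% of the TE's length, else they are flagged unlinked.
Region-restricted tallies sum SV lengths by direction; an SV belongs to
a region set when at least 50% of its bases fall inside. Because
SNP-depleted regions are defined on reference coordinates while
query-carried SVs have query coordinates, every SV carries a
reference-side anchor (its own span, or the zero-length insertion
point), and membership is judged on the anchor — a query insertion is
in-region iff its insertion point is.

## SNP-depleted (identity-by-state) regions

Recently co-inherited haplotype blocks show SNP rates far below the
~1-per-44-bp background of diverged maize inbreds. Windows of 1 Mb at
250 kb offsets, anchored at position 0 of each reference chromosome,
are scored for SNP count and alignable bp; a window qualifies when
alignable bp > 950,000 (strict) and `snp_count × 10,000 < alignable_bp`
(the exact-integer form of rate < 1/10,000; zero-alignable windows have
undefined rate and never qualify). A maximal run of ≥ 5 windows whose
starts differ by exactly one step becomes a region: raw span = first
start to last start + 1 Mb, hence ≥ 2 Mb always. Trailing partial
windows participate but cannot pass the alignable floor. For all scoped
analyses the raw region is trimmed by 100 kb on each side so feature and
SV counts stay inside the identity-by-state block.

## Summaries

Per-family percent-polymorphic is computed per comparison against the
family's copy number in the classified genome, restricted to families
with at least 20 copies, with the across-comparison range as the
dispersion statistic; superfamily × method roll-ups report mean ± sd
across comparisons. Candidate currently-active families are those with
strictly more than `active_min_events` (default 10) TE = SV links inside
SNP-depleted regions; the report includes the per-genome insertion
balance and the element-length distribution, since genuinely mobile
families produce near-identical element lengths.

## The simulator

`tesv.simulate` builds an ancestral chromosome set and derives a
reference and query genomes from it, so that every downstream expectation
is known analytically.

*Ancestor.* TEs are placed left to right; lengths come from a
configurable family catalog (defaults: LTR families of 5–10 kb
dominating genome space, DNA/TIR families of 0.3–3 kb dominating
counts) and gaps from an exponential law whose mean yields the target
coverage (default 0.77, the TE fraction of a maize genome). A fraction
of placed elements are homology fragments; structural elements ≥ 1 kb
may host one nested homology fragment clear of the host's edges
(exercising the containment exemption of the filter). Annotations keep
at least `min_gap` (30 bp) clearance so clean simulated sets pass the
filter untouched. Structural LTR elements draw an LTR identity from
1 − Exp(0.03) clipped to [0.8, 1]. Genes, when requested, occupy large
TE-free gaps with 2–4 exons.

*Events.* Planted per genome with global non-overlap (a 12 bp alignable
spacer between any two events, 1 kb chromosome-edge margin, rejection
sampling with a retry cap): TE insertions whose annotation exactly spans
the inserted sequence (expected TE = SV / insertion); deletions removing
one whole TE plus ≥ len/15 + 10 bp of flank (expected TE-within-SV — an
exact-span single-TE deletion would be indistinguishable from an
insertion by construction), 2–4 adjacent whole TEs with no TE exceeding
94% of the span (expected Multi-TE), an internal fragment of one TE
capped at 94% of its length (expected Incomplete-TE), non-TE gap
sequence (expected No-TE), or intronic gene sequence; sub-threshold
indels; unequal-sided substitution blocks (unalignable); record-free
gaps (missing). Deletions are planted in query genomes; insertions in
the reference or a query. Per-query SNPs fall at the background rate on
ancestral positions outside that query's identity-by-state blocks and
at least 2 bp away from any event of the pair.

*Alignments.* Pairwise partitions are constructed analytically from the
event history — no sequence aligner — and also emitted as GVCF text
(blocks split at SNPs, indels anchored one base left, VCF-style; missing
gaps uncovered). Allele strings are length-correct placeholders
(`A`/`C`/`G`), since no analysis stage depends on base content; the
GVCF → `condense_gvcf` round trip reproduces the analytic partition
exactly and is asserted in the tests. Derived annotations map through
the event history: inserted TEs exactly span their insertion, fully
deleted TEs vanish from the carrier, internally deleted TEs keep a
single merged remnant.

*What the simulator does not emulate* — and hence what passing tests do
not show about real data: aligner noise and breakpoint ambiguity
(AnchorWave-style alignments shift SV edges within homopolymers and
repeats), nested insertion aging, solo-LTR formation by ectopic
recombination, annotation error (fragmented or chimeric panEDTA calls),
inversions/translocations (the event model is collinear), and base-level
mutation processes beyond uniform SNPs. Recovery rates of 100% on
simulated data therefore measure the classification logic, not
annotation or alignment quality.

## Problem sizes and determinism

The test suite and the acceptance script run scaled scenarios chosen as
representative rather than exhaustive: 100–400 kb genomes for per-base
oracle comparisons (50 random replicates), and a 10 Mb, 3-query,
60-event scenario with two 2.5 Mb identity-by-state blocks for
chromosome-scale recovery; the full suite completes in well under a
minute. All randomness flows from explicit seeds (simulation events,
filter tie-breaks), identical inputs yield byte-identical output tables,
and the pipeline manifest records the config hash and input checksums.

## Known limitations

* One pairwise comparison per partition; multi-sample VCFs are rejected.
* Chromosome correspondence is by name; rearranged assemblies need
  renaming upstream.
* The query coordinate system covers aligned bases only, so query
  features inside alignment gaps cannot be classified (they do not occur
  in simulated data; in real data they would surface as bound errors).
* `restrict_analysis` assigns features to regions by the ≥ 50%-of-bp
  rule; counts near region edges are sensitive to that choice.
* The boundary filter rule compares all four endpoint pairs; annotation
  sets with legitimately abutting elements (distance ≤ 5 bp) will lose
  the smaller member.
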
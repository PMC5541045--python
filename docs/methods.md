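# Methods

Model, parameter choices and numerical details for the `rtcrispr` pipeline.
All defaults live on `rtcrispr.pipeline.RunConfig` and the function
signatures they feed.

## Sequence comparison

**Pairwise identity** is computed on a global, end-gap-free alignment
(BLOSUM62, gap open 11, extend 1; terminal gaps are free). Percent identity
uses the *shorter* sequence as denominator, the convention of greedy
clustering tools, so a perfect substring scores 100%. When several alignments
are co-optimal in score, any of their identity counts is acceptable; the test
suite checks the reported identity against the full co-optimal range computed
by an independent dynamic-programming oracle.

**Dereplication** is greedy longest-first: sequences shorter than 200 aa are
dropped, the rest are sorted by length (ties broken by input order), and each
candidate is kept only if its identity to every already-kept representative
is ≤ 85%. The procedure is idempotent; re-running it on its own output
changes nothing.

**Local search** uses Smith–Waterman (same scoring) with gapped
Karlin–Altschul statistics: λ = 0.267, K = 0.041 (standard published values
for BLOSUM62 11/1), bitscore = (λS − ln K)/ln 2, e-value = m·n·2^(−bit) with
the search space m·n the product of query and target lengths.

**Two e-value thresholds** are deliberate and distinct:

- `evalue_max = 0.01` for cas-family annotation. This is a *screening*
  threshold: by construction it admits on the order of 1% chance hits per
  comparison, which is acceptable when the caller inspects family context.
- `evalue_domain = 1e-6` for domain-architecture decisions — "is this gene
  an RT?", "which domains does the fusion carry?". Anchoring loci on 0.01
  hits produced exactly the expected chance anchors in planted cohorts
  (spurious hits at 1e-2…1e-6, vs true hits below 1e-100), so architecture
  calls require confident similarity.

## CRISPR arrays

Arrays are detected as runs of ≥3 near-identical repeats (19–48 bp) with
spacers of compatible length; coordinates are 1-based inclusive. Orientation
is a three-criterion cascade, stopping at the first criterion that decides:

1. **Intrinsic leader signal.** Score = AT-fraction(upstream flank) −
   AT-fraction(downstream flank) + terminal-repeat-degeneracy asymmetry/100,
   computed on 200 nt flanks. |score| ≥ 0.15 → band H, ≥ 0.06 → band M,
   otherwise L (not trusted). If either flank is shorter than 200 nt the
   band is NA and criterion i abstains. Band boundaries were calibrated
   against the synthetic generator's signal model only (leader AT-enrichment
   0.25 with 3 terminal repeat mutations must land in H).
2. **Repeat database.** Exact match of the array's repeat consensus, on
   either strand, to the oriented repeat table.
3. **Group similarity.** ≥ 90% identity between repeat consensi transfers
   the orientation of an already-oriented array. The pipeline applies this
   as a second pass over the arrays criterion i/ii could not orient.

Arrays that exhaust the cascade stay `undetermined`.

## Locus extraction and classification

Starting from an RT anchor gene, annotated cas genes are chained outward in
both directions within a ±50 kb window; a neighbor is added only if the gap
to the current locus edge (intervening bases, `next_start − cur_end − 1`) is
**strictly less than 5,000 bp**. Arrays link to the locus within 1 kb of a
locus gene; the RT is "array-linked" if an array sits within 1 kb of the RT
gene itself. Extraction is idempotent: re-trimming an extracted locus
returns it unchanged.

Fusion classes (RT, RT-Cas1, Cas6-RT-Cas1) come from the N→C order of
confident domains on the anchor protein. Type III effector subtype is
signature-based: csm2–csm5 ⇒ III-A/D, cmr1/cmr3–cmr6 ⇒ III-B/C; cas10 is
shared and non-discriminative; weak (0.01-level) signatures alone yield
`partial/unknown`.

## Phylogeny and clades

Trees are neighbor-joining on Poisson-corrected p-distances over mutually
ungapped columns, with supports = bootstrap bipartition frequencies (column
resampling, seeded). The NJ tree is **midpoint-rooted before supports are
attached**: NJ output is arbitrarily rooted, and a root inside a genuine
clade would prevent that clade from being a rooted subtree. Mapping supports
after rooting avoids the classic reroot bug where supports migrate to the
wrong edges; the two children of a binary root subtend the same unrooted
edge and share one support value.

Clades are maximal internal nodes with support ≥ 0.92 (configurable), at
least 2 leaves, and all leaves CRISPR-flagged. Subclades split a clade at
children with support ≥ 0.92, ≥ 3 leaves and phylum purity ≥ 0.9. Per-clade
membership models are the clade consensus plus an exclusion threshold at the
log10 midpoint between the worst member self-hit and the best non-member hit
(e-values floored at 1e-300 first; near-identical self-hits on long proteins
underflow to exactly 0). Monophyly of a label set is tested on the unrooted
tree (some edge separates exactly those leaves); congruence of two
partitions combines the adjusted Rand index of the labelings with per-label
monophyly in each tree.

**Coarsening without an outgroup.** When *every* leaf is CRISPR-flagged
(e.g. a cohort whose RTs all come from planted loci), the complement of a
well-supported clade is itself a well-supported all-CRISPR node, so adjacent
true clades can merge into one maximal clade. This is a property of
support-threshold delimitation, not a bug: no true clade is ever split or
partially mixed (the acceptance run reports this as coarsening consistency
1.0). With non-CRISPR background leaves present, planted clades are
recovered exactly.

## Synthetic data

The generator brackets every planted gene with the insulator
`TTAATTAATTAA` (stop codons in all six frames, self-reverse-complement), so
the ≥300 bp ATG/longest-per-stop ORF caller recovers planted coordinates
exactly. Decoy genes are length-matched random-permutation proteins audited
to have no profile hit at e ≤ 0.01. Protein families follow a per-cluster
identity ladder verified against the package's own identity operation
(±2 pp). Clade alignments are founder-plus-divergence with random
background. All generators are deterministic in their seed; seeds stay below
2^31.

The shipped profile library (14 families) and repeat database (12 repeats)
are synthetic stand-ins, generated once and committed as text. Each family
consensus is audited for mutual dissimilarity (best cross-family e-value
> 0.1, a 10× margin over the annotation threshold); without the audit, one
random pair happened to show chance similarity below 1e-6, which planted
one family's genes as false RT anchors.

## Determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`. The pipeline's `run.log` records stage
input/output counts but no wall-clock times (timings go to stderr), so two
runs with the same config and seed produce byte-identical output
directories.

## Limitations

- The profile "library" is one consensus sequence per family, not a true
  profile HMM; sensitivity to remote homologs is far below real tools and
  is not the point — the pipeline's logic, statistics and bookkeeping are.
- The ORF caller is minimal (ATG-only starts, no RBS model) and relies on
  the generator's insulators for exact coordinates; on real genomes a
  dedicated gene caller should be supplied via GFF3 (`--gff3` /
  `RunConfig.gff3`), which takes precedence over ORF calling.
- NJ + bootstrap is a deliberately lightweight tree method; clade
  delimitation quality on real data would warrant ML trees and outgroup
  selection.
- Karlin–Altschul parameters are fixed constants; no edge-effect or
  composition corrections are applied.
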
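# Methods

This note records the models, conventions and numerical choices behind
`popref`, in the order the pipeline runs them. Parameters named here are
all exposed through `popref.config.RunConfig` or the functions' own
keyword arguments.

## Coordinate and representation conventions

All internal coordinates are 0-based half-open; conversion to 1-based
happens only at the VCF/GFF3/AGP boundaries. Soft-masking (lowercase
FASTA) is preserved through I/O but ignored by every algorithm: sequences
are capitalized on read and the mask re-emitted on write. Variants are
VCF-style records, left-anchored for indels; two variants are "the same
allele" if and only if their *normalized* records match — normalization
(left-align + parsimony, the vt/bcftools-norm semantics) runs before any
cross-assembly comparison, so voting is representation-invariant.

## Pairwise alignment

The internal aligner is an anchor–chain–extend design sized for
megabase-scale inputs:

1. **Anchors** — exact matches of k-mers (k = 19) that occur exactly once
   in the target; k-mers containing N are skipped. Both query strands are
   scanned (reverse-complement anchors chain in the reversed-query frame,
   so downstream code never handles strand arithmetic in op lists).
2. **Chaining** — the longest strictly co-linear subset per
   (query contig, target contig, strand), an O(n log n) LIS with ties
   resolved toward smaller target coordinate.
3. **Extension** — inter-anchor gaps are closed by a banded Gotoh DP with
   affine costs (match 0, mismatch 4, gap open 4, gap extend 2 — chosen to
   behave like an asm5-class aligner on ≥95 %-identity pairs, and
   configurable). The band doubles on exhaustion up to a limit, after
   which the gap pair is emitted as an unaligned deletion+insertion.
   Traceback prefers diagonal moves at equal cost, which places
   equivalent gaps leftmost; normalization later canonicalizes any
   remaining representational freedom. One-sided gaps (pure indels,
   including multi-kb SV insertions) bypass the DP entirely.

Runs of ≥ 10 Ns split contigs into independently aligned segments, so no
variant is ever called across an assembly gap. Overlapping blocks are
reduced to a one-to-one cover greedily by descending score. Precomputed
PAF with `cs` tags can substitute for the internal aligner at any point.

The aligner is *not* repeat-aware and keeps one chain per contig pair and
strand: translocations and inversions nested inside a contig are out of
scope (the simulator does not generate them).

## Majority voting

Variant sets from N assemblies, each called against the same backbone and
normalized, are grouped by site. An allele with support ≥ ⌊N/2⌋+1 (2 of 3
by default) enters the major set. Sites where ≥ 2 alleles are observed
but none reaches the share become tie sites; the candidate list is the
multiset of alleles the assemblies actually carry — an assembly with no
variant at the site votes for the backbone allele. (A switch,
`include_backbone_candidate`, adds the backbone allele even when no
assembly carries it.) Ties are resolved uniformly by a seeded generator
(numpy PCG64 seeded from the run seed); decisions are logged with the
full candidate list so a run can be replayed. A site where a single
assembly differs from the backbone keeps the backbone allele.

Applying the major set walks each contig once; overlapping records keep
the first by coordinate and report the rest. The resulting
`CoordinateMap` stores every identity-copied segment, giving exact
backbone→consensus point lookups and, via chain export, liftover.

`expected_tie_errors` scores the random tie picks against an AF panel:
per site with m candidates, the error probability is 1 − 1/m when the
panel-major allele is among the candidates and 1 otherwise; sites absent
from the panel are tallied separately. This is this package's own
definition of the expected-error bookkeeping for random tie resolution.

## In-silico PCR and anchoring

A marker amplifies where its forward primer and the reverse complement of
its reverse primer match opposite strands facing each other, each with at
most 1 mismatch and an exact match over the 3′-terminal 3 bases, and the
amplicon length is within ±50 % of the stated expected size (≤ 5 kb when
none is stated). These are conventional e-PCR settings, exposed in
config; candidate positions come from exact search on primer chunks
(pigeonhole over max_mismatch+1 pieces), verified exhaustively — tests
pin equivalence to an all-positions scan.

Markers amplifying on more than one scaffold are dropped as ambiguous. A
scaffold is flagged chimeric when ≥ 2 linkage groups each contribute
≥ 2 marker hits (singletons are tolerated as map noise). Chromosome
assignment maximizes the summed hit weight — genetic-map hits weigh 5, RH
hits 1 — with exact ties left unplaced.

Ordering uses the weighted mean of hit map positions after z-scoring
within (map, linkage group): centimorgan and centiray scales are not
commensurable, and standardization is monotone per map, so single-map
behaviour is unchanged while mixed-map scores stay comparable.
Orientation combines *per-map* Pearson correlations (weighted by map
weight) between within-scaffold amplicon coordinate and map position;
markers from different maps are never correlated against each other,
because two maps agree on scale only approximately and a two-point
cross-map correlation would carry pure sign noise. A scaffold on which no
single map places ≥ 2 markers has unidentifiable orientation and defaults
to '+'. This deterministic scheme replaces a genetic-algorithm search; on
≤ 6 scaffolds the tests show it matches the exhaustive-permutation
optimum of the weighted per-map correlation objective.

Pseudo-molecules concatenate ordered, oriented scaffolds with 10,000-bp N
gaps (AGP 2.1 emitted alongside; rebuilding from AGP + scaffolds is
asserted byte-identical). Co-linearity reports |r| between pseudo-
molecule coordinate and map position per (map, chromosome), summarized
mean ± SD by map type. On toy fixtures (tens of kb per chromosome) the
fixed 10 kb gap would dominate the geometry, so the test suite evaluates
co-linearity with a gap proportional to the toy scale (100 bp); at genome
scale the 10 kb default is negligible relative to chromosome length.

## Liftover

Chains follow the UCSC format exactly (validated arithmetic:
Σsize + Σdt = target span, Σsize + Σdq = query span; '-' strand query
coordinates in the reversed frame). Chain score is the count of aligned
bases — a documented convention, not load-bearing. Interval lifts are
exact when fully inside aligned blocks; intervals spanning gaps lift each
end through the nearest block as "partial" when the aligned fraction
meets `min_overlap` (1.0 for variants, 0.95 for features by default) and
are otherwise unmapped. GFF3 groups tied by ID/Parent are rejected whole
under the strict policy when any member fails; a permissive per-feature
mode exists.

## SV and depth statistics

SVs are insertions/deletions with |Δlength| ≥ 51 bp. Merging is
single-linkage: two records are linked iff they share the SV type and
both breakpoints are within 1000 bp inclusive; insertions compare
(start, start + length) — their extent on the inserted-sequence frame —
since a 1-bp reference anchor carries no second breakpoint. The merged
representative comes from the first-listed call set.

Accessible regions are maximal runs with mean depth in
[5, mean + 2·SD], mean and SD per chromosome. Δ average depth takes the
upstream window [start − len, start) as reference and returns the signed
depth deviation at the most deviant position inside the SV window;
records whose SV-plus-upstream span leaves the contig or the accessible
set are skipped with a reason. The whole window is required accessible
(the alternative — masking inaccessible positions within the window —
would change Δ only at sites that are dubious anyway). The paired
Wilcoxon test drops zero differences, uses the exact null for n ≤ 25 and
the normal approximation with continuity correction beyond (scipy's
implementation; an enumeration oracle pins n ≤ 10 in the tests).

## Representativeness SFS

Each consensus-vs-external-reference SNV's employed allele is looked up
in the AF panel; statuses are found / missing / allele-mismatch, and the
conservation Σcounts + missing + mismatch = input sites is asserted. Bins
are 0.01 wide with AF = 1.0 as its own closed bin, because the fixed
class is reported separately. Sites at AF ≈ 0 are kept and visible (they
flag alignment-edge artifacts). Threshold summaries take the panel
denominators as explicit inputs, so the caller controls whether they are
genome-wide or restricted to aligned regions.

## Simulator

The generator targets *structural* realism — every downstream code path
exercised with known truth — not demographic realism:

* Ancestral chromosomes are uniform random sequence; variant sites are
  placed with exponential spacing floored at 60 bp, which guarantees
  normalized representations never collide. Rates default to 1/800 bp
  SNVs, 1/8 kb indels (1–10 bp), 1/25 kb SVs.
* SV lengths come from a two-mode log-normal mixture centred at 300 bp
  and 6 kb (weights 0.7/0.3) — the two insertion-length peaks
  characteristic of active Alu and LINE1 elements — floored at 51 bp.
* Alt-allele frequencies are Beta(0.8, 0.8): U-shaped, both alleles
  segregating. Haploids carry each site's alt independently with
  probability AF.
* Scaffold fragmentation draws exponential fragment lengths with mean
  target_N50/1.678 (the length-weighted median of an exponential is
  ≈1.678× its mean), separated by 50–200 bp unsequenced gaps; fragments
  are optionally reverse-complemented, and a placement truth table is
  emitted.
* Marker maps place primer pairs (20 bp, exact substrings flanking a
  unique 200–500 bp amplicon) away from catalogued variant spans, so the
  same primers amplify on every haploid; map positions are the true
  genomic fraction scaled to the map length plus Gaussian noise
  (genetic maps default noiseless, RH maps noisy).
* Depth tracks: per sample and position the read depth is Poisson(30);
  the mean over 200 samples is drawn as a single
  Poisson(n_present × 30)/200 per position, which is the same
  distribution without materializing a samples × length matrix. A sample
  lacking sequence the frame has contributes zero across that interval;
  a sample carrying sequence the frame lacks piles an extra Poisson(30)
  over a 100-bp junction window. These are deliberate simplifications:
  no mappability structure, no GC bias, no read-length tapering at
  junction edges. Consequently the depth tests demonstrate the *logic*
  of the Δ contrast (shared SVs dent the frame that lacks them), not its
  effect size on real short-read data.
* All randomness derives from one master seed through named substreams
  (crc32 of the stage name spawns a child SeedSequence), so any stage
  reruns identically in isolation.

Fixture profiles: `tiny` (2 × 50 kb chromosomes, seconds) and `desk`
(2 × 500 kb, ~15 s for a genome-pair alignment). These sizes keep the
full validation battery interactive while remaining large enough that
every per-variant code path (SNV/indel/SV, both SV length modes, tie
sites) is exercised hundreds of times per run.

## What passing tests do and do not show

Exact round-trip recovery, the majority-recovery law, anchoring recovery
and the Δ-depth contrast are all properties of the *method* verified on
generated data with known truth. They do not certify performance on real
assemblies, where alignment ambiguity in segmental duplications,
centromeres and long repeats — explicitly outside the internal aligner's
scope — dominates the error budget. The printed-ratio worked examples
(PPV 98.3 %, sensitivity 96.6 %, support shares 47 %/48 %, SFS capture
97.99 %/97.11 %/96.24 %) are exact arithmetic on published count tables
and validate the metric implementations, not the genome-scale pipeline.
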
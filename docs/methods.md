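# Methods

## The compartment k-mer screen

The screen assumes that a repeat-directed mutagenic process leaves a
*consistent, directional* skew in short-word composition: specific k-mers
become systematically over-represented in repeats relative to the rest of
the genome, and — because old, no-longer-annotated repeat relics litter
intergenic space — in non-coding relative to coding sequence. Neutral
drift, by contrast, perturbs k-mer frequencies without a shared direction
across compartments. The screen therefore requires *joint* enrichment: a
genome is called RIP-proficient only when the k-mers enriched in
non-coding sequence are largely the same k-mers enriched in repeats.

Definitions and conventions:

* Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
  is converted at the boundary, BED is native. Strand is ignored when
  building compartments; counting is on the given strand (a
  canonical-collapse option is deliberately not the default, so the
  behavior is explicit). IUPAC ambiguity codes are mapped to N and any
  window containing N is skipped, which makes interval-restricted counting
  identical to counting a hard-masked FASTA (a property the tests verify
  exactly).
* Scaffolds < 50 kb are dropped before anything else; the threshold
  suppresses composition artefacts of fragmented assemblies.
* Frequencies are normalized **per k-length** (dimers, trimers and
  tetramers each sum to 1 within a compartment). This makes the
  enrichment ratios invariant to the k-mixture; a literal
  grand-total normalization (`scope="all_kmers"`) is available and leaves
  same-k ratios essentially unchanged.
* Zero counts are never smoothed. A ratio with a zero denominator is
  flagged undefined and excluded from every threshold count; pseudo-counts
  would manufacture enrichment in exactly the AT-rich tail the screen
  reads.

Classification parameters (defaults): fold threshold 2 on both ratios;
recent requires ratio > 0.5 **and** ≥ 10 doubly enriched k-mers; trace is
the closed band [0.3, 0.5]. The cell {ratio > 0.5, n_both < 10} is not
covered by the published rule set; it is classified `none` with a warning
flag, on the reasoning that the 10-k-mer floor exists precisely because
ratios computed from a handful of words are unstable.

## GC segmentation

Recursive binary segmentation per scaffold: split at the point maximizing

    S = n_L n_R / (n_L + n_R) · (gc_L − gc_R)² / (p(1 − p)),

where p is the segment's GC fraction; recurse while S exceeds the halting
threshold (default 100) and both parts stay ≥ 200 bp. Standardizing by
p(1 − p) makes S behave like a squared standardized change-point statistic:
on homogeneous sequence its maximum grows only logarithmically with length
(≈ 20–30 for megabase scaffolds), far below 100, so a homogeneous scaffold
yields one segment; a 20-percentage-point GC junction between kilobase
blocks scores in the thousands. The procedure is deterministic and the
segment count is non-increasing in the threshold. This reproduces the
*behavior* of classic genome-order-index segmentation, not its exact
constant; bit-exactness with any particular tool is out of scope.

## Gene density and compartmentalization

Distances are measured between merged gene spans; scaffold ends count as
neighbors, so a lone gene on a fragment is not automatically "sparse" on
its open side — a deliberate guard against fragmented assemblies inflating
two-speed calls (it can under-call sparse genes on very fragmented
assemblies). Sparse means both flanks > 5 kb (strict); compartmentalized
means the sparse fraction exceeds 1% of the gene pool (strict).

## Homology metrics

* Alignment tables are the standard 12-column tabular dialect. De-duplication
  removes self-hits (same ids **and** same coordinates, so shifted
  self-alignments of a repeat against itself survive) and keeps the first
  record among those identical on (qseqid, sseqid, pident, length,
  mismatch, gapopen, qstart) — "first" means input file order.
* Repeat-identity length bins are cumulative (a 6 kb hit increments >100,
  >1,000 and >5,000); identity bins are 80–95% versus >95%. The headline
  per-genome statistic is `n_1kb` (> 1 kb at > 95%), a proxy for recent
  unmutated copies. An exclusive-bin mode exists for cross-checks.
* Reciprocal best hits rank by bitscore, then lower e-value, then input
  order; ties resolved by order are logged.
* Pangenome bands: core f > 0.9, softcore 0.8 < f ≤ 0.9, shell
  0.5 < f ≤ 0.8, variable f ≤ 0.5, singleton = exactly one species. The
  published band edges leave f = 0.8 and f = 0.9 ambiguous; closing each
  band at its upper edge keeps the partition exhaustive and exclusive.
* Synteny: windows are ≤ 10 genes each side, never crossing scaffold
  boundaries (truncated windows used as-is). For a multi-copy focal gene
  the windows around all copies are unioned — the permissive reading. The
  mean is over all neighbor orthogroups observed in at least one carrier's
  window.

## Independent contrasts

Standard Felsenstein recursion; polytomies are resolved arbitrarily into
zero-length bifurcations (logged) and non-positive branch lengths replaced
by ε = 10⁻⁸. The regression of one contrast set on another is ordinary
least squares **through the origin** (contrast signs are arbitrary), with
adjusted R² as the correlation measure and BH-FDR for families of tests.
`log10_with_zeros` reproduces the common "log-transform, keep zeros at 0"
pre-processing; it is discontinuous by construction, and `log10(x + 1)` is
the cleaner alternative when the mixed scale matters. The implementation
is cross-checked against the GLS identity: the sum of squared contrasts
equals the Brownian GLS residual quadratic form of the tip data.

## The synthetic-data generator

The generator's defaults describe one fixed set of study conditions — a
moderately repetitive, compartmentalized fungal genome:

| parameter | default | why |
|---|---|---|
| genome | 5 × 400 kb | all scaffolds clear the 50 kb filter |
| background GC | 0.50 | neutral midpoint |
| genes | 500 × ~1.5 kb (σ 300 bp, min 300 bp) | ~37% coding, typical gene spacing ~1.7 kb |
| coding GC | 0.60 | flat elevated GC stands in for codon bias; it separates all-AT k-mers (> 2-fold non-coding enriched) cleanly from k-mers with any G/C (below 2-fold), giving the screen a realistic but unambiguous non-coding baseline |
| repeat families | 5 × 40 copies × 600 bp | ~6% repeat content, ~10% of the non-coding compartment — enough that repeat counts are stable, small enough that repeat-driven words are not diluted out of the repeat/non-coding ratio |
| per-copy divergence | 2% uniform substitutions | spreads self-alignment identity over the 80–100% range |
| `rip_rate` | per-cross probability that an available CpA/TpG context mutates | |
| `rip_generations` | 7 | repeats in a genome are relics of repeated sexual cycles; seven crosses at the *N. crassa*-like per-cross intensity of ~0.3 drive cumulative context conversion past 90%, reproducing the strong AT-skew of genuinely RIP'd repeats while a rate of 0.05 or less stays indistinguishable from background |
| sparse region | 20% of each scaffold, holding ~2% of genes with > 5 kb flanks | realizes a two-speed architecture (sparse fraction > 1%) |

Because a C→T at CpA would need an A where the created T sits, and a G→A
at TpG would need a T where the created A sits, RIP conversions can never
create new CpA/TpG contexts. Repeated rounds therefore commute into a
single pass over the original contexts with cumulative probability
1 − (1 − rate)^generations, which is how `simulate_genome` applies them —
the expected mutation count stays analytic (binomial over the context
census), and the truth table records the realized count per repeat copy.
A single experimental cross (`simulate_rlr_cross`, 802 bp repeats, 729 bp
linker, mutations confined to the repeat copies) applies `rip_rate`
directly.

What the generator does **not** emulate: nested/fragmented TE insertions,
TE phylogenies, selection, recombination, real codon structure (coding
bias is flat GC, not position-specific GC3), isochore-scale GC gradients,
and assembly gaps. Passing recovery tests therefore show that the screen
reads a clean, localized RIP signature correctly at realistic magnitudes —
not that it is robust to every messiness of real annotations, where repeat
misannotation and UTR-less gene models remain the dominant risks.

## Problem sizes and numerics

The test-suite and acceptance runs use: 50 single-scaffold 60 kb genomes
for conservation checks; 50 random 10 kb sequences for mask equivalence;
20 + 20 full-size (2 Mb) genomes for the recovery arms; 12 RLR progeny;
200 random alignment records for binning; 100 Brownian replicates on 16-
or 20-tip trees (plus 200-tip trees for the ρ² calibration). Frequency
conservation is asserted at 10⁻¹², contrast identities at 10⁻¹⁰; interval
arithmetic and k-mer counting are integer-exact. All randomness flows
through seeded NumPy generators; the genome writer records the seed in
its output headers.
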
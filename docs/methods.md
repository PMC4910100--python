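# Methods

`pomedev` re-implements, as one tested pipeline, the computational analyses
typically run on a multi-cultivar fruit-development RNA-seq time course:
five cultivars sampled at seven stages (six developmental stages plus one
post-harvest senescence stage), with two cultivars whose fruit continues
ripening after harvest ("post-ripening") and three eaten at harvest.  All
stages operate on synthetic data with planted ground truth, so every claim a
test makes can be checked against a known answer.

## Expression quantification

Counts are converted to RPKM (reads per kilobase of exon model per million
mapped reads):

    rpkm[g, s] = 1e9 * count[g, s] / (length_bp[g] * total_mapped[s])

Gene length is the exon-union length of the gene's longest transcript —
the closest genome-side analogue of quantifying against spliced transcript
sequences.  The presence filter keeps genes expressed in at least
`min_stages` (default 5) of a cultivar's seven stages; "expressed" defaults
to RPKM > 0 because no universal threshold exists for this filter, and
`min_rpkm` is exposed in config.  A global variant of the filter (at least
5 of all 35 samples) is available by flag; the per-cultivar reading is the
default because the filter is applied per cultivar downstream.

## Sample dendrogram

Sample relatedness uses Spearman rank correlation (midrank ties) on
log2(RPKM+1) — rank correlation is already insensitive to monotone
transforms, but the log is kept so that the optional Pearson/raw modes stay
comparable.  The tree is UPGMA (average linkage) on distance 1 − rho.  UPGMA
is implemented directly rather than through `scipy.cluster` because the
merge order must be fully deterministic: ties in merge height (within 1e-12)
are broken by the lexicographically smallest member label, which makes tree
topology invariant to sample input order.  scipy's linkage serves as an
independent cross-check on tie-free random matrices in the test suite.
Undefined correlations (constant samples) are recorded as 0 with a warning.

## Model-profile time-course clustering

Short time-series clustering follows the model-profile idea of STEM:

1. **Candidate templates.** All integer vectors of length T = 7 starting at
   0 with successive differences in [−c, c], c = 2 by default; the all-flat
   template is excluded.  This gives 5^6 − 1 = 15,624 candidates.
2. **Profile selection.** Greedy max-min selection of m = 20 profiles under
   distance 1 − Pearson: start from the pair at maximum distance, then
   repeatedly add the candidate maximizing its minimum distance to the
   chosen set.  Ties resolve to the lexicographically smallest template, so
   selection is deterministic; one shared profile set is used for all
   cultivars so cross-cultivar comparisons are well defined.
3. **Assignment.** Each gene's series is log2(RPKM+1) anchored to its
   stage-1 value and assigned to the profile with maximal Pearson
   correlation (ties to the lowest profile id).  Pearson makes assignment
   invariant to affine transforms of a gene's series.  Zero-variance genes
   are reported separately rather than forced into a profile.
4. **Cluster significance.** Each gene's seven values are permuted
   (uniformly over orderings, seeded; an exhaustive mode over all 5,040
   orderings exists) and re-assigned; the expected gene count per profile is
   the mean over permutations, and the p-value is the binomial upper tail
   P(X ≥ observed) with success probability expected/total, Bonferroni
   corrected over the m profiles.

Measured behavior at the default settings (300 genes, 30% planted on the
monotone-decrease template, noise sd 0.25 on the template scale, 300
permutations): planted-gene recovery is 100%, the planted profile is
Bonferroni-significant in 20/20 seeded runs, and a flat null produces no
significant profile in ≥ 19/20 runs — the binomial tail is conservative for
the discrete counts, which keeps the family-wise error below nominal.

## Maturity → senescence contrast

Per cultivar, genes expressed (RPKM > 0) in stage 6 or 7 are classed by
log2 fold change with pseudocount 1: up if fc ≥ 1, down if fc ≤ −1
(threshold, pseudocount, and expression floor are config keys; at threshold
0 the unchanged set is exactly fc = 0).  Up-proportions are compared between
maturity groups with Welch's unequal-variance two-sample t-test and
Satterthwaite degrees of freedom.  Welch rather than pooled: applied to the
published per-cultivar up-percentages (43.95, 44.63 vs 21.39, 24.33, 27.04)
it returns p = 0.005032, which pins down the variant of the test actually
used; the pooled version (p ≈ 0.0025) is available by flag.

Group-exclusive sets use the intersection-minus-union reading:
`only_up_in_post` = genes up in **every** post-ripening cultivar and up in
**no** non-post-ripening cultivar (an "any" mode relaxes the intersection);
the dual definition gives `only_down_in_non`.

## SNP effect classification

Every single-nucleotide substitution is classified against transcript
models into 12 categories (upstream/downstream within 2 kb, splice boundary,
intron, the seven codon-level classes, and reference-N), with intergenic as
a sentinel; exonic non-CDS (UTR) positions carry an `unclassified_utr` flag
rather than being forced into a class.  Details that needed a decision:

- **Coordinates** are 1-based inclusive end to end (GFF3 and VCF native).
- **Splice boundary** means the two intronic bases at each junction — the
  canonical donor/acceptor dinucleotides; exonic boundary bases take their
  codon class.
- **Codon classes** substitute the strand-corrected allele into the spliced
  CDS and translate ref and alt codons under the standard nuclear code.
  First codon: class 5 unless the alt codon is ATG (class 11).  Last codon:
  class 6 unless the alt codon is still a stop (class 10).  Internal: stop
  gained → 8, amino acid unchanged → 7, changed → 9.
- **Class 11 (silent initiation change)** is unreachable for an ATG start —
  any substitution leaves ATG — so it is defined as "alt codon is ATG" and
  is reachable only for transcripts annotated with a non-canonical start
  (the synthetic generator can plant GTG-start genes for exactly this
  purpose).  Models with non-ATG starts or missing terminal stops are
  flagged but still classified.
- **Precedence.** A variant hitting several contexts yields one record per
  transcript; summaries keep one primary record per variant under
  N > codon classes > UTR flag > splice > intron > upstream > downstream >
  intergenic, ties broken by lexicographic gene then mRNA id.  Flank
  regions are truncated at chromosome ends and deliberately not trimmed at
  neighboring genes — the neighbor's own context outranks a flank.
- Models whose CDS length (after phase) is not a multiple of 3 are flagged
  `non_coding_frame` and excluded from codon calls (their CDS variants get
  the unclassified flag).

Correctness is established three ways on planted fixtures of ≥ 500 variants
spanning all 12 classes, both strands and multi-exon genes: agreement with
the planting truth, agreement with an independent oracle that rebuilds the
whole mutant chromosome and re-translates every transcript, and exact
invariance of all classes under reverse-complementing the entire fixture.
All three hold at 100%.

## Enrichment

Generic over-representation of a gene set against a supplied gene → term
table: upper-tail hypergeometric P(X ≥ k) per term, tested against exhaustive
enumeration (exact rational arithmetic) on all instances with N ≤ 25 at
1e-12.  The default universe is the presence-filtered gene set, not the
whole genome — the defensible background for expression-derived sets.
Correction defaults to none (matching how raw enrichment p-values are
typically quoted), with Bonferroni and Benjamini-Hochberg available.

## Co-expression network

Weighted network in the WGCNA style: Pearson correlation on log2(RPKM+1),
soft-thresholded unsigned adjacency |cor|^β (β = 6, signed mode available),
topological overlap

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

and modules from a **static** cut of the average-linkage tree on 1 − TOM
(default height 0.75, minimum module size 5; clusters below the minimum are
labeled 0).  Static rather than dynamic hybrid cutting is a deliberate
simplification: deterministic, adequate at desk scale, and stated here as a
divergence from full WGCNA.  β and the cut parameters are config-exposed and
echoed in output headers.  "Direct" interaction in the edge report means an
edge above `min_weight`; "indirect" means a path of length 2 in the
thresholded graph.

## Synthetic data generator

The generator is first-class, tested code; it emulates the study design,
not the sequencing:

- **Genome:** random chromosomes (default 2 × 120 kb) with a configurable
  fraction of N positions (default 0.5%) to exercise the reference-N class.
- **Gene models:** default 40 genes, 1–4 exons, ~half on the minus strand,
  clean ORFs (ATG start, no internal stop, one terminal stop) written into
  the genome; intergenic spacing ≥ 4001 bp guarantees that 2 kb flank
  windows never overlap a neighboring gene or each other, so planted flank
  variants have unambiguous truth.  The default sizing (2 × 120 kb for 40
  genes) is the smallest round configuration that holds 40 spaced genes and
  keeps the full pipeline under ~10 s.
- **Variants:** per-class planting with the context of every candidate site
  verified by direct sequence inspection at planting time; classes with too
  few eligible sites (e.g. silent stop swaps, or silent initiation changes
  when no non-ATG-start gene exists) raise a named error instead of being
  dropped silently.
- **Counts:** negative-binomial draws (variance = μ + noise·μ²) around
  log2-space stage templates (flat, steady decrease/increase, early/late
  peak); with noise 0 the counts are the rounded means, making the
  zero-noise contract exact (flat templates give identical RPKM across
  stages).  Baseline log2 expression is uniform on [8, 11] so that even
  six-fold-decreased genes stay clearly expressed.  Stage 6 → 7
  up/down-regulation is planted per cultivar by independent Bernoulli draws
  at the maturity group's rate (defaults 0.44 post-ripening vs 0.24
  non-post-ripening, the magnitudes the pipeline's group test is designed around), ±4-fold; the
  Bernoulli choice makes realized per-cultivar fractions vary with binomial
  spread, as real cultivars do.  Library sizes are planted per sample and
  carried as the RPKM totals.
- **Annotation:** per-term Bernoulli carriage at a background rate (default
  0.15), optionally with one term's in-subset odds raised to a requested
  odds ratio.

What the generator does **not** model: read-level error, alignment
artifacts, multi-mRNA genes (the classifier supports them; the generator
emits one mRNA per gene), overlapping genes (exercised by hand-built
fixtures in tests instead), UTRs (synthetic exons are fully coding), batch
or library-prep effects, and any real biology of the planted terms.
Passing tests therefore demonstrate algorithmic correctness on data with
the declared structure — not robustness to the messiness of real reads.

## Verification of the group-test power

Two routes exercise the maturity-group Welch test at the planted effect
(0.44 vs 0.24):

1. **Count-level:** the generator plants the fractions, the contrast module
   recovers per-cultivar up-proportions within ±3 points, and at a 300-gene
   fixture the realized within-group spread is binomial (sd ≈ 2.5–3
   points).
2. **Percentage-level power:** per-cultivar up-percentages are drawn at the
   published group means and within-group standard deviations (0.48 for the
   two post-ripening cultivars, 2.83 for the three non-post-ripening ones)
   and Welch-tested; over 100 replicates the test is significant at 0.05 in
   100 of them.  This is the route whose spread matches the published
   percentages exactly; the count-level route has a larger post-ripening
   spread (binomial, not biological) and correspondingly lower power
   (~80%), which is reported here for honesty rather than asserted.

## Numerical and reproducibility notes

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; the CLI derives per-stage seeds from one global seed by hashing the
  stage name, so toggling one stage never reshuffles another's draws.
- Binomial/hypergeometric tails come from scipy; p-values are clamped into
  (0, 1].
- Pearson standardization treats zero-variance rows explicitly (excluded or
  flagged, never NaN).
- Problem sizes in the test suite (40-gene effect fixtures, 300-gene
  expression fixtures, 300 permutations, 20 seeds) were chosen as the
  smallest sizes at which the planted structure is unambiguous; they are
  stated in each test.

## Known limitations

- The presence filter's "expressed" threshold and the up/down fold-change
  rule are conventions, config-exposed; published gene counts from any real
  study depend on the exact upstream read processing and cannot be
  reproduced from counts alone.
- Profile selection is global across cultivars; a per-cultivar profile set
  would change cross-cultivar comparisons.
- The static module cut can split or merge modules that dynamic tree
  cutting would resolve differently.
- Indels and multi-nucleotide variants are counted and skipped, never
  classified.
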
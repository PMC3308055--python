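# Methods

## The analysis problem

A single proband born of a first-cousin marriage is suspected to carry a
recessive causal variant. Linkage is impossible with one affected
individual, but consanguinity concentrates the search space: a variant that
is homozygous by descent must lie in a run of homozygosity (ROH), and for
first-cousin parents the expected autozygous fraction of the autosomal
genome is the inbreeding coefficient F = 1/16. `rohmap` chains the standard
single-proband steps — genotype quality gating, windowed ROH detection,
known-variant subtraction, functional-class filtering, ROH intersection,
conservation ranking — and adds the two side analyses such a case needs:
a heterozygous screen of mitochondrial genes (to exclude a dominant
*de novo* explanation) and qPCR-based mtDNA copy-number assessment (to
distinguish deletion from depletion phenotypes).

Note on expectations: the source analysis style quotes "one eighth of the
genome" as the expected ROH total for first-cousin offspring; standard
pedigree theory gives F = 1/16 (kinship of first cousins), and the package
follows theory throughout. The realized ROH total of a permissive windowed
caller is in any case far larger than F × genome, by design (below).

## Kinship and expected autozygosity

`expected_inbreeding` evaluates the classic kinship recursion exactly over
`fractions.Fraction`:

    φ(i,i) = ½ (1 + φ(father_i, mother_i))
    φ(i,j) = ½ (φ(father_i, j) + φ(mother_i, j)),  expanding the deeper individual,

with founders unrelated. The recursion is safe because the individual
furthest from the founders can never be an ancestor of the other argument.
Unit tests check it against an independent oracle that enumerates every
allele-transmission pattern at a single locus (2 coin flips per non-founder
meiosis) and counts autozygous outcomes: 0 for unrelated parents, 1/4 for
full-sibling parents, 1/16 for first cousins.

## ROH detection

Input genotype calls are gated before detection: indel calls are dropped
(less reliable detection), as are calls with coverage < 8× (unreliable) or
> 100× (duplicated regions and pseudogenes attract excess coverage). Both
retained bounds are inclusive.

Detection is a simplified, site-anchored variant of PLINK-style windowing.
One window of `window_kb` (default 1,000 kb) is anchored at every site; a
window with at most `max_het_per_window` heterozygous calls (default 1) is
homozygous; a site is ROH-supporting when at least `min_hom_window_fraction`
(default 0.05) of the windows covering it are homozygous; maximal runs of
consecutive supporting sites — broken by a non-supporting site or by an
inter-site gap above `max_gap_kb` (default 1,000 kb) — become segments when
they span ≥ `min_segment_kb` (default 1,000 kb) and contain ≥ `min_sites`
(default 25) sites. Segment coordinates are the first and last supporting
site positions, 1-based inclusive in memory, 0-based half-open in BED
exports.

These defaults are deliberately *relaxed*: the purpose of the map is to
avoid overlooking the causal region, not to delimit autozygosity precisely,
and with exome-density sites the detector substantially overcalls —
mirroring the large observed-vs-expected ROH gap typical of this design
(e.g. 992 Mb ≈ 32% of a 3,080 Mb genome against an expectation of 1/16).
What is tested and reported is therefore *recall* of true autozygous base
pairs (≈99% on default synthetic data), not precision. Linkage
disequilibrium is deliberately not modelled or pruned.

Only the window size is pinned by the source design; every other threshold
is exposed. Duplicate input positions are deduplicated (a heterozygous
duplicate wins, the conservative choice for ROH). The implementation is
vectorized with prefix sums and is checked, on random instances up to 100
sites, against a brute-force oracle that enumerates every window and every
candidate run; relaxing any single threshold is verified never to shrink
the total ROH length.

## Exclusion cascade

The cascade applies, in order: the input contract (coding variants only,
logged as stage 0), subtraction of each known-variant set, the functional
filter (missense, nonsense, frameshift, splice site), and ROH membership
(inclusive boundaries, interval-tree backed). Matching is allele-aware on
(chrom, pos, ref, alt); a novel allele at a known site survives. The three
subtractions commute as set operations, so survivor identity is independent
of their order (intermediate counts are not). Zygosity is *not* a cascade
filter — the reference design filters by ROH membership and tolerates
heterozygous calls from low-coverage sites — but a strict `hom_only` option
exists, and the homozygous sub-count after the functional stage is always
reported. A variant's zygosity, when it must be derived from read support,
uses variant-allele-fraction thresholds: ≥ 0.8 homozygous, 0.2–0.8
heterozygous (caller heuristics are unpublished; the thresholds are
consistent with published support columns such as 58/58 hom and 36/69 het).

## Prioritization

Survivors are ranked by phyloP score, descending; ties break by genomic
position so ranking is deterministic under input permutation; a missing
score sorts below every real score (no evidence should not outrank
evidence). The mitochondrial heterozygote screen keeps variants that are
heterozygous, lie in a supplied mitochondrial gene set, are absent from
every extra known set, and have phyloP strictly greater than 2.0.
Inheritance annotation consumes Sanger-style binary carrier flags per
parent plus proband confirmation; both-parents-carrier yields
`either_parent` rather than an error.

## mtDNA copy number

Ratios are 2^[Ct(reference) − Ct(target)] with RNaseP as the nuclear
reference and ND1/ND4 as mitochondrial targets. Replicate wells are
averaged as Cts within each independent reaction; per-reaction ratios are
then averaged across reactions (the replication structure is stated in the
validated protocol this follows; averaging Cts first is the conventional
order and is permutation-invariant). The ND4/ND1 deletion index falls below
1 when deletions spanning ND4 (such as the common ~5 kb deletion)
accumulate. Sample ratios are finally divided by the *arithmetic* mean of
the control subjects' ratios — pooled across reactions — so the normalized
control mean is exactly 1. No PCR-efficiency or standard-curve correction
is applied.

## Synthetic study conditions

The generator reproduces the study conditions rather than idealized data:

- **Pedigree**: the built-in first-cousin structure (shared grandparental
  founder couple → two siblings → two first cousins → proband); arbitrary
  pedigrees are accepted, and an unrelated-parents pedigree yields zero
  autozygosity by construction. Autosomes only (a male proband's hemizygous
  X would contaminate ROH); hg18 autosome lengths by default.
- **Recombination**: Poisson crossover counts at 1 cM/Mb, uniform
  positions, no interference, sex-averaged — the simplest model adequate
  for segment-length statistics. True autozygous segments are exact maximal
  intervals where both proband homologs carry the same founder haplotype.
- **Variant table**: 19,215 coding variants; coverage negative-binomial
  with mean 37 and dispersion 8; allele frequencies uniform on
  [0.05, 0.5]; inside truth segments every call is homozygous, outside it
  is homozygous with the Hardy-Weinberg conditional probability
  q/(2 − q); functional classes at 44.3% overall (missense-dominated).
- **Known sets**: membership independent per set with per-stage novel
  fractions (0.105, 0.91, 0.73), chosen so the expected cascade counts
  reproduce the retention profile of a real single-exome analysis
  (~19,215 → ~2,015 → ~1,833 → ~1,336).
- **phyloP**: background mixture of N(0, 0.8) with weight 0.85 and
  2 + Exp(0.8) with weight 0.15 — mass near zero plus a conserved tail
  above 2, matching the observed score range (2.0–6.7) among printed
  survivors. The causal score (6.741) exceeds the background 99th
  percentile (≈4.2) by construction.
- **Genotype sites for ROH**: 10 per Mb (≈31 k genome-wide, the density of
  usable exome SNV calls), heterozygote error 0.002 inside autozygous
  segments, 3% indels.
- **Causal variant**: exactly one, homozygous missense, novel in every
  set, planted in the central half of an autozygous segment chosen
  uniformly among those ≥ 5 Mb (falling back to the longest). The size
  floor is a design constraint, not a convenience: at 10 sites/Mb a
  segment below ~2.5 Mb cannot contain the 25 sites any windowed caller
  needs, so an unconstrained placement would make "the causal variant is
  recoverable" false for reasons unrelated to the pipeline. Generation
  fails loudly if no autozygous segment exists in a realization (possible
  on small single-chromosome genomes; negligible at genome scale).

All randomness flows from a single integer seed; the same seed yields
byte-identical tables, sites, known sets and truth.

### What the generator does not emulate

Linkage disequilibrium, mutation-rate heterogeneity, clustering of exonic
sites into genes, reference bias, population allele-frequency structure,
X/Y/mtDNA, and sequence-level artifacts. Passing tests therefore
demonstrate correctness of the algorithms and the statistical behaviour of
the design (autozygosity fractions, cascade retention, causal recovery),
not robustness to real-exome artifacts.

## Problem sizes and numerical choices

Monte-Carlo autozygosity uses 2,000 single-chromosome (150 Mb) replicates
and is compared to 1/16 within three standard errors; causal
survival/ranking rates use 100 full-genome pipeline runs at the default
conditions; ROH oracle equivalence uses random instances up to 100 sites
(the brute-force oracle is cubic). Kinship is exact rational arithmetic;
2^ΔCt identities hold to machine precision and are tested at ~1e-12
tolerances. Chromosome labels are opaque strings; natural ordering
("2" < "10") is used for deterministic output sorting, and `chr`-prefix
stripping is always explicit.

## Known limitations

The windowed caller's boundaries have site-spacing resolution, so short
true segments (< ~2.5 Mb at default density) are invisible — accepted, and
compensated by the causal-placement floor. The mitochondrial screen's
novelty step depends entirely on the supplied stand-in known sets. The
cascade treats functional class as input annotation; no transcript-model
annotation, variant normalization or multi-allelic decomposition is
performed.
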
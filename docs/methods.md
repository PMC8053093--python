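# Methods

This note documents the models, conventions and numerical choices behind
`replimut`, in the spirit of a methods supplement: what each stage computes,
which knobs matter, and what the synthetic-data generator does and does not
emulate.

## Coordinates and conventions

All coordinates are 1-based and inclusive (VCF convention). Substitutions
are always described as read on the reference (Watson) strand; the
pyrimidine-referenced representative of a class (`A>C` → `T>G`) is used
wherever complementary pairs are pooled. Indels are left-aligned before any
classification: a shared terminal base is repeatedly traded for the
reference base to its left until the representation is leftmost, then shared
leading bases are trimmed. Left-alignment is idempotent and leaves SNVs
untouched; it guarantees that a conserved homopolymer context sits 3' of the
recorded indel position.

## Variant filtering

The filter chain reproduces a conservative MA-experiment workflow in five
ordered stages. Hard thresholds (strict `<` comparisons, flags added rather
than records removed) are DP < 10, DV < 3, QUAL < 100 for SNVs and < 30 for
indels, GQ < 40, plus a `snp_gap` flag for SNVs within 7 bp of any indel in
the same sample. Missing DP/DV/GQ fields fail the corresponding check by
default (conservative; configurable). Control subtraction removes exact
(chrom, pos, ref, alt) matches against variants seen in control samples and
is idempotent.

The prevalence-scaled quality filter is the cohort-level defence against
systematic sequencing errors: in a bottleneck design a genuine mutation is
expected in one line (two colonies at most under single-cell propagation),
so a call shared by many samples is suspect unless its quality is high. A
record is removed when `QUAL < intercept + slope x prevalence`, prevalence
being the number of distinct samples carrying the identical variant after
the preceding stages (counting after, not before, hard filtering is a
deliberate choice: hard-filter failures should not inflate prevalence).
Defaults are intercept 60 with slope 15 QUAL-units per carrier for
single-cell cohorts and slope 2 for small-population cohorts, where
legitimate sharing through colony ancestry is expected; the shallower slope
is what "less stringent" means operationally. These two slopes were
calibrated once on synthetic cohorts so that total removal falls in the
~1-10% band while recurrent artifacts (which cluster at low-to-middling
QUAL) are eliminated; both are exposed in `FilterConfig`.

Colony intersection retains a variant only when every sequenced colony of a
single-cell line carries it (all variants of a sole colony are kept);
variants present at passage 0 are removed in both modes. Per-line
deduplication keeps one representative per variant per line — highest QUAL,
ties to the lexicographically smallest sample id — so shared ancestry in
small-population cohorts does not over-weight a single mutagenic event.
The chain is order-stable: permuting input record order cannot change the
final set.

Ploidy is inferred from the median allele frequency of a sample's de-novo
calls: above 0.75 (midway between the haploid expectation 1.0 and the
heterozygous-diploid expectation 0.5) calls haploid, at or below calls
diploid, and fewer than five informative alleles is indeterminate (no
mating-type fallback is implemented; such samples are simply flagged).
Genotype confirmation translates the consensus codon for the residue of
interest with the standard genetic code; codons containing N are
indeterminate rather than failures, and stop codons fail with an explicit
note.

## Replicon model

Each confirmed origin is reduced to the floor of its ARS-interval midpoint;
consecutive midpoints on a chromosome bound an inter-origin span whose own
midpoint is declared the termination point — an admitted simplification, as
real termination zones are broad and stochastic. A mutation inside a span is
summarised by its relative distance from the left origin as a percentage of
the span (0% at the origin, 50% at termination, 100% at the next origin).
Spans are half-open: a position equal to an interior origin midpoint opens
the next span, positions before the first or after the last origin of a
chromosome are discarded with a logged reason, and chromosomes with fewer
than two confirmed origins contribute nothing. Boundary conventions, on
which the source material is silent: exactly 50% is lagging (leading is
[0, 50)), and exactly one-third is the middle third. Under these definitions
leading and lagging territory each cover exactly half of the origin-bounded
genome, which is what licenses the 50/50 null in the strand-bias test.

## Spectra and signatures

SNVs are assigned to one of 96 channels (pyrimidine-referenced class x 5'
base x 3' base, COSMIC file order). Purine-reference mutations are reverse
complemented together with their context; context always comes from the
reference genome, not the VCF line, and a REF/genome disagreement is an
error rather than a silent skip. Mutations at chromosome ends or with N in
the context are excluded and counted.

Genome normalisation divides each channel frequency by the relative
abundance of its trinucleotide in the genome and renormalises, converting
"share of mutations" into "per-available-site intensity". The census counts
every overlapping 3-mer on the reference strand (windows containing N
excluded, no partial windows at chromosome ends) and by default collapses
each 3-mer with its reverse complement into the pyrimidine-centred
representative — matching the channel definition; an uncollapsed census is
available and is summed with its reverse complement when used for
normalisation, so the two modes agree. Signature comparison is plain cosine
similarity against the 96-vector columns of a COSMIC-dialect probability
table, reconciled by channel label; no pseudocounts are applied to sparse
spectra.

## Strand bias

A mutation read as `A>C` in lagging territory is the same fork event as
`T>G` in leading territory, so the pair statistic pools both readings into
one leading/lagging count oriented to a chosen frame. Significance is a
one-degree chi-square goodness-of-fit of the two-cell collapse against
50/50 (the binned density profiles are display-level output, not the test),
with no continuity correction and, by default, no multiple-testing
correction across the six pairs (a Bonferroni option exists). Effect size
is Cohen's w = sqrt(sum (p_obs - p_exp)^2 / p_exp), which for two cells
equals sqrt(chi2 / n); a 3:1 odds ratio corresponds to w = 0.5. Totals
below 10 are reported but flagged underpowered with no significance call.

## Sequence context and indels

Context matrices record base frequencies at positions -2..+2 around each
SNV, keyed by raw mutation type (both members of a complementary pair are
kept separate) and by side: "right" of the nearest origin (first half of
the span, leading side) or "left" (second half). By default only mutations
in the first and last thirds of a replicon are counted, trimming positions
where synthesis past the presumed termination midpoint would blur the
strand assignment.

Indels are classified by their inserted/deleted unit (+A, -T, +TA, ...;
units over 2 nt are pooled as "other" but kept in totals) and by the
reference homopolymer run starting at the base immediately 3' of the
left-aligned anchor — for deletions this run includes the deleted bases
themselves, which are reference bases 3' of the anchor. The run length is
checked against a brute-force scan in the tests. Strand class comes from
the replicon model at the anchor position. Sequence-logo rendering is not
implemented; the frequency matrices are the tested artifact and plot
tooling can consume the TSV output.

## Rates

MA rates are mutations passing all filters per line, divided by passages
and by a ploidy divisor (2 for diploids, so rates are per haploid genome; 1
with a flag when ploidy is unknown). Conversion to per-generation per-bp
uses 12,071,326 bp and 20 generations per passage for single-cell
propagation or 6 doublings per growth cycle for small-population
propagation; the conversion is exact and invertible. Genotype summaries use
the median across lines (mean available). For a double mutant with single
fold changes f_a and f_b over the reference, the additive expectation is
f_a + f_b - 1 and the multiplicative expectation f_a x f_b; observed folds
exceeding both indicate synergy.

Fluctuation assays use the Lea-Coulson formulation of the Luria-Delbrueck
distribution: p_0 = exp(-m), p_n = (m/n) sum_{i<n} p_i / (n-i+1). The
Ma-Sandri-Sarkar MLE maximises this likelihood with jackpot censoring:
counts at or above a cap (default 512) contribute the tail probability
P(X >= cap), which keeps the O(cap^2) recursion cheap without discarding
jackpot cultures. The 95% interval is the profile likelihood (drop of
chi2(1)/2 = 1.92). The P0 closed form m = -ln(fraction of zero-mutant
cultures) serves as a cross-check and fails loudly when no culture is
mutant-free. All-zero counts give the boundary estimate m = 0; cultures
that are entirely mutant make m unbounded and raise. No plating-efficiency
correction is applied. The rate per cell per division is m divided by the
final population size.

## Synthetic cohorts

The generator exists so every downstream statistic can be scored against
known truth. A toy genome (default two 100 kb chromosomes, uniform base
composition) carries planted 3-6 nt T-homopolymers with non-T flanks
(recorded in a registry) and confirmed origins every ~15 kb with +/-10%
jitter. SNVs are drawn channel-first: a channel from the configured
96-vector, then a site uniformly among all genomic positions whose
reference trinucleotide matches the channel context on either strand,
restricted to origin-bounded territory so every planted mutation has a
defined strand class. Site weights implement per-class leading:lagging
odds (the complement of a configured class defaults to the reciprocal, the
same fork event seen from the other strand); sampling is with replacement,
because drawing without replacement would deplete high-weight sites and
flatten the realised odds — only the cohort generator enforces per-sample
position uniqueness, where the draw count is far below the site pool.
Defaults emulate a proofreading-mutant arm: odds 3 for A>C/A>T/G>T on the
leading strand (Cohen's w 0.5 at the two-cell collapse) and 1.5 for
A>G/G>A, 26 passages, diploid lines, two colonies each.

Slippage indels are emitted at A/T homopolymer runs: the leading-strand
polymerase slipping on a T template surfaces in reference coordinates as
+A/-A at A-runs in leading territory and +T/-T at T-runs in lagging
territory, left-aligned. Read-level quantities are modelled minimally: DP ~
Poisson(40), DV ~ Binomial(DP, AF) with AF 1.0 (haploid) or 0.5 (diploid),
QUAL uniform in a genuine-call band (120-225), GQ uniform 50-99. Artifacts
are positionally identical across their carrier samples (default 50
artifacts in 10 samples each) with QUAL in a lower band (110-180) that
passes hard filters but falls under the prevalence threshold at high
prevalence. Passage-0 variants appear in a line's passage-0 sample and all
its colonies; background variants appear in every sample including the
control. Small-population lines share a fixed fraction (default 0.5) of
ancestral mutations per line, giving expected pairwise colony Jaccard
f/(2-f). All randomness flows from one seed; a fixed seed reproduces the
cohort bit-identically, VCFs included.

What the generator does not emulate: read-level errors and alignment
artefacts (quality fields are drawn, not derived from reads), selection and
fitness effects across passages, replication timing or passive origin
firing, clustered/complex mutations, and real yeast base composition or
chromosome structure. Tests passing on these cohorts therefore validate
the statistical machinery and bookkeeping, not the upstream calling
pipeline, and effect sizes recovered here say nothing about how noisy real
short-read data would be.

## Problem sizes in the test and acceptance suites

The routine checks use cohorts of 6-10 lines with ~50-500 SNVs per sample
on 2 x 100 kb genomes, 6,000-20,000 draws for asymmetry and spectrum
recovery, 100 replicates for error-rate calibration, exhaustive 100 kb
scans for the locate oracle, and 10,000 cultures for the fluctuation MLE —
sizes chosen to make binomial/multinomial standard errors small relative
to the tested tolerances while keeping the whole suite fast.

## Known limitations

Termination-at-midpoint is a geometric idealisation; profiles near 50%
blur in reality and no correction is attempted. The prevalence-filter
slopes are calibration choices, not estimates of any laboratory's values.
The two-cell chi-square discards positional information within a span.
The fluctuation model assumes constant mutation rate, no phenotypic lag,
full plating efficiency and deterministic clone growth. The CLI is a thin
dispatch layer; anything beyond the provided subcommands is meant to be
done through the Python API.
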
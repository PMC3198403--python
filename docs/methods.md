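# Methods

## Scope and data flow

The package covers the analysis stages downstream of read alignment for
dUTP strand-specific RNA-seq. Annotation-dependent assets (gene models,
the intron database, non-coding regions, base-composition profiles) are
computed once per genome; per-run stages (demultiplexing, counting,
background estimation, detection, normalization, metagene profiles)
consume alignments and the prepared assets. Alignment itself, splice
junction discovery, isoform quantification and differential expression
between conditions are out of scope.

Coordinates are 0-based half-open internally; GFF3/GTF (1-based
inclusive) are converted at I/O. Each gene is represented by the exon
chain of its longest isoform ("unique gene models"); the all-isoform
exon union is available via `isoform_rule="union"`. Introns are indexed
1-based in transcript (5'→3') orientation, so on '−'-strand genes the
genomically last gap is intron 1.

## Background rate λ₀

A non-coding region is a maximal interval whose every base is at least
`min_distance` (default 5000 bp) from any annotated exon. Padding whole
gene spans instead of exons is available (`pad="span"`) but exons are
the default: the exon set is the operational definition of annotated
transcribed sequence. Regions above the 99th percentile of
length-normalised coverage (LNC = reads/bp) are excluded — they are
usually unannotated genes — and λ₀ is the pooled ratio Σcounts/Σlength
over the retained regions, which is the maximum-likelihood estimate of a
shared Poisson rate and equals the length-weighted mean LNC. The
percentile uses the linearly interpolated empirical quantile with ties
retained. A λ₀ of exactly 0 is floored at 1/(retained length) so the
null Poisson never degenerates. NCRs are unstranded and both strands are
counted; one λ₀ is shared by the gene, antisense and intron tests.

The exclusion rule assumes contamination of at most one region in a
hundred; when the contaminated fraction fluctuates above the percentile
(e.g. Bernoulli 1 % contamination of only 100 regions), the occasional
second hot region enters the retained set and inflates λ₀ — a property
of the percentile rule itself, not of this implementation.

## The detection test

Pooled counts Y_g over technical replicates are Poisson (replicates are
summed; Poisson additivity absorbs the replicate count). The point null
is λ_g = λ₀; under the alternative λ_g ~ Gamma(a, b) (shape/rate —
chosen because the prior mean is then a/b), giving the negative binomial
marginal evaluated in log space throughout. Posterior odds
B = π₀·Pois(y; Lλ₀) / ((1−π₀)·NB(y; L, a, b)); detection is strict
B < 1; the FDR of a detected set is the mean of p₀ = B/(1+B) over the
set, and the threshold-vs-FDR curve is emitted alongside. π₀ = 1 yields
B = +∞ (nothing detected); π₀ = 0 yields B = 0 with a warning.

**π₀ estimation.** π₀ is the fraction of units with LNC below λ₀. This
plug-in is consistent only in the sparse-background regime L·λ₀ ≪ 1
(silent units essentially read-free). Its exact expectation is

    E[π₀̂] = π₀·P(Pois(Lλ₀) ≤ K) + (1−π₀)·P(NB(a, b/(b+L)) ≤ K),

with K the largest count strictly below L·λ₀. For L·λ₀ ≈ 1.5 a silent
unit falls below its own mean only ~56 % of the time, so π₀̂ can
undershoot π₀ by nearly half. Tests therefore check the estimator
against this expectation, and check recovery of π₀ itself only where
the estimator is consistent.

**(a, b) fitting.** Given λ₀ and π₀, (a, b) maximise the
negative-binomial marginal log-likelihood over units with LNC ≥ λ₀.
Optimisation is Nelder–Mead in (log a, log b) from a method-of-moments
start (Gamma variance estimated as the excess of Var(y/L) over the mean
Poisson term), converging to 1e-8 on the objective; non-convergence
raises with the last iterate. On data drawn purely from the marginal the
fit recovers (a, b) to a few percent at 5000 units. The LNC ≥ λ₀
stratification left-truncates the expressed stratum and admits
background units with a stray read, which biases the fitted shape
downward when background occupancy is non-negligible — the same regime
caveat as for π₀.

**FDR calibration.** When the model is correctly specified and scored
with its generating parameters, p₀ = B/(1+B) is the exact local
false-discovery probability, so the mean of p₀ over the detected set is
an unbiased estimate of the expected false-discovery proportion; the
calibration tests verify this over 200 simulation replicates for both
the gene and intron tests. The full plug-in pipeline inherits the π₀
bias above: with L·λ₀ ≈ 1.5 its estimated FDR understates the realized
FDP by roughly a factor of two (both remain small); this is covered by a
separate pipeline test and should be kept in mind when quoting FDRs from
deeply sequenced data against short gene models.

## Intron retention

For intron i of gene g: X ~ Poisson(L_i·λ₀) under H₀ and, by default,
X ~ Poisson(L_i·E_g·r) with r ~ Gamma(a, b) under H₁, where E_g is the
host gene's summed across-replicate RPKM — intronic signal is assumed
proportional to transcription, so identical evidence is weaker for a
highly expressed gene. That ordering (larger E_g ⇒ larger B at fixed x,
L_i) holds once the predicted retained count L_i·E_g·a/b is at least the
observed count; below that, raising E_g first moves the prediction
toward the data and B decreases. An additive variant with H₁ mean
L_i·(E_g·r + λ₀), evaluated as an exact Poisson⊗NB convolution, is
available behind `additive_background=True`. Introns of genes with E_g
at or below the expression floor (default: 0, strictly) are reported
untestable and excluded. π₀′ and (a, b) are estimated as in the gene
test, with exposure offsets L_i·E_g.

## Counting rules

Only primary, uniquely mapped alignments count (configurable). A read
counts toward a gene on ≥ 1 bp exonic overlap; reads touching the exon
space of more than one gene are discarded as ambiguous. A read counts
toward an intron only when at least half of it lies inside the intron,
so junction reads are not retention evidence; NCR counting is
strand-agnostic with boundary reads going to the majority region; exact
ties are discarded in both. Under `orientation="reverse"` (dUTP) an
alignment opposite the gene strand is sense. Interval lookups use an
interval tree and are tested for exact agreement with quadratic
brute-force enumeration.

Metagene profiles are computed in spliced (exonic) coordinates, 5'→3',
over genes with exonic length ≥ n_bins (default 100): coverage profiles
normalise each gene by its mean coverage before averaging across genes;
the antisense profile pools per-bin sense/antisense coverage across
genes and reports 100·antisense/(sense+antisense), NaN where total
coverage is zero. Composition profiles (%GC, %T) follow the same
binning on the mature transcript sequence.

## Demultiplexing

Index sets are validated for minimum pairwise Hamming distance ("edit
distance" over fixed-length indices means substitutions; a Levenshtein
validator via edlib is included for designing new sets) and per-position
base balance. Reads are assigned to the unique index within
`max_mismatch` (default 1) Hamming distance of their first k bases; ties
are unassigned even in distance-2 sets, because distance 2 does not
guarantee unambiguous one-error correction. Assigned reads are trimmed
of the index plus the common base(s); the common base is configurable in
number and position multiplicity (default one T after a 5-base index; a
7-base variant ships as well) and never affects assignment. The shipped
example sets (`set11x5`, `set4x7`) are balanced with minimum pairwise
distance ≥ 2.

## Normalization comparison

Factors per replicate: total counts; upper quartile of nonzero counts;
TMM with the method's published defaults (30 % log-ratio trim, 5 %
intensity trim, precision weights, reference column = the one whose
0.75-quantile of count/libsize is closest to the mean), multiplied by
library size to give an effective depth; spike-in column sums. All are
rescaled to geometric mean 1. The TMM implementation is checked against
edgeR's `calcNormFactors` to 1e-6 in the test suite. The
goodness-of-fit diagnostic computes, per gene, the chi-square
homogeneity statistic of replicate counts against expected counts
d_j·Y_g·/Σd — invariant to global factor rescaling — and pairs observed
quantiles with χ²(n−1): factors that leave technical replicates
Poisson-homogeneous put the QQ curve on the diagonal, while mis-scaled
factors (e.g. noisy spike-in capture) inflate it.

## Synthetic data

The generator emulates the target study design: a single chromosome with
non-overlapping genes separated by ≥ 12 kb (so 5 kb-padded exons leave
non-empty NCRs), 1–5 exons of 150–400 bp with 80–300 bp introns,
uniform random sequence; single-end 35 nt reads placed uniformly (or
3'-weighted, emulating oligo-dT capture) along the spliced body and
clipped at exon junctions so every alignment is a single block; dUTP
strand convention with a default 2 % antisense contamination; gene
counts from the two-component model with defaults λ₀ = 0.001 reads/bp,
π₀ = 0.4, Gamma(2, 20) expression prior (prior mean 0.1 reads/bp, ~100
pooled reads on a 1 kb gene — a desk-scale transcriptome), three
technical replicates; intron counts with a 10 % retained fraction and a
Gamma(2, ·) retention-rate prior whose mean defaults to ten times
background density. Multiplexed FASTQ carries index + common T +
random insert with independent per-base substitution errors. All
entry points take explicit seeds and are byte-deterministic under them.

What the generator does **not** emulate: sequencing quality scores,
indels, paired ends, multi-mapping, splice-junction reads (alignments
never span an intron), GC- or mappability-dependent background, and
biological-replicate overdispersion. Passing tests therefore demonstrate
correctness of the algorithms and calibration under the stated model,
not robustness to those real-data effects.

## Problem sizes and numerical choices

Test and acceptance simulations use 1 200–5 000 genes, 700–10 000
introns, ≤ 100 kb oracle genomes with ≤ 5 000 reads, 10⁵ demultiplexed
reads, and 40–200 replicates per calibration — sizes at which every
stochastic tolerance (3 SE bands, 10–15 % parameter recovery) is
meaningful while the whole suite stays fast. Probability arithmetic is
in log space; quadrature oracles integrate over the posterior's
support (Gamma(y+a, b+L) quantiles 1e-14 to 1−1e-14) to keep adaptive
integration honest for peaked integrands; the additive intron variant
uses an exact finite convolution. Degenerate inputs (empty NCR sets,
zero-length regions, all-zero columns, missing spike-ins, unknown
chromosomes) raise or warn as documented in the docstrings.
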
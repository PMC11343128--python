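# Methods

## From reads to molecules

A droplet experiment observes molecules, not reads: a molecule is a
(cell barcode, UMI, feature) triple, and reads are evidence about it.
`snase` resolves each read first, then collapses.

**Read resolution.** Multimapping reads (`NH > 1`) and reads failing the
upstream WASP reference-bias filter are excluded outright. Each
remaining read carries per-SNP observations (reference base, alternative
base, or neither — the last is dropped). Observations at sites not
heterozygous in the analysed individual are dropped with a warning. If
the surviving observations disagree, the majority allele is taken only
when its share of observation entries is *strictly* greater than 0.95;
otherwise the read is excluded. The share is computed over evidence
entries, not distinct SNPs, so a SNP seen twice counts twice. In phased
mode each observation is first translated to haplotype 1/2 through the
SNP's phased genotype (reference under `0|1` lies on haplotype 1, under
`1|0` on haplotype 2); with every genotype `0|1` this reduces exactly to
the unphased labelling, a property the tests assert.

**Collapsing.** One call per distinct triple: the common allele if all
of its reads agree, else *ambiguous*. Ambiguous molecules are counted
and reported but never enter allelic ratios. Per-SNP counting uses the
same collapsing keyed by (cell, UMI, SNP), with each read contributing
its own observation at each SNP it physically covers; peak-level
counting reuses gene logic on peak labels (same strand, all alignment
blocks contained in the peak's intervals).

Unphased counting genuinely loses molecules that phased counting keeps:
a read covering two SNPs whose genotypes are oriented oppositely
(`0|1` and `1|0`) shows one reference and one alternative base even
without sequencing error, fails the majority rule, and is excluded.
This is the expected behaviour, not an artefact.

## Isoform assignment

The reference isoform set is extended with one *unspliced* pseudo-isoform
per gene spanning the whole gene body, standing in for pre-mRNA — the
dominant species in single-nucleus data. Candidate isoforms are those
whose extent overlaps the read (interval tree per chromosome). For each
candidate, exon blocks are trimmed to the read's extent and the base
overlap with the read's blocks (gaps ≤ 10 bp pre-merged) is computed. A
candidate survives only if the overlap reaches 95% of **both** the
trimmed isoform length and the read length. The largest surviving
overlap wins unless another survivor comes within 10 bp (strictly less),
in which case the read is discarded as a tie. Reads with several
equally best-scoring alignments are discarded before assignment.

The both-criteria rule is the deliberate design choice here. The
unspliced candidate, trimmed to the read's extent, always covers every
read base, so a rule that keeps candidates meeting *either* criterion
would leave it tied with any spliced candidate and nothing would ever be
assigned to a spliced isoform. Under the strict rule the outcomes are
biologically sensible: junction-spanning reads defeat the unspliced
candidate (which then fails its isoform-side criterion); intron-touching
reads defeat all spliced candidates; and a contiguous exon-contained
read — which pre-mRNA explains just as well as mRNA — ties and is
discarded as genuinely ambiguous. The lenient reading remains available
(`strict_95=False`). Strand is ignored during candidate lookup by
default (`stranded=True` restricts to same-strand isoforms), and ties
are evaluated among surviving candidates only.

## The beta-binomial layer

Counts are oriented before testing: per-individual haplotype-level gene
counts are re-labelled so that "reference" means the haplotype carrying
the anchor SNP's reference base (`0|1` keeps, `1|0` swaps, non-het
individuals are dropped). All individuals then share a sign convention
and one regression tests the SNP's effect on the gene.

With y reference-oriented molecules out of n per unit,

    y ~ BetaBinomial(n, mu, rho),  logit(mu) = x'beta (+ b_j),
    b_j ~ Normal(0, sigma_b^2),

where in terms of the beta shapes mu = a/(a+b) and rho = 1/(a+b+1), so
rho ∈ [0,1) is the intra-unit correlation and rho → 0 the binomial limit
(taken analytically below 1e-8 to avoid catastrophic cancellation in the
gammaln differences). The intercept is the imbalance effect; its Wald z
against 0 is the default test, with a likelihood-ratio alternative via
`Results.lr_test`. Differential imbalance replaces the formula with
`~condition` and reports the condition coefficient's Wald test. The
peak-vs-gene comparison stacks peak and rest-of-gene observations
(rest = gene − peak, clamped at zero with a warning when inconsistent;
skipped when the peak holds everything) and tests an is-peak indicator.

**Numerics.** rho is optimised as logit(rho) and sigma_b as log(sigma),
keeping the search unconstrained; starting values are the pooled ratio
for the intercept, rho = 0.01 (pseudobulk), and for the mixed model the
pseudobulk fit on per-individual aggregates. Gradients are analytic.
The mixed marginal likelihood uses adaptive Gauss–Hermite quadrature
(default 20 nodes): per group the integrand's mode is found by
safeguarded Newton steps with analytic first/second derivatives and the
nodes are centred and scaled by the curvature there; scores use the
Fisher identity (posterior-weighted complete-data scores) under the same
nodes. Standard errors come from the observed information, computed by
central differences of the analytic score; at a variance-component
boundary (rho → 0 on symmetric data, sigma_b → 0) the information matrix
is singular in that direction and a pseudo-inverse supplies the
fixed-effect block, with the boundary flagged. BFGS exits reporting
"precision loss" with a gradient below 1e-3 are accepted as converged
and flagged, since float64 cancellation in the log-likelihood prevents
reaching tighter gradient norms on well-identified optima. Fits are
cross-checked in the test suite against glmmTMB's betabinomial family
(frozen reference values): the pseudobulk fit agrees to ~1e-4 in all
quantities, the mixed fit to a few 1e-3 (glmmTMB uses a Laplace
approximation where this package uses adaptive quadrature, so exact
agreement is not expected — the quadrature log-likelihood is slightly
higher).

**Inclusion filters.** A feature is tested when at least 2 individuals
contribute informative counts and at least 5 phased molecules exist in
total (`min_individuals`, `min_total`, both configurable). Features
below threshold are reported with an `insufficient_data` flag rather
than dropped silently.

**Calibration by permutation.** `permute_alleles` swaps n_ref and n_alt
with probability 1/2 per (individual, feature) — one decision shared by
all cells of that pair, so cell-level tables stay coherent — preserving
totals while destroying any true imbalance. `fpr_experiment` repeats
this, retests every feature, and reports the per-replicate fraction of
features with p < 0.05 and its median. `downsample_individuals` draws a
seeded uniform subset and returns the chosen ids for reuse across
parallel analyses.

## Synthetic data

`simulate_counts` draws from exactly the generative model the mixed test
assumes: per (gene, individual) random intercepts, per-cell
negative-binomial molecule depth (default mean 5, size 2 — sparse
snRNA-seq scale), beta-binomial allele draws. Defaults: 40 individuals,
50 cells each, 50 genes, sigma_b = 0.5, rho = 0.05. For experiments that
need "true imbalance then permuted away", per-gene effects are drawn
from Normal(0, 0.5²) — a moderate scale at which most genes have
noticeable but not extreme imbalance; chosen once and not tuned.

`simulate_read_fixture` lays out toy genes (5 exons of 400 bp, 800 bp
introns, two spliced isoforms of which the second skips one internal
exon, plus the implicit unspliced isoform) with one het SNP per exon and
per intron, and generates molecules of three truth classes: unspliced
(single block straddling an exon/intron boundary), spliced
(junction-spanning read over the isoform-discriminating junction) and
exonic (contiguous exon-contained block, deliberately ambiguous). Allele
evidence follows the molecule's haplotype through the phased genotypes,
with an optional symmetric per-observation flip rate to exercise the
majority rule and ambiguous molecules; multimapper and WASP-failure
flags are set on configurable fractions of reads. Everything is
deterministic given the seed, and fixtures can be written out as
GTF/VCF/SAM/BED plus TSV truth tables.

What the generator does **not** emulate: barcode/UMI sequence errors,
fragment-length and positional (3' bias) effects, platform-specific
indel error profiles, doublets, ambient RNA, or genes overlapping on
the same strand. Passing tests therefore demonstrate correctness of the
counting/assignment/testing logic under clean structural assumptions,
not robustness to every artefact of real libraries.

## Problem sizes and reproducibility

The test suite and the acceptance script use desk-scale problems chosen
as the package's own study conditions: the calibration experiment runs
100 permutations of a 50-gene × 40-individual dataset; counting and
isoform oracles use ~5,000- and ~500-read fixtures; parameter recovery
uses 100 replicates of 50 individuals × 50 cells per effect size. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configuration and seed give
byte-identical outputs.

## Known limitations

- SNPs only: indel evidence is excluded from allele assignment, and
  multiallelic VCF records are skipped rather than split.
- No barcode error correction or UMI sequence-error collapsing beyond
  exact match.
- Wald tests can be slightly anticonservative at very small numbers of
  individuals; the mixed model inherits the usual boundary issues when
  sigma_b is near 0 (flagged, not corrected).
- The per-feature loop refits genes independently; no information is
  shared across genes (no shrinkage of rho or sigma_b).
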
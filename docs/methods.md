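# Methods

## Coordinates, reference and catalogue

All positions are HGVS-style c.-coordinates over the 873 bp intronless
coding exon, 1-based from the A of the initiator ATG. Typing uses
coding-exon positions only; an amplicon's flanking bases are mapped into
c.-space by the aligner and substitutions outside [1, 873] are reported but
never typed, because every allele definition in the nomenclature is stated
in c.-notation.

The bundled reference FASTA (`nat2_reference_synthetic.fasta`) is a
**synthetic stand-in** for the NAT2*4 coding sequence: 873 bp, starts with
ATG, and carries the correct reference base at all thirteen catalogued SNP
positions (c.33C, c.82C, c.191G, c.282C, c.341T, c.345C, c.481C, c.518A,
c.590G, c.609G, c.622T, c.803A, c.857G); the remaining bases are generated
filler. Every computation in the package — alignment mapping, IUPAC
decoding, haplotype bookkeeping, typing, statistics — depends only on
length, coordinates and the catalogued bases, so results are unaffected by
the filler. Users analysing real traces should substitute the GenBank
coding sequence via `load_reference`.

The SNP catalogue carries the seven globally common variants with their
rsIDs and synonymy (c.191G>A, c.282C>T, c.341T>C, c.481C>T, c.590G>A,
c.803A>G, c.857G>A; note c.803A>G is nonsynonymous, p.Lys268Arg, yet
phenotypically conservative) plus six rarer variants that appear in newer
haplotypes (c.33C>A, c.82C>T, c.345C>T, c.518A>G, c.609G>T, c.622T>C),
whose synonymy is left `unknown`.

## Nomenclature table, groups and functions

The default table ships 21 alleles: the ten common alleles with printed
SNP-composition matrices, nine newer alleles likewise printed, and the two
additional rapid alleles named in the survey text (NAT2*11A as the bare
c.481C>T signature haplotype; NAT2*12C as c.481C>T + c.803A>G, its
consensus composition). Functions: the ten common alleles as printed
(rapid: \*4, \*12A, \*12B, \*13A; slow: \*5A, \*5B, \*5C, \*6A, \*7B,
\*14B); \*11A and \*12C rapid; newer alleles carrying the c.341T>C slow
signature (\*5AA, \*5BA, \*5BB, \*5CA) slow; \*12Q, \*12R, \*12S, \*13H and
\*28 `unknown` — their phenotypic effect is not established, and an
unknown-function allele propagates to an ND phenotype rather than a guess.

Allelic groups are assigned by the first signature variant present, in the
priority order **191 > 341 > 590 > 857 > 803 > 481 > 282** (then 622 →
\*28; empty → \*4). The slow block leads because any slow signature defines
the group regardless of accompanying conservative variants (\*5B carries
481 and 803 yet is \*5; \*6A carries 282 yet is \*6). Within the rapid
block, 803 must outrank 481: alleles carrying both (e.g. \*12C, \*12S)
belong to the \*12 group in the consensus nomenclature. The relative order
inside the slow block never fires on catalogued alleles (no named allele
carries two slow signatures) and is fixed purely for determinism. c.622T>C
is not one of the seven classic signatures, but the 622-only haplotype has
its own group symbol (\*28), so the signature map is extended accordingly.

Novel (untabled) haplotypes are reported as `novel` with a
signature-derived group; they are classed slow when they carry a slow
signature and `unknown` otherwise — a deliberately conservative rule that
sends such samples to ND instead of inventing a function.

## Variant calling

Fragment merging seeks the longest suffix/prefix overlap ≥ 30 bases in
which ≥ 80% of positions are IUPAC-compatible; within the overlap,
base-vs-compatible-code disagreements resolve to the more ambiguous code
and incompatible bases to N. The published workflow does not state its
conflict-resolution rule, so this contract is the module's own.

Alignment is global pairwise with match +1, mismatch −1, gap open −5, gap
extend −1; an ambiguity code scores as a match against any compatible base
(via a substitution matrix over the 15-letter IUPAC alphabet, Biopython's
`PairwiseAligner`). Samples below 80% compatible-column identity are
rejected — an unrelated random sequence sits near 25%. Calls at catalogued
sites: plain base → homozygote; the exact two-base code {ref, alt} →
heterozygote; N, three/four-base codes, third alleles, or sites falling in
alignment gaps → missing. Indels are tolerated by the aligner but not
genotyped. Diploid data cannot support more than two alleles at a site,
hence multi-base codes are missing data, not calls.

## Phasing

Haplotype frequencies are estimated with the gene-counting EM of Excoffier
& Slatkin: E-step weights each compatible unordered pair (h₁, h₂) by
2^[h₁≠h₂]·f(h₁)·f(h₂), M-step re-counts chromosomes; iteration stops when
the log-likelihood gain drops below 1e-8 (default) or at 500 iterations.
The log-likelihood is asserted non-decreasing on every fit. Initialisation
is uniform over the haplotypes compatible with at least one sample;
frequencies below 1e-12 are pruned. A deterministic EM was chosen over a
Bayesian MCMC sampler deliberately: for a single short locus with at most a
couple of dozen segregating sites it reaches the same fixed point on every
run, with no chain diagnostics, and is verified in the tests against a
dense brute-force EM over the complete 2^k haplotype space.

Pair enumeration is capped at 12 heterozygous sites (2048 pairs). Samples
with ≤ 2 missing catalogued calls are marginalised by enumerating the 3^m
diploid fill-ins; beyond that the sample is excluded from fitting and
reported unphased — the pair space grows too fast and such a sample carries
little phase information anyway.

A sample is *phased* when its MAP pair's posterior reaches `min_posterior`
(default 0.90). This threshold is a package convention, exposed as a
parameter: the source survey reports that some individuals "could not be
phased" without stating its criterion, so no attempt is made to mimic an
unknown rule. Ties in the MAP pair are broken by canonical (lexicographic)
haplotype order. Samples with ≤ 1 heterozygous site are always phased with
posterior exactly 1.

## Population statistics

Frequencies are chromosome counts over 2N for allele/group/SNP units and
sample counts for genotype/phenotype units; pooling across strata sums
counts (equivalently, N-weighted frequency averaging). Counts are stored as
reals so that tables reconstructed from printed percentages × printed N
(which are not exactly integral) flow through the same aggregation code.

The HWE test is the exact conditional test: given the observed allele
counts, the two-sided p-value sums the probabilities of every heterozygote
count no more probable than the observed one,
P(het | n, n_rare) = n! 2^het n_rare! (2n−n_rare)! / (hom_c! het! hom_r! (2n)!),
computed in log space. Monomorphic sites return p = 1 by convention. Being
an exact test it is mildly conservative; at study-scale sample sizes
(n ≈ 950, intermediate allele frequencies) its attained size is close to
nominal, which the tests verify over 1000 HWE-true replicates.

Stratum comparisons use Pearson chi-square without continuity correction
(matching generic statistical-package defaults) on 2×k tables — one item
vs rest (k = 2), or a stated partition such as the three determinable
phenotypes (k = 3, df = 2). Expected cells below 1 trigger an advisory
warning recommending an exact alternative. Reported percentages round
half-even to one decimal; comparisons against externally printed
percentages should allow ±0.1 because independent rounding of the same
counts can disagree in the last digit (the printed tables themselves
contain such inconsistencies, e.g. 55/956 = 5.75% printed as 5.7%).

Multi-allelic HWE at the diplotype level is out of scope; HWE is assessed
per-SNP biallelically.

## Synthetic cohorts

`sample_cohort` draws two haplotypes i.i.d. from a stratum's frequency
distribution — HWE by construction — and emits a truth manifest plus the
exact unphased genotypes; `render_sequences` superimposes the two
chromosome sequences into an IUPAC consensus, after applying independent
per-base substitution noise at `error_rate` (bounded at 5%, far above any
plausible consensus error) to each chromosome. All randomness flows from a
single integer seed (sampling and rendering use distinct child streams);
sample IDs are `<stratum>_<index>` in spec order, so identical specs give
byte-identical outputs.

The shipped presets are the five published regional haplotype-frequency
rows (plus the nationwide row), with the unprinted remainder mass — the
rare alleles below the 1% reporting threshold, about 5–6% per region —
assigned to a catch-all `other` pseudo-allele of unknown function. For
sequence rendering, `other` is realised as a haplotype carrying the single
catalogued variant c.518A>G, which no named allele claims alone: it
re-calls as a novel haplotype of unknown function and an ND phenotype,
exactly as its truth record says. Recovery metrics are therefore keyed by
haplotype identity, not by name.

What the generator emulates: HWE diplotype sampling from realistic
frequencies, IUPAC consensus rendering, uniform base-call noise,
deterministic reproducibility. What it does not: chromatogram-level
artefacts and quality variation, indels, allele-specific dropout,
within-stratum admixture substructure, genotyping batch effects. Passing
the round-trip and recovery tests shows the pipeline's bookkeeping is
exact and its inference well-calibrated under the stated model — not that
real Sanger data are error-free.

## Problem sizes and fixed choices

Defaults used by the analysis drivers and tests: the simulated survey
cohort is 956 samples in five regions (the per-region genotyped sample
counts of the source study); parameter-recovery checks use n = 2000
(RMSE < 0.01) and n = 500 (±0.02); end-to-end recovery uses n = 300 per
cohort; exact-test calibration uses 1000 replicates at n = 956 and allele
frequency 0.36 (the most common nonsynonymous variant). Seeds are fixed
constants in each driver and test.

## Known limitations

- The bundled reference is a labelled synthetic stand-in (above); real-data
  use requires the GenBank coding sequence.
- Alleles defined only by their signature in the source material (\*11A,
  \*12C) are encoded with minimal/consensus compositions; extended
  compositions can be supplied via a user TSV.
- The EM phaser ignores recombination (irrelevant within one 873 bp exon)
  and assumes HWE within each stratum; strong unmodelled substructure
  within a stratum would bias posteriors.
- Printed-table cross-checks are value-level only where the publication
  prints the inputs; per-state significance matrices depend on
  per-state counts in an unavailable supplement and are covered by
  direction-of-effect simulations instead.
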
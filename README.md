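# nat2typer

Star-allele typing and acetylator-phenotype inference for the human *NAT2*
gene, with stratified population statistics and a synthetic-cohort
generator.

*NAT2* encodes arylamine N-acetyltransferase 2, the phase-II enzyme that
acetylates isoniazid, hydralazine, dapsone, sulphonamides and several other
drugs. Its entire 873 bp coding sequence sits in one intronless exon, and a
handful of common SNPs there combine into named haplotypes ("star alleles",
e.g. `NAT2*5B`) that are either functional ("rapid") or defective ("slow").
The individual phenotype is trimodal: carriers of two, one, or no defective
alleles are slow, intermediate, or rapid acetylators — a classification
that predicts drug toxicity and treatment failure, and whose population
distribution varies strongly with ancestry. This package implements the
complete sequence-to-phenotype pipeline used in population surveys of
admixed cohorts:

1. **Variant calling** (`nat2typer.calling`) — merge forward/reverse Sanger
   fragments, globally align a consensus to the NAT2*4 reference exon
   (affine gaps; IUPAC codes match compatible bases), and decode two-base
   ambiguity codes into heterozygous diploid calls at catalogued SNPs.
2. **Phasing** (`nat2typer.phasing`) — gene-counting EM
   (Excoffier–Slatkin) over the 2^(k−1) haplotype pairs compatible with k
   heterozygous sites: under HWE, P(h₁,h₂) = 2^[h₁≠h₂] f(h₁) f(h₂);
   each sample gets its maximum-posterior pair and counts as phased when
   that posterior ≥ 0.90.
3. **Typing** (`nat2typer.star_typing`) — exact SNP-set lookup against the
   nomenclature table; allelic groups (\*4, \*5, \*6, \*7, \*11, \*12,
   \*13, \*14, \*28) via signature SNPs; the two/one/zero-defective-allele
   phenotype rule, with ND when an allele's function is unknown.
4. **Population statistics** (`nat2typer.popstats`) — chromosome-counting
   frequency tables per stratum, weighted pooling, the exact conditional
   Hardy–Weinberg test, and Pearson chi-square contrasts between strata.
5. **Simulation** (`nat2typer.simulate`) — truth-annotated cohorts drawn
   under HWE from published regional haplotype frequencies, rendered as
   IUPAC consensus FASTA with a configurable base-error rate.

The bundled reference FASTA is a synthetic stand-in with the correct length
and the correct base at every catalogued SNP position (see
`docs/methods.md`); the bundled nomenclature and frequency tables encode the
published Brazilian regional survey data used throughout the tests.

## Worked example

```python
import nat2typer as nt

ref = nt.default_reference()
catalog = nt.default_snp_catalog(ref)
table = nt.default_allele_table(ref)

# a heterozygous consensus: Y at c.341 and c.481, R at c.803
seq = list(ref.sequence)
seq[340], seq[480], seq[802] = "Y", "Y", "R"
sample = nt.SampleSequence("patient_1", "".join(seq))

genotype = nt.call_genotype(sample, ref, catalog)
print("het sites:", genotype.het_positions)

# phase against population frequencies fitted on a reference cohort
spec = nt.preset_spec("Southeast", 300, seed=11)
_, cohort = nt.sample_cohort(spec, table, catalog)
freqs = nt.em_fit(cohort + [genotype], catalog)
diplotype = nt.phase_sample(genotype, freqs, catalog)
typed = nt.type_sample(diplotype, table)
print(f"{typed.allele1.name} / {typed.allele2.name} "
      f"(posterior {diplotype.posterior:.3f}) -> {typed.phenotype.phenotype}")
```

Output:

```
het sites: (341, 481, 803)
NAT2*4 / NAT2*5B (posterior 0.992) -> intermediate
```

The three heterozygous sites admit four haplotype pairs; given realistic
population frequencies the EM posterior concentrates on NAT2\*4 (no
variants, rapid) with NAT2\*5B (c.341T>C + c.481C>T + c.803A>G, slow), so
the sample is an intermediate acetylator with one defective allele.

## Analysis pipeline

`analysis/` contains numbered drivers that run the whole study workflow on
a simulated five-region cohort of 956 samples (regional sizes matching the
published survey) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py    # HWE diplotypes -> FASTA + truth
python analysis/02_call_genotypes.py     # consensus -> diploid calls
python analysis/03_phase_haplotypes.py   # per-region EM + MAP diplotypes
python analysis/04_assign_alleles.py     # star alleles + phenotypes
python analysis/05_population_stats.py   # frequencies, HWE, chi-square
```

On the default seed this recovers the generating allele frequencies, phases
~97% of samples, finds no HWE deviations (the cohort is HWE by
construction), and reproduces the published qualitative pattern: the South
differs from every other region in phenotype mix (p < 1e-6) while North and
Northeast are homogeneous.

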
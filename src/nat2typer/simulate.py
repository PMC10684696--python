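"""Truth-annotated synthetic NAT2 cohorts.

The generator draws, for each sample, two haplotypes i.i.d. from its
stratum's haplotype-frequency distribution — i.e. diplotypes under
Hardy-Weinberg equilibrium — and emits (a) a truth manifest, (b) the exact
unphased genotype table those diplotypes imply, and (c) optionally Sanger-
style consensus FASTA sequences in which heterozygous positions appear as
two-base IUPAC ambiguity codes, with a configurable per-base substitution
error rate.

The default frequency presets are the five Brazilian regional distributions
over the ten common star alleles (plus a catch-all ``other`` pseudo-allele
absorbing the unprinted remainder mass of rare alleles, a few percent per
region).  ``other`` is realised in sequence space as a haplotype carrying
the single catalogued variant c.518A>G, which no named allele claims alone:
it therefore re-calls as a novel haplotype of unknown function and an ND
phenotype, mirroring how a real rare allele would flow through the pipeline.

What this emulates: HWE diplotype sampling, IUPAC consensus rendering and
uniform base-call noise.  What it does not: chromatogram-level artefacts,
indels, linked-marker structure beyond the single exon, or within-stratum
admixture substructure.  Exactness guarantees from these cohorts therefore
speak to the pipeline's bookkeeping, not to wet-lab error modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calling import AMBIGUITY_CODE, SampleSequence, UnphasedGenotype, call_genotype
from .phasing import em_fit, phase_sample
from .popstats import load_regional_frequency_tables
from .reference import (
    AlleleTable,
    Haplotype,
    ReferenceExon,
    SnpCatalog,
    regional_frequency_path,
)
from .star_typing import phenotype_from_functions, type_sample

#: Catch-all pseudo-allele for the sub-threshold remainder mass.
OTHER_ALLELE = "other"
OTHER_HAPLOTYPE = Haplotype(((518, "G"),))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class StratumSpec:
    label: str
    n_samples: int
    frequencies: dict[str, float]  # allele name -> relative frequency

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise SimulationError(f"{self.label}: n_samples must be >= 1")
        if any(f < 0 for f in self.frequencies.values()):
            raise SimulationError(f"{self.label}: negative frequency")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(
                f"{self.label}: frequencies sum to {total}, expected 1"
            )


@dataclass(frozen=True)
class CohortSpec:
    strata: tuple[StratumSpec, ...]
    seed: int
    error_rate: float = 0.0
    iupac_render: bool = True

    def __post_init__(self) -> None:
        if not self.strata:
            raise SimulationError("at least one stratum required")
        if not 0.0 <= self.error_rate <= 0.05:
            raise SimulationError("error_rate must lie in [0, 0.05]")


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    stratum: str
    hap1: str  # allele names
    hap2: str
    phenotype: str


def regional_presets(path=None) -> dict[str, dict[str, float]]:
    """Haplotype-frequency presets for the five regions (plus the printed
    pooled row under key ``Total``), remainder mass under ``other``."""
    tables = load_regional_frequency_tables(path or regional_frequency_path())
    return {stratum: t.frequencies for stratum, t in tables.items()}


def preset_spec(
    region: str, n_samples: int, seed: int, error_rate: float = 0.0
) -> CohortSpec:
    presets = regional_presets()
    if region not in presets:
        raise SimulationError(f"unknown region preset {region!r}; have {sorted(presets)}")
    return CohortSpec(
        strata=(StratumSpec(region, n_samples, presets[region]),),
        seed=seed,
        error_rate=error_rate,
    )


def resolve_haplotype(name: str, table: AlleleTable) -> tuple[Haplotype, str]:
    """Map a truth allele name to (haplotype, function class)."""
    if name == OTHER_ALLELE:
        return OTHER_HAPLOTYPE, "unknown"
    entry = table.get(name)
    if entry is None:
        raise SimulationError(f"unknown allele name {name!r}")
    return entry.haplotype, entry.function


def sample_cohort(
    spec: CohortSpec, table: AlleleTable, catalog: SnpCatalog
) -> tuple[list[TruthRecord], list[UnphasedGenotype]]:
    """Draw diplotypes under HWE and derive the exact unphased genotypes.

    Fully reproducible from ``spec.seed``; sample IDs are
    ``<stratum>_<index>`` with strata processed in spec order.
    """
    rng = np.random.default_rng([spec.seed, 0])
    truth: list[TruthRecord] = []
    genotypes: list[UnphasedGenotype] = []
    for stratum in spec.strata:
        names = sorted(stratum.frequencies)
        probs = np.array([stratum.frequencies[n] for n in names])
        probs = probs / probs.sum()
        draws = rng.choice(len(names), size=(stratum.n_samples, 2), p=probs)
        for i, (a, b) in enumerate(draws):
            sample_id = f"{stratum.label}_{i}"
            name1, name2 = sorted((names[a], names[b]))
            hap1, fn1 = resolve_haplotype(name1, table)
            hap2, fn2 = resolve_haplotype(name2, table)
            phenotype = phenotype_from_functions(fn1, fn2).phenotype
            truth.append(TruthRecord(sample_id, stratum.label, name1, name2, phenotype))
            genotypes.append(
                _genotype_from_haplotypes(sample_id, stratum.label, hap1, hap2, catalog)
            )
    return truth, genotypes


def _genotype_from_haplotypes(
    sample_id: str,
    stratum: str,
    hap1: Haplotype,
    hap2: Haplotype,
    catalog: SnpCatalog,
) -> UnphasedGenotype:
    calls: dict[int, tuple[str, str]] = {}
    het = 0
    for snp in catalog:
        b1 = hap1.alt_at(snp.c_position) or snp.ref_base
        b2 = hap2.alt_at(snp.c_position) or snp.ref_base
        pair = tuple(sorted((b1, b2)))
        calls[snp.c_position] = pair  # type: ignore[assignment]
        het += b1 != b2
    return UnphasedGenotype(
        sample_id=sample_id, calls=calls, het_count=het,
        missing_sites=[], stratum=stratum,
    )


def haplotype_sequence(ref: ReferenceExon, hap: Haplotype) -> str:
    seq = list(ref.sequence)
    for pos, alt in hap.variants:
        seq[pos - 1] = alt
    return "".join(seq)


def render_sequences(
    truth: Sequence[TruthRecord],
    ref: ReferenceExon,
    spec: CohortSpec,
    table: AlleleTable,
) -> list[SampleSequence]:
    """Render each truth diplotype as an IUPAC consensus sequence.

    Per-base substitution noise at ``spec.error_rate`` is applied to each of
    the two chromosome sequences independently, before superposition;
    discordant positions become two-base ambiguity codes.
    """
    rng = np.random.default_rng([spec.seed, 1])
    bases = np.array(list("ACGT"))
    out = []
    for record in truth:
        chromo = []
        for name in (record.hap1, record.hap2):
            hap, _fn = resolve_haplotype(name, table)
            seq = np.array(list(haplotype_sequence(ref, hap)))
            if spec.error_rate > 0:
                hits = rng.random(len(seq)) < spec.error_rate
                for idx in np.nonzero(hits)[0]:
                    choices = [b for b in "ACGT" if b != seq[idx]]
                    seq[idx] = choices[rng.integers(3)]
            chromo.append(seq)
        consensus = [
            b1 if b1 == b2 else AMBIGUITY_CODE[frozenset((b1, b2))]
            for b1, b2 in zip(chromo[0], chromo[1])
        ]
        out.append(
            SampleSequence(record.sample_id, "".join(consensus), stratum=record.stratum)
        )
    return out


def write_fasta(sequences: Sequence[SampleSequence], path) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.sample_id} stratum={s.stratum}\n")
            for i in range(0, len(s.sequence), 60):
                fh.write(s.sequence[i:i + 60] + "\n")


def truth_to_df(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in truth])


@dataclass
class RecoveryReport:
    """End-to-end round-trip metrics of the full pipeline on one cohort."""

    n_samples: int
    n_phased: int
    allele_freq_rmse: float
    phase_accuracy: float  # among phased samples
    phenotype_accuracy: float  # among phased samples
    confusion: dict[tuple[str, str], int]  # (truth phenotype, called) -> count

    @property
    def fraction_unphased(self) -> float:
        return 1.0 - self.n_phased / self.n_samples if self.n_samples else 0.0


def end_to_end_recovery(
    spec: CohortSpec,
    ref: ReferenceExon,
    catalog: SnpCatalog,
    table: AlleleTable,
    min_posterior: float = 0.90,
) -> RecoveryReport:
    """Simulate, render, re-call, re-phase and re-type a cohort; compare to truth.

    EM haplotype frequencies are fitted per stratum.  The frequency RMSE is
    haplotype-keyed (truth empirical vs EM estimate), pooled over strata
    weighted by chromosome count; phase and phenotype accuracies are over
    phased samples only.
    """
    truth, _ = sample_cohort(spec, table, catalog)
    sequences = render_sequences(truth, ref, spec, table)
    genotypes = [call_genotype(s, ref, catalog) for s in sequences]

    truth_by_id = {t.sample_id: t for t in truth}
    by_stratum: dict[str, list[UnphasedGenotype]] = {}
    for g in genotypes:
        by_stratum.setdefault(g.stratum, []).append(g)

    n_phased = 0
    n_phase_correct = 0
    n_pheno_correct = 0
    confusion: dict[tuple[str, str], int] = {}
    sq_err_sum = 0.0
    n_terms = 0

    for stratum, members in by_stratum.items():
        complete = [g for g in members if not g.missing_sites]
        freqs = em_fit(complete, catalog)

        # Truth haplotype frequencies for this stratum.
        truth_counts: dict[Haplotype, int] = {}
        for g in members:
            t = truth_by_id[g.sample_id]
            for name in (t.hap1, t.hap2):
                hap, _fn = resolve_haplotype(name, table)
                truth_counts[hap] = truth_counts.get(hap, 0) + 1
        n_chrom = sum(truth_counts.values())
        for hap in set(truth_counts) | set(freqs.freqs):
            diff = truth_counts.get(hap, 0) / n_chrom - freqs.get(hap)
            sq_err_sum += n_chrom * diff * diff
            n_terms += n_chrom

        for g in members:
            diplotype = phase_sample(g, freqs, catalog, min_posterior=min_posterior)
            if not diplotype.phased:
                continue
            n_phased += 1
            t = truth_by_id[g.sample_id]
            true_pair = tuple(sorted(
                resolve_haplotype(n, table)[0] for n in (t.hap1, t.hap2)
            ))
            n_phase_correct += diplotype.pair == true_pair
            typed = type_sample(diplotype, table)
            called = typed.phenotype.phenotype
            n_pheno_correct += called == t.phenotype
            confusion[(t.phenotype, called)] = confusion.get((t.phenotype, called), 0) + 1

    return RecoveryReport(
        n_samples=len(truth),
        n_phased=n_phased,
        allele_freq_rmse=float(np.sqrt(sq_err_sum / n_terms)) if n_terms else 0.0,
        phase_accuracy=n_phase_correct / n_phased if n_phased else 0.0,
        phenotype_accuracy=n_pheno_correct / n_phased if n_phased else 0.0,
        confusion=confusion,
    )
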
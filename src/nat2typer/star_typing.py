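"""Star-allele assignment and acetylator-phenotype inference.

A phased haplotype is matched against the nomenclature table by its exact
SNP set; haplotypes absent from the table are reported as "novel" but still
receive an allelic group via their signature SNP, and are classed slow if
they carry one of the four slow-signature variants (a conservative rule —
any other novel haplotype has unknown function).

The acetylator phenotype is the classic trimodal rule: an individual is a
slow, intermediate or rapid acetylator according to whether they carry two,
one or no defective (slow) NAT2 alleles.  If either allele's function is
unknown, the phenotype is not determinable (ND).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .phasing import Diplotype
from .reference import (
    SLOW_SIGNATURES,
    AlleleTable,
    Haplotype,
)

PHENOTYPES = ("rapid", "intermediate", "slow", "ND")


@dataclass(frozen=True)
class AlleleCall:
    haplotype: Haplotype
    name: str  # star symbol or "novel"
    group: str
    function: str
    exact_match: bool


@dataclass(frozen=True)
class PhenotypeCall:
    sample_id: str
    phenotype: str  # rapid | intermediate | slow | ND
    defective_count: Optional[int]  # 0-2, or None when unknown


@dataclass(frozen=True)
class TypedSample:
    """One sample's complete typing record, ready for population statistics."""

    sample_id: str
    stratum: Optional[str]
    allele1: AlleleCall
    allele2: AlleleCall
    phenotype: PhenotypeCall
    posterior: float = 1.0
    phased: bool = True


def allelic_group(haplotype: Haplotype, table: Optional[AlleleTable] = None) -> str:
    """Allelic-group symbol from the first signature SNP present, in priority
    order; the empty haplotype is the reference group *4."""
    from .reference import SIGNATURE_PRIORITY

    priority = table.signature_priority if table is not None else SIGNATURE_PRIORITY
    variants = set(haplotype.variants)
    for signature, group in priority:
        if signature in variants:
            return group
    return "*4"


def assign_allele(haplotype: Haplotype, table: AlleleTable) -> AlleleCall:
    """Match a haplotype's exact SNP set to a named star allele."""
    entry = table.lookup(haplotype)
    if entry is not None:
        return AlleleCall(haplotype, entry.name, entry.group, entry.function, True)
    group = allelic_group(haplotype, table)
    has_slow_signature = bool(set(haplotype.variants) & SLOW_SIGNATURES)
    function = "slow" if has_slow_signature else "unknown"
    return AlleleCall(haplotype, "novel", group, function, False)


def phenotype_from_functions(
    function1: str, function2: str, sample_id: str = ""
) -> PhenotypeCall:
    """Trimodal phenotype from two allele function classes."""
    if "unknown" in (function1, function2):
        return PhenotypeCall(sample_id, "ND", None)
    defective = (function1 == "slow") + (function2 == "slow")
    phenotype = {0: "rapid", 1: "intermediate", 2: "slow"}[defective]
    return PhenotypeCall(sample_id, phenotype, defective)


def infer_phenotype(diplotype: Diplotype, table: AlleleTable) -> PhenotypeCall:
    """Acetylator phenotype of a phased sample (two/one/no defective alleles
    -> slow/intermediate/rapid; any unknown-function allele -> ND)."""
    call1 = assign_allele(diplotype.pair[0], table)
    call2 = assign_allele(diplotype.pair[1], table)
    return phenotype_from_functions(call1.function, call2.function, diplotype.sample_id)


def type_sample(diplotype: Diplotype, table: AlleleTable) -> TypedSample:
    call1 = assign_allele(diplotype.pair[0], table)
    call2 = assign_allele(diplotype.pair[1], table)
    # Canonical report order: table order by name, novel last.
    if (call2.name, str(call2.haplotype)) < (call1.name, str(call1.haplotype)):
        call1, call2 = call2, call1
    return TypedSample(
        sample_id=diplotype.sample_id,
        stratum=diplotype.stratum,
        allele1=call1,
        allele2=call2,
        phenotype=phenotype_from_functions(
            call1.function, call2.function, diplotype.sample_id
        ),
        posterior=diplotype.posterior,
        phased=diplotype.phased,
    )


def typed_samples_to_rows(samples) -> list[dict]:
    rows = []
    for s in samples:
        rows.append({
            "sample": s.sample_id, "stratum": s.stratum or "",
            "allele1": s.allele1.name, "allele2": s.allele2.name,
            "group1": s.allele1.group, "group2": s.allele2.group,
            "phenotype": s.phenotype.phenotype,
            "posterior": s.posterior, "phased": s.phased,
        })
    return rows
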
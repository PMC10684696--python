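"""Haplotype phasing by expectation-maximisation over a single locus.

Unphased diploid calls at k heterozygous sites are compatible with 2^(k-1)
unordered haplotype pairs.  Population haplotype frequencies are estimated
with the classic gene-counting EM (Excoffier & Slatkin): under
Hardy-Weinberg equilibrium the probability of an unordered pair (h1, h2) is
2^[h1 != h2] * f(h1) * f(h2); the E-step distributes each genotype over its
compatible pairs in proportion to that probability and the M-step re-counts
haplotypes.  The log-likelihood is non-decreasing in every iteration and the
fit is deterministic given the data — unlike an MCMC sampler there is no
chain to seed or monitor, which is adequate for one short locus with at most
a couple of dozen segregating sites.

Each sample is then assigned its maximum-posterior pair; a sample counts as
*phased* only if that posterior reaches ``min_posterior`` (default 0.90, a
package convention).  Samples with up to two missing catalogued calls are
handled by enumerating the possible fill-ins; beyond that the pair space
grows too fast and the sample is reported unphased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

from .calling import UnphasedGenotype
from .reference import Haplotype, SnpCatalog


class PhasingError(ValueError):
    pass


class CombinatorialExplosionError(PhasingError):
    """Too many heterozygous (or missing) sites to enumerate pairs."""


@dataclass
class HaplotypeFrequencies:
    """EM-estimated haplotype relative frequencies with its likelihood trace."""

    freqs: dict[Haplotype, float]
    loglik_trace: list[float]
    n_iterations: int
    converged: bool

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if any(f < 0 for f in self.freqs.values()) or abs(total - 1.0) > 1e-9:
            raise PhasingError(f"frequencies must be nonnegative and sum to 1 (sum={total})")
        for prev, cur in zip(self.loglik_trace, self.loglik_trace[1:]):
            if cur < prev - 1e-7:
                raise PhasingError("log-likelihood decreased during EM")

    def get(self, hap: Haplotype) -> float:
        return self.freqs.get(hap, 0.0)


@dataclass
class Diplotype:
    """MAP haplotype pair for one sample, with its posterior probability."""

    sample_id: str
    pair: tuple[Haplotype, Haplotype]  # canonically ordered
    posterior: float
    phased: bool
    stratum: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.posterior <= 1.0 + 1e-12:
            raise PhasingError(f"posterior {self.posterior} outside [0, 1]")
        if self.pair and self.pair[0] > self.pair[1]:
            self.pair = (self.pair[1], self.pair[0])


def _site_dosages(genotype: UnphasedGenotype, catalog: SnpCatalog) -> dict[int, int]:
    """Alt-allele dosage (0/1/2) at each called catalogued site."""
    dosages = {}
    for pos, (a, b) in genotype.calls.items():
        snp = catalog.get(pos)
        if snp is None:
            raise PhasingError(f"{genotype.sample_id}: uncatalogued call at c.{pos}")
        for base in (a, b):
            if base not in (snp.ref_base, snp.alt_base):
                raise PhasingError(
                    f"{genotype.sample_id}: base {base} at c.{pos} is neither ref nor alt"
                )
        dosages[pos] = (a != snp.ref_base) + (b != snp.ref_base)
    return dosages


def _pairs_from_dosages(
    dosages: dict[int, int], catalog: SnpCatalog, max_het: int
) -> list[tuple[Haplotype, Haplotype]]:
    shared = tuple(
        (pos, catalog.get(pos).alt_base) for pos, d in sorted(dosages.items()) if d == 2
    )
    het_sites = [pos for pos, d in sorted(dosages.items()) if d == 1]
    k = len(het_sites)
    if k > max_het:
        raise CombinatorialExplosionError(
            f"{k} heterozygous sites exceed the enumeration cap ({max_het})"
        )
    if k == 0:
        h = Haplotype(shared)
        return [(h, h)]
    pairs = []
    first, rest = het_sites[0], het_sites[1:]
    for assignment in product((0, 1), repeat=len(rest)):
        set1 = [first] + [p for p, side in zip(rest, assignment) if side == 0]
        set2 = [p for p, side in zip(rest, assignment) if side == 1]
        h1 = Haplotype(shared + tuple((p, catalog.get(p).alt_base) for p in set1))
        h2 = Haplotype(shared + tuple((p, catalog.get(p).alt_base) for p in set2))
        pairs.append((h1, h2) if h1 <= h2 else (h2, h1))
    return pairs


def enumerate_pairs(
    genotype: UnphasedGenotype, catalog: SnpCatalog, max_het: int = 12
) -> list[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs compatible with a complete genotype.

    Exactly 2^(k-1) pairs for k >= 1 heterozygous sites, one pair for k <= 1.
    Requires every catalogued site to be called.
    """
    if genotype.missing_sites:
        raise PhasingError(
            f"{genotype.sample_id}: missing calls at {genotype.missing_sites}"
        )
    return _pairs_from_dosages(_site_dosages(genotype, catalog), catalog, max_het)


def _pairs_allowing_missing(
    genotype: UnphasedGenotype,
    catalog: SnpCatalog,
    max_het: int = 12,
    max_missing: int = 2,
) -> Optional[list[tuple[Haplotype, Haplotype]]]:
    """Compatible pairs, marginalising <= max_missing missing sites over their
    three possible diploid fill-ins. Returns None if the sample is unphaseable."""
    missing = [p for p in genotype.missing_sites if p in catalog]
    if len(missing) > max_missing:
        return None
    base = _site_dosages(genotype, catalog)
    pairs: set[tuple[Haplotype, Haplotype]] = set()
    try:
        for fill in product((0, 1, 2), repeat=len(missing)):
            dosages = dict(base)
            dosages.update(dict(zip(missing, fill)))
            pairs.update(_pairs_from_dosages(dosages, catalog, max_het))
    except CombinatorialExplosionError:
        return None
    return sorted(pairs)


def em_fit(
    genotypes: Sequence[UnphasedGenotype],
    catalog: SnpCatalog,
    tol: float = 1e-8,
    max_iter: int = 500,
    max_het: int = 12,
    max_missing: int = 2,
) -> HaplotypeFrequencies:
    """Estimate haplotype frequencies from unphased genotypes by EM.

    Initialisation is uniform over every haplotype compatible with some
    sample.  Samples whose missing calls cannot be marginalised are skipped.
    Haplotypes whose fitted frequency falls below 1e-12 are pruned.
    """
    if not genotypes:
        raise PhasingError("no genotypes supplied")

    # Collapse identical pair-supports to weighted patterns.
    pattern_counts: dict[tuple, int] = {}
    pattern_pairs: dict[tuple, list[tuple[Haplotype, Haplotype]]] = {}
    for g in genotypes:
        pairs = _pairs_allowing_missing(g, catalog, max_het=max_het, max_missing=max_missing)
        if pairs is None:
            continue
        key = tuple(pairs)
        pattern_counts[key] = pattern_counts.get(key, 0) + 1
        pattern_pairs[key] = pairs
    if not pattern_counts:
        raise PhasingError("no phaseable genotypes supplied")

    haps = sorted({h for pairs in pattern_pairs.values() for pair in pairs for h in pair})
    freqs = {h: 1.0 / len(haps) for h in haps}
    n_chrom = 2 * sum(pattern_counts.values())

    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        counts = {h: 0.0 for h in haps}
        loglik = 0.0
        for key, n in pattern_counts.items():
            pairs = pattern_pairs[key]
            weights = []
            for h1, h2 in pairs:
                w = (2.0 if h1 != h2 else 1.0) * freqs.get(h1, 0.0) * freqs.get(h2, 0.0)
                weights.append(w)
            total = sum(weights)
            if not math.isfinite(total):
                raise PhasingError("non-finite likelihood in EM")
            if total <= 0.0:
                # All compatible haplotypes pruned; re-seed uniformly.
                weights = [1.0] * len(pairs)
                total = float(len(pairs))
            loglik += n * math.log(total) if total > 0 else float("-inf")
            for (h1, h2), w in zip(pairs, weights):
                share = n * w / total
                counts[h1] += share
                counts[h2] += share
        freqs = {h: c / n_chrom for h, c in counts.items()}
        trace.append(loglik)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    freqs = {h: f for h, f in freqs.items() if f >= 1e-12}
    total = sum(freqs.values())
    freqs = {h: f / total for h, f in freqs.items()}
    return HaplotypeFrequencies(
        freqs=freqs, loglik_trace=trace, n_iterations=n_iter, converged=converged
    )


def phase_sample(
    genotype: UnphasedGenotype,
    freqs: HaplotypeFrequencies,
    catalog: SnpCatalog,
    min_posterior: float = 0.90,
    max_het: int = 12,
    max_missing: int = 2,
) -> Diplotype:
    """Assign the maximum-posterior haplotype pair to one sample.

    Samples with a single compatible pair (k <= 1 het sites, nothing
    missing) get posterior exactly 1.  A genotype incompatible with every
    positive-frequency pair, or with too many missing sites, is returned
    unphased with posterior 0.
    """
    try:
        pairs = _pairs_allowing_missing(
            genotype, catalog, max_het=max_het, max_missing=max_missing
        )
    except PhasingError:
        pairs = None
    if not pairs:
        return Diplotype(genotype.sample_id, (Haplotype(), Haplotype()), 0.0, False,
                         stratum=genotype.stratum)
    if len(pairs) == 1:
        return Diplotype(genotype.sample_id, pairs[0], 1.0, True,
                         stratum=genotype.stratum)
    weights = [
        (2.0 if h1 != h2 else 1.0) * freqs.get(h1) * freqs.get(h2) for h1, h2 in pairs
    ]
    total = sum(weights)
    if total <= 0.0:
        return Diplotype(genotype.sample_id, pairs[0], 0.0, False,
                         stratum=genotype.stratum)
    # Ties broken by canonical (lexicographic) pair order: pairs is sorted.
    best_w = max(weights)
    best_idx = min(i for i, w in enumerate(weights) if w == best_w)
    posterior = best_w / total
    return Diplotype(
        genotype.sample_id, pairs[best_idx], min(posterior, 1.0),
        posterior >= min_posterior, stratum=genotype.stratum,
    )


def frequencies_to_rows(
    freqs: HaplotypeFrequencies, catalog: Optional[SnpCatalog] = None
) -> list[dict]:
    rows = []
    for hap, f in sorted(freqs.freqs.items(), key=lambda kv: -kv[1]):
        rows.append({
            "haplotype": ",".join(hap.tokens(catalog)) if hap.variants else "(ref)",
            "frequency": f,
        })
    return rows
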
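"""EM haplotype-frequency estimation and MAP diplotype assignment."""

import itertools
import math

import numpy as np
import pytest

from nat2typer.calling import UnphasedGenotype
from nat2typer.phasing import (
    CombinatorialExplosionError,
    Diplotype,
    HaplotypeFrequencies,
    PhasingError,
    em_fit,
    enumerate_pairs,
    phase_sample,
)
from nat2typer.reference import Haplotype, SnpCatalog, SnpDef
from nat2typer.simulate import preset_spec, sample_cohort


@pytest.fixture(scope="module")
def toy_catalog():
    return SnpCatalog([
        SnpDef(10, "A", "G"), SnpDef(20, "C", "T"), SnpDef(30, "G", "A"),
        SnpDef(40, "T", "C"), SnpDef(50, "A", "C"),
    ])


def _genotype(dosages, catalog, sid="s"):
    """Build an UnphasedGenotype from {position: alt dosage}."""
    calls = {}
    het = 0
    for pos, d in dosages.items():
        snp = catalog.get(pos)
        pair = {
            0: (snp.ref_base, snp.ref_base),
            1: tuple(sorted((snp.ref_base, snp.alt_base))),
            2: (snp.alt_base, snp.alt_base),
        }[d]
        calls[pos] = pair
        het += d == 1
    return UnphasedGenotype(sid, calls, het, [])


class TestEnumeratePairs:
    @pytest.mark.parametrize("k, expected", [(0, 1), (1, 1), (2, 2), (3, 4), (5, 16)])
    def test_pair_count_is_2_to_k_minus_1(self, toy_catalog, k, expected):
        positions = toy_catalog.positions[:k]
        dosages = {p: 1 for p in positions}
        pairs = enumerate_pairs(_genotype(dosages, toy_catalog), toy_catalog)
        assert len(pairs) == expected
        assert len(set(pairs)) == expected

    def test_pairs_are_genotype_compatible(self, toy_catalog):
        dosages = {10: 1, 20: 2, 30: 1, 40: 0}
        g = _genotype(dosages, toy_catalog)
        for h1, h2 in enumerate_pairs(g, toy_catalog):
            for pos, d in dosages.items():
                alt = toy_catalog.get(pos).alt_base
                assert (h1.alt_at(pos) == alt) + (h2.alt_at(pos) == alt) == d

    def test_homozygous_everywhere_single_identical_pair(self, toy_catalog):
        pairs = enumerate_pairs(_genotype({10: 2, 20: 0}, toy_catalog), toy_catalog)
        assert len(pairs) == 1
        assert pairs[0][0] == pairs[0][1] == Haplotype(((10, "G"),))

    def test_het_cap_raises(self, toy_catalog):
        g = _genotype({p: 1 for p in toy_catalog.positions}, toy_catalog)
        with pytest.raises(CombinatorialExplosionError):
            enumerate_pairs(g, toy_catalog, max_het=4)

    def test_missing_sites_rejected(self, toy_catalog):
        g = UnphasedGenotype("s", {10: ("A", "A")}, 0, [20])
        with pytest.raises(PhasingError, match="missing"):
            enumerate_pairs(g, toy_catalog)


class TestEmFit:
    def test_single_homozygous_haplotype(self, toy_catalog):
        genotypes = [_genotype({10: 2, 20: 2}, toy_catalog, f"s{i}") for i in range(5)]
        fit = em_fit(genotypes, toy_catalog)
        hap = Haplotype(((10, "G"), (20, "T")))
        assert fit.freqs == {hap: pytest.approx(1.0)}
        assert fit.converged

    def test_two_hom_groups_fifty_fifty(self, toy_catalog):
        genotypes = [_genotype({10: 2, 20: 2}, toy_catalog, f"a{i}") for i in range(50)]
        genotypes += [_genotype({10: 0, 20: 0}, toy_catalog, f"b{i}") for i in range(50)]
        fit = em_fit(genotypes, toy_catalog)
        AB = Haplotype(((10, "G"), (20, "T")))
        ab = Haplotype()
        assert fit.freqs[AB] == pytest.approx(0.5)
        assert fit.freqs[ab] == pytest.approx(0.5)

    def test_loglik_monotone_on_random_cohorts(self, toy_catalog):
        rng = np.random.default_rng(3)
        for rep in range(5):
            genotypes = [
                _genotype({p: int(rng.integers(3)) for p in toy_catalog.positions[:4]},
                          toy_catalog, f"s{rep}_{i}")
                for i in range(30)
            ]
            fit = em_fit(genotypes, toy_catalog)
            diffs = np.diff(fit.loglik_trace)
            assert (diffs >= -1e-9).all()

    def test_matches_direct_counting_when_at_most_one_het(self, toy_catalog):
        # unambiguous samples: EM must equal chromosome counting exactly
        rng = np.random.default_rng(8)
        genotypes = []
        counting = {}
        for i in range(60):
            hom = {p: 2 * int(rng.integers(2)) for p in (10, 20)}
            het_site = int(rng.choice([0, 10, 20]))
            dosages = dict(hom)
            if het_site:
                dosages[het_site] = 1
            g = _genotype(dosages, toy_catalog, f"s{i}")
            genotypes.append(g)
            (h1, h2), = enumerate_pairs(g, toy_catalog)  # unique pair when k <= 1
            counting[h1] = counting.get(h1, 0) + 1
            counting[h2] = counting.get(h2, 0) + 1
        fit = em_fit(genotypes, toy_catalog)
        total = sum(counting.values())
        for hap, count in counting.items():
            assert fit.get(hap) == pytest.approx(count / total, abs=1e-9)

    def test_requires_genotypes(self, toy_catalog):
        with pytest.raises(PhasingError):
            em_fit([], toy_catalog)


def _dense_em_oracle(genotype_dosage_vectors, n_sites, tol=1e-12, max_iter=2000):
    """Brute-force EM over the complete 2^k haplotype space.

    Haplotypes are bit masks; independent of the package's sparse
    enumeration path.
    """
    haps = list(range(2 ** n_sites))
    freqs = np.full(len(haps), 1.0 / len(haps))
    n_chrom = 2 * len(genotype_dosage_vectors)
    compatible = []
    for dosages in genotype_dosage_vectors:
        pairs = []
        for h1, h2 in itertools.combinations_with_replacement(haps, 2):
            ok = all(
                ((h1 >> s) & 1) + ((h2 >> s) & 1) == dosages[s] for s in range(n_sites)
            )
            if ok:
                pairs.append((h1, h2))
        compatible.append(pairs)
    prev = -math.inf
    for _ in range(max_iter):
        counts = np.zeros(len(haps))
        loglik = 0.0
        for pairs in compatible:
            w = np.array([
                (2.0 if h1 != h2 else 1.0) * freqs[h1] * freqs[h2] for h1, h2 in pairs
            ])
            total = w.sum()
            loglik += math.log(total)
            for (h1, h2), wi in zip(pairs, w):
                counts[h1] += wi / total
                counts[h2] += wi / total
        freqs = counts / n_chrom
        if abs(loglik - prev) < tol:
            break
        prev = loglik
    return freqs


def test_em_matches_dense_bruteforce_oracle(toy_catalog):
    """On <=4 sites / <=30 samples the sparse EM fixed point equals a dense EM
    over the complete 2^k haplotype space."""
    rng = np.random.default_rng(17)
    positions = toy_catalog.positions[:4]
    for rep in range(3):
        dosage_vectors = [
            tuple(int(rng.integers(3)) for _ in positions) for _ in range(25)
        ]
        genotypes = [
            _genotype(dict(zip(positions, d)), toy_catalog, f"s{i}")
            for i, d in enumerate(dosage_vectors)
        ]
        fit = em_fit(genotypes, toy_catalog, tol=1e-12, max_iter=2000)
        oracle = _dense_em_oracle(dosage_vectors, len(positions))
        for mask in range(2 ** len(positions)):
            hap = Haplotype(tuple(
                (p, toy_catalog.get(p).alt_base)
                for s, p in enumerate(positions) if (mask >> s) & 1
            ))
            assert fit.get(hap) == pytest.approx(oracle[mask], abs=2e-4)


class TestPhaseSample:
    @pytest.fixture()
    def two_site_setup(self, toy_catalog):
        AB = Haplotype(((10, "G"), (20, "T")))
        ab = Haplotype()
        Ab = Haplotype(((10, "G"),))
        aB = Haplotype(((20, "T"),))
        g = _genotype({10: 1, 20: 1}, toy_catalog, "dh")
        return g, (AB, ab, Ab, aB)

    def test_double_het_posterior_closed_form(self, toy_catalog, two_site_setup):
        g, (AB, ab, Ab, aB) = two_site_setup
        freqs = HaplotypeFrequencies({AB: 0.45, ab: 0.45, Ab: 0.05, aB: 0.05}, [], 1, True)
        d = phase_sample(g, freqs, toy_catalog)
        expected = (2 * 0.45 * 0.45) / (2 * 0.45 * 0.45 + 2 * 0.05 * 0.05)
        assert d.posterior == pytest.approx(expected)
        assert set(d.pair) == {AB, ab}
        assert d.phased

    def test_symmetric_frequencies_unphased(self, toy_catalog, two_site_setup):
        g, (AB, ab, Ab, aB) = two_site_setup
        freqs = HaplotypeFrequencies({AB: 0.25, ab: 0.25, Ab: 0.25, aB: 0.25}, [], 1, True)
        d = phase_sample(g, freqs, toy_catalog)
        assert d.posterior == pytest.approx(0.5)
        assert not d.phased

    def test_single_het_posterior_exactly_one(self, toy_catalog):
        g = _genotype({10: 1, 20: 0}, toy_catalog)
        freqs = HaplotypeFrequencies({Haplotype(): 1.0}, [], 1, True)
        d = phase_sample(g, freqs, toy_catalog)
        assert d.posterior == 1.0
        assert d.phased

    def test_incompatible_with_all_frequencies_unphased(self, toy_catalog, two_site_setup):
        g, (AB, ab, Ab, aB) = two_site_setup
        freqs = HaplotypeFrequencies({Haplotype(((30, "A"),)): 1.0}, [], 1, True)
        d = phase_sample(g, freqs, toy_catalog)
        assert d.posterior == 0.0
        assert not d.phased

    def test_two_missing_sites_marginalised(self, toy_catalog):
        g = UnphasedGenotype("m", {10: ("A", "G")}, 1, [20, 30])
        freqs = HaplotypeFrequencies(
            {Haplotype(): 0.9, Haplotype(((10, "G"),)): 0.1}, [], 1, True
        )
        d = phase_sample(g, freqs, toy_catalog)
        assert d.phased
        assert set(d.pair) == {Haplotype(), Haplotype(((10, "G"),))}

    def test_three_missing_sites_unphased(self, toy_catalog):
        g = UnphasedGenotype("m", {10: ("A", "G")}, 1, [20, 30, 40])
        freqs = HaplotypeFrequencies({Haplotype(): 1.0}, [], 1, True)
        d = phase_sample(g, freqs, toy_catalog)
        assert not d.phased and d.posterior == 0.0


class TestParameterRecovery:
    def test_recovery_rmse_below_001_at_n2000(self, allele_table, catalog):
        """Diplotypes drawn under HWE from the pooled printed frequencies are
        refit by EM to within RMSE 0.01."""
        spec = preset_spec("Total", 2000, seed=42)
        truth_freqs = spec.strata[0].frequencies
        _, genotypes = sample_cohort(spec, allele_table, catalog)
        fit = em_fit(genotypes, catalog)
        from nat2typer.simulate import resolve_haplotype

        sq = 0.0
        haps = {name: resolve_haplotype(name, allele_table)[0] for name in truth_freqs}
        for name, hap in haps.items():
            sq += (truth_freqs[name] - fit.get(hap)) ** 2
        rmse = math.sqrt(sq / len(haps))
        assert rmse < 0.01

    def test_regional_preset_recovery_within_002(self, allele_table, catalog):
        spec = preset_spec("South", 500, seed=7)
        truth_freqs = spec.strata[0].frequencies
        _, genotypes = sample_cohort(spec, allele_table, catalog)
        fit = em_fit(genotypes, catalog)
        from nat2typer.simulate import resolve_haplotype

        for name, f in truth_freqs.items():
            hap = resolve_haplotype(name, allele_table)[0]
            assert abs(fit.get(hap) - f) < 0.02

    def test_unphased_fraction_small_at_study_scale(self, allele_table, catalog):
        """On a printed-frequency cohort of study size, nearly all samples
        reach the phasing-confidence threshold (the study lost 8 of 964)."""
        spec = preset_spec("Total", 956, seed=13)
        _, genotypes = sample_cohort(spec, allele_table, catalog)
        fit = em_fit(genotypes, catalog)
        unphased = sum(
            not phase_sample(g, fit, catalog).phased for g in genotypes
        )
        assert unphased / len(genotypes) < 0.05
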
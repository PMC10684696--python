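"""Stratified population statistics over typed NAT2 samples.

Frequencies are obtained by chromosome counting (allele copies over 2N
chromosomes for allele-level units; samples for genotype/phenotype units),
per stratum and pooled across strata by weighted aggregation.  Site-level
Hardy-Weinberg equilibrium is assessed with the exact conditional test
(two-sided: the p-value sums the probabilities of all heterozygote counts no
more probable than the observed one, given the allele counts).  Pairwise
stratum comparisons use the Pearson chi-square statistic on 2 x k
contingency tables without continuity correction.

Reported percentages follow the convention of one decimal place with
round-half-even; comparisons against externally printed percentages should
allow +/-0.1 because independent rounding of the same counts can differ in
the last digit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .calling import UnphasedGenotype
from .reference import AlleleTable, SnpCatalog
from .star_typing import TypedSample, phenotype_from_functions

UNITS = ("snp", "allele", "group", "genotype", "phenotype")


class PopStatsError(ValueError):
    pass


@dataclass
class FrequencyTable:
    """Item counts and frequencies for one stratum at one unit level.

    ``n_total`` counts chromosomes for snp/allele/group units and samples
    for genotype/phenotype units.  Counts are usually integers; tables
    reconstructed from printed percentages may carry fractional counts.
    """

    stratum: str
    unit: str
    counts: dict[str, float]
    n_total: float

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise PopStatsError(f"unknown unit {self.unit!r}")
        if any(c < 0 for c in self.counts.values()):
            raise PopStatsError("negative count")
        total = sum(self.counts.values())
        if abs(total - self.n_total) > 1e-6 * max(1.0, self.n_total):
            raise PopStatsError(
                f"{self.stratum}/{self.unit}: counts sum to {total}, n_total {self.n_total}"
            )

    @classmethod
    def from_percentages(
        cls, stratum: str, unit: str, percents: Mapping[str, float], n_total: float,
        fill_item: str = "other",
    ) -> "FrequencyTable":
        """Reconstruct a table from printed percentages and a printed N; any
        remainder mass (rows below a reporting threshold) goes to ``fill_item``."""
        counts = {item: pct / 100.0 * n_total for item, pct in percents.items()}
        remainder = n_total - sum(counts.values())
        if remainder > 1e-9 * n_total:
            counts[fill_item] = counts.get(fill_item, 0.0) + remainder
        return cls(stratum=stratum, unit=unit, counts=counts, n_total=n_total)

    def frequency(self, item: str) -> float:
        return self.counts.get(item, 0.0) / self.n_total

    @property
    def frequencies(self) -> dict[str, float]:
        return {item: c / self.n_total for item, c in self.counts.items()}

    def percent(self, item: str) -> float:
        return round_pct(100.0 * self.frequency(item))


def round_pct(value: float, decimals: int = 1) -> float:
    """Round-half-even to one decimal, the reporting convention for percents."""
    return float(np.round(value, decimals))


@dataclass(frozen=True)
class ComparisonResult:
    strata: tuple[str, str]
    items: tuple[str, ...]
    chi2: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.chi2 < -1e-12 or not (0.0 < self.p <= 1.0):
            raise PopStatsError(f"invalid comparison result chi2={self.chi2}, p={self.p}")


def count_frequencies(
    samples: Sequence[TypedSample],
    units: Iterable[str] = ("allele", "group", "genotype", "phenotype"),
) -> dict[str, dict[str, FrequencyTable]]:
    """Per-stratum frequency tables at each requested unit level.

    Allele and group tables count two chromosomes per sample; genotype and
    phenotype tables count samples.  Returns ``{unit: {stratum: table}}``.
    Empty strata cannot arise (a stratum exists only via its samples).
    """
    units = tuple(units)
    for u in units:
        if u not in UNITS or u == "snp":
            if u == "snp":
                raise PopStatsError("snp unit requires genotypes; use snp_frequency_tables")
            raise PopStatsError(f"unknown unit {u!r}")
    by_stratum: dict[str, list[TypedSample]] = {}
    for s in samples:
        by_stratum.setdefault(s.stratum or "all", []).append(s)

    out: dict[str, dict[str, FrequencyTable]] = {u: {} for u in units}
    for stratum, members in by_stratum.items():
        for unit in units:
            counts: dict[str, float] = {}
            if unit in ("allele", "group"):
                for s in members:
                    for call in (s.allele1, s.allele2):
                        key = call.name if unit == "allele" else call.group
                        if unit == "allele" and call.name == "novel":
                            key = f"novel:{call.haplotype}"
                        counts[key] = counts.get(key, 0) + 1
                n_total = 2 * len(members)
            elif unit == "genotype":
                for s in members:
                    key = f"{s.allele1.name}/{s.allele2.name}"
                    counts[key] = counts.get(key, 0) + 1
                n_total = len(members)
            else:  # phenotype
                for s in members:
                    counts[s.phenotype.phenotype] = counts.get(s.phenotype.phenotype, 0) + 1
                n_total = len(members)
            out[unit][stratum] = FrequencyTable(stratum, unit, counts, n_total)
    return out


def snp_frequency_tables(
    genotypes: Sequence[UnphasedGenotype], catalog: SnpCatalog
) -> dict[str, dict[int, FrequencyTable]]:
    """Per-stratum, per-site ref/alt chromosome counts (missing sites skipped)."""
    by_stratum: dict[str, list[UnphasedGenotype]] = {}
    for g in genotypes:
        by_stratum.setdefault(g.stratum or "all", []).append(g)
    out: dict[str, dict[int, FrequencyTable]] = {}
    for stratum, members in by_stratum.items():
        out[stratum] = {}
        for snp in catalog:
            counts = {snp.ref_base: 0.0, snp.alt_base: 0.0}
            n = 0
            for g in members:
                pair = g.calls.get(snp.c_position)
                if pair is None:
                    continue
                for base in pair:
                    counts[base] += 1
                    n += 1
            if n:
                out[stratum][snp.c_position] = FrequencyTable(
                    stratum, "snp", counts, n
                )
    return out


def site_genotype_counts(
    genotypes: Sequence[UnphasedGenotype], c_position: int, catalog: SnpCatalog
) -> tuple[int, int, int]:
    """(hom-ref, het, hom-alt) sample counts at one catalogued site."""
    snp = catalog.get(c_position)
    if snp is None:
        raise PopStatsError(f"c.{c_position} not in catalogue")
    counts = [0, 0, 0]
    for g in genotypes:
        pair = g.calls.get(c_position)
        if pair is None:
            continue
        dosage = (pair[0] != snp.ref_base) + (pair[1] != snp.ref_base)
        counts[dosage] += 1
    return tuple(counts)  # type: ignore[return-value]


def aggregate_weighted(tables: Sequence[FrequencyTable], stratum: str = "pooled") -> FrequencyTable:
    """Pool strata: summed counts, frequency = pooled count / pooled N."""
    if not tables:
        raise PopStatsError("no tables to aggregate")
    units = {t.unit for t in tables}
    if len(units) != 1:
        raise PopStatsError(f"cannot aggregate mixed units {sorted(units)}")
    counts: dict[str, float] = {}
    n_total = 0.0
    for t in tables:
        n_total += t.n_total
        for item, c in t.counts.items():
            counts[item] = counts.get(item, 0.0) + c
    return FrequencyTable(stratum, tables[0].unit, counts, n_total)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test for one biallelic site.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed count.  A monomorphic site returns p = 1 by convention.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0 or c != int(c):
            raise PopStatsError("genotype counts must be nonnegative integers")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise PopStatsError("need at least one sample")
    n_a = 2 * n_hom_alt + n_het  # minor-allele copies (either allele works)
    n_A = 2 * n_hom_ref + n_het
    if n_a == 0 or n_A == 0:
        return 1.0
    rare = min(n_a, n_A)

    def log_prob(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        # P(het | allele counts) = n! 2^het / (hom_c! het! hom_r!) * rare! common! / (2n)!
        return (
            gammaln(n + 1)
            - gammaln(hom_common + 1) - gammaln(het + 1) - gammaln(hom_rare + 1)
            + het * np.log(2.0)
            + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1)
        )

    hets = np.arange(rare % 2, rare + 1, 2)
    logps = np.array([log_prob(int(h)) for h in hets])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    obs_prob = probs[list(hets).index(n_het)]
    p = float(probs[probs <= obs_prob * (1 + 1e-12)].sum())
    return min(p, 1.0)


def chi2_compare(
    table_a: FrequencyTable,
    table_b: FrequencyTable,
    item: Optional[str | Sequence[str]] = None,
) -> ComparisonResult:
    """Pearson chi-square (no continuity correction) comparing two strata.

    ``item``: a single item gives an item-vs-rest 2x2 test; a sequence gives
    a 2xk test over that partition; None uses the union of all items.
    """
    if table_a.unit != table_b.unit:
        raise PopStatsError("cannot compare tables with different units")
    if table_a.n_total <= 0 or table_b.n_total <= 0:
        raise PopStatsError("zero-margin table")

    if item is None:
        items: tuple[str, ...] = tuple(sorted(set(table_a.counts) | set(table_b.counts)))
        cols = [
            [table_a.counts.get(i, 0.0), table_b.counts.get(i, 0.0)] for i in items
        ]
    elif isinstance(item, str):
        items = (item, "rest")
        a_item = table_a.counts.get(item, 0.0)
        b_item = table_b.counts.get(item, 0.0)
        cols = [[a_item, b_item],
                [table_a.n_total - a_item, table_b.n_total - b_item]]
    else:
        items = tuple(item)
        cols = [
            [table_a.counts.get(i, 0.0), table_b.counts.get(i, 0.0)] for i in items
        ]
    observed = np.array(cols, dtype=float).T  # 2 x k
    observed = observed[:, observed.sum(axis=0) > 0]
    if observed.shape[1] < 2:
        raise PopStatsError("need at least two non-empty categories")
    if observed.sum(axis=1).min() <= 0:
        raise PopStatsError("zero-margin table")
    expected = stats.contingency.expected_freq(observed)
    if expected.min() < 1.0:
        warnings.warn(
            "expected cell count below 1; consider an exact test", stacklevel=2
        )
    chi2, p, df, _ = stats.chi2_contingency(observed, correction=False)
    return ComparisonResult(
        strata=(table_a.stratum, table_b.stratum),
        items=items, chi2=float(chi2), df=int(df), p=float(p),
    )


def parse_genotype_label(label: str) -> tuple[str, str]:
    """Split a printed genotype label like ``NAT2*5B/*6A`` into allele names."""
    left, _, right = label.partition("/")
    left = left.strip()
    right = right.strip()
    if not right:
        raise PopStatsError(f"cannot parse genotype label {label!r}")
    if right.startswith("*"):
        right = "NAT2" + right
    if left.startswith("*"):
        left = "NAT2" + left
    return left, right


def classify_genotype_rows(
    rows: pd.DataFrame,
    table: AlleleTable,
    label_col: str = "genotype",
    freq_col: str = "brazil_percent",
) -> pd.DataFrame:
    """Classify printed genotype rows into acetylator phenotypes.

    Each label is parsed into a star-allele pair and classified by the
    two/one/zero-defective-allele rule using the nomenclature table's
    function classes; rows naming an allele absent from the table are routed
    to ND.  Returns the input with ``phenotype`` appended.
    """
    phenotypes = []
    for label in rows[label_col]:
        try:
            name1, name2 = parse_genotype_label(str(label))
        except PopStatsError:
            phenotypes.append("ND")
            continue
        e1, e2 = table.get(name1), table.get(name2)
        if e1 is None or e2 is None:
            phenotypes.append("ND")
            continue
        phenotypes.append(phenotype_from_functions(e1.function, e2.function).phenotype)
    out = rows.copy()
    out["phenotype"] = phenotypes
    return out


def phenotype_frequency_sums(
    rows: pd.DataFrame,
    table: AlleleTable,
    label_col: str = "genotype",
    freq_col: str = "brazil_percent",
) -> dict[str, float]:
    """Per-phenotype sums of printed genotype frequencies (percent scale)."""
    classified = classify_genotype_rows(rows, table, label_col, freq_col)
    sums = classified.groupby("phenotype")[freq_col].sum().to_dict()
    return {ph: float(sums.get(ph, 0.0)) for ph in ("rapid", "intermediate", "slow", "ND")}


def load_printed_genotype_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_regional_frequency_tables(path: str | Path) -> dict[str, FrequencyTable]:
    """Regional allele-frequency tables reconstructed from printed percents.

    Returns one table per stratum, including any printed pooled row.  The
    unprinted remainder mass (alleles below the reporting threshold) is
    assigned to the catch-all item ``other``.
    """
    df = pd.read_csv(path, sep="\t")
    out: dict[str, FrequencyTable] = {}
    for stratum, sub in df.groupby("stratum", sort=False):
        n = float(sub["n_chromosomes"].iloc[0])
        percents = dict(zip(sub["allele"], sub["percent"].astype(float)))
        out[stratum] = FrequencyTable.from_percentages(stratum, "allele", percents, n)
    return out
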
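#!/usr/bin/env python
"""Stratified population statistics and printed-table cross-checks.

From the typed cohort: per-region allele/group/phenotype frequency tables,
per-site Hardy-Weinberg exact tests, and pairwise regional chi-square
comparisons of the phenotype distribution.  Independently of the simulated
cohort, recomputes the summary figures implied by the printed population
tables (phenotype partition of the 21 common genotypes; nationwide
composite allele figures; weighted regional aggregation).  Writes
results/frequencies_*.tsv, results/hwe.tsv, results/comparisons.tsv and
results/summary.md.
"""

from itertools import combinations
from pathlib import Path

import pandas as pd

from nat2typer.calling import table_to_genotypes
from nat2typer.phasing import Diplotype
from nat2typer.popstats import (
    aggregate_weighted,
    chi2_compare,
    count_frequencies,
    hwe_exact_test,
    load_printed_genotype_table,
    load_regional_frequency_tables,
    phenotype_frequency_sums,
    round_pct,
    site_genotype_counts,
)
from nat2typer.reference import (
    Haplotype,
    common_genotype_table_path,
    default_allele_table,
    default_reference,
    default_snp_catalog,
    regional_frequency_path,
)
from nat2typer.star_typing import type_sample

RESULTS = Path(__file__).resolve().parents[1] / "results"
COMMON_SITES = (191, 282, 341, 481, 590, 803, 857)


def main() -> None:
    reference = default_reference()
    catalog = default_snp_catalog(reference)
    table = default_allele_table(reference)

    typing = pd.read_csv(RESULTS / "typing.tsv", sep="\t")
    diplotypes = pd.read_csv(RESULTS / "diplotypes.tsv", sep="\t")
    phased_ids = set(typing[typing["phased"]]["sample"])
    hap_by_sample = {
        row["sample"]: (row["hap1"], row["hap2"])
        for _, row in diplotypes.iterrows()
    }

    def parse_hap(text):
        return Haplotype() if text == "(ref)" else Haplotype.from_tokens(text.split(","))

    typed = []
    for _, row in diplotypes[diplotypes["sample"].isin(phased_ids)].iterrows():
        pair = tuple(sorted((parse_hap(row["hap1"]), parse_hap(row["hap2"]))))
        d = Diplotype(row["sample"], pair, float(row["posterior"]), True,
                      stratum=row["stratum"])
        typed.append(type_sample(d, table))

    # --- frequency tables ---------------------------------------------------
    tables = count_frequencies(typed)
    for unit in ("allele", "group", "genotype", "phenotype"):
        rows = []
        strata = tables[unit]
        pooled = aggregate_weighted(list(strata.values()), stratum="Brazil")
        for stratum, t in {**strata, "Brazil": pooled}.items():
            for item, count in sorted(t.counts.items(), key=lambda kv: -kv[1]):
                rows.append({
                    "stratum": stratum, unit: item, "count": count,
                    "percent": round_pct(100 * count / t.n_total),
                    "n_total": t.n_total,
                })
        pd.DataFrame(rows).to_csv(RESULTS / f"frequencies_{unit}.tsv",
                                  sep="\t", index=False)

    # --- Hardy-Weinberg per common site ------------------------------------
    genotypes = table_to_genotypes(pd.read_csv(RESULTS / "genotypes.tsv", sep="\t"),
                                   catalog)
    hwe_rows = []
    for pos in COMMON_SITES:
        counts = site_genotype_counts(genotypes, pos, catalog)
        hwe_rows.append({
            "c_position": pos, "hom_ref": counts[0], "het": counts[1],
            "hom_alt": counts[2], "p": hwe_exact_test(*counts),
        })
    hwe = pd.DataFrame(hwe_rows)
    hwe.to_csv(RESULTS / "hwe.tsv", sep="\t", index=False)
    n_dev = int((hwe["p"] < 0.05).sum())
    print(f"HWE exact tests at {len(COMMON_SITES)} common sites: "
          f"{n_dev} nominal deviations at alpha = 0.05")

    # --- pairwise regional phenotype comparisons ---------------------------
    comp_rows = []
    pheno = tables["phenotype"]
    for a, b in combinations(sorted(pheno), 2):
        res = chi2_compare(pheno[a], pheno[b], item=("rapid", "intermediate", "slow"))
        comp_rows.append({
            "stratum_a": a, "stratum_b": b, "chi2": round(res.chi2, 3),
            "df": res.df, "p": res.p,
        })
    comparisons = pd.DataFrame(comp_rows)
    comparisons.to_csv(RESULTS / "comparisons.tsv", sep="\t", index=False)

    # --- printed-table cross-checks ----------------------------------------
    printed = load_printed_genotype_table(common_genotype_table_path())
    sums = phenotype_frequency_sums(printed, table)
    regional = load_regional_frequency_tables(regional_frequency_path())
    pooled_printed = aggregate_weighted(
        [regional[r] for r in ("North", "Northeast", "Midwest", "Southeast", "South")]
    )
    total = regional["Total"]
    two_major = 100 * (total.frequency("NAT2*5B") + total.frequency("NAT2*6A"))
    defective = [e.name for e in table
                 if e.function == "slow" and total.frequency(e.name) > 0]
    six_defective = 100 * sum(total.frequency(n) for n in defective)

    lines = [
        "# Cohort summary",
        "",
        f"Phased samples: {len(typed)} / {len(diplotypes)}",
        "",
        "## Phenotype distribution by region (percent of phased samples)",
        "",
    ]
    for stratum, t in pheno.items():
        mix = ", ".join(
            f"{ph} {round_pct(100 * t.counts.get(ph, 0) / t.n_total)}%"
            for ph in ("rapid", "intermediate", "slow", "ND")
        )
        lines.append(f"- {stratum} (n={int(t.n_total)}): {mix}")
    lines += [
        "",
        "## Pairwise regional phenotype contrasts (Pearson chi-square, df=2)",
        "",
        comparisons.to_string(index=False),
        "",
        "## Printed-table cross-checks",
        "",
        f"- 21-genotype phenotype partition: rapid {round_pct(sums['rapid'])}%, "
        f"slow {round_pct(sums['slow'])}%, intermediate {round_pct(sums['intermediate'])}%",
        f"- *5B + *6A nationwide: {round_pct(two_major)}%",
        f"- six defective alleles nationwide: {round_pct(six_defective)}%",
        f"- weighted regional aggregation: *4 {round_pct(100 * pooled_printed.frequency('NAT2*4'))}%, "
        f"*5B {round_pct(100 * pooled_printed.frequency('NAT2*5B'))}%, "
        f"*6A {round_pct(100 * pooled_printed.frequency('NAT2*6A'))}%",
        "",
    ]
    (RESULTS / "summary.md").write_text("\n".join(lines))
    print("\n".join(lines[-9:]))


if __name__ == "__main__":
    main()
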
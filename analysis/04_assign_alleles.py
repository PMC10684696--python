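#!/usr/bin/env python
"""Assign star alleles, allelic groups and acetylator phenotypes.

Maps each phased haplotype to its star allele (exact SNP-set match against
the nomenclature table; unmatched haplotypes are reported as novel with a
signature-derived group), applies the two/one/zero-defective-allele
phenotype rule, and writes results/typing.tsv.
"""

from pathlib import Path

import pandas as pd

from nat2typer.phasing import Diplotype
from nat2typer.reference import Haplotype, default_allele_table, default_reference
from nat2typer.star_typing import type_sample, typed_samples_to_rows

RESULTS = Path(__file__).resolve().parents[1] / "results"


def _parse_hap(text: str) -> Haplotype:
    if text == "(ref)":
        return Haplotype()
    return Haplotype.from_tokens(text.split(","))


def main() -> None:
    table = default_allele_table(default_reference())
    diplotypes = pd.read_csv(RESULTS / "diplotypes.tsv", sep="\t")

    typed = []
    for _, row in diplotypes.iterrows():
        pair = tuple(sorted((_parse_hap(row["hap1"]), _parse_hap(row["hap2"]))))
        d = Diplotype(row["sample"], pair, float(row["posterior"]),
                      bool(row["phased"]), stratum=row["stratum"])
        typed.append(type_sample(d, table))

    df = pd.DataFrame(typed_samples_to_rows(typed))
    df.to_csv(RESULTS / "typing.tsv", sep="\t", index=False)

    phased = df[df["phased"]]
    print(f"typed {len(df)} samples ({len(phased)} phased)")
    print("phenotype counts among phased samples:")
    print(phased["phenotype"].value_counts().to_string())
    novel = phased[(phased["allele1"] == "novel") | (phased["allele2"] == "novel")]
    print(f"samples carrying a haplotype outside the nomenclature table: {len(novel)}")


if __name__ == "__main__":
    main()
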
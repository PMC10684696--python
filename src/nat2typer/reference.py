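"""Reference model for the NAT2 coding exon.

The NAT2 gene carries its entire 873 bp protein-coding sequence in a single
intronless exon, and every variant of pharmacogenetic interest is described
in HGVS c.-notation over that exon (c.1 = the A of the initiator ATG).  This
module holds the three pieces of bookkeeping everything else builds on:

* :class:`ReferenceExon` — the coding sequence of the reference (rapid)
  allele NAT2*4, with 1-based c.-coordinate access;
* :class:`SnpDef` and the SNP catalogue — the known coding-exon substitutions
  (position, ref/alt base, rsID, synonymy);
* :class:`AlleleDef` / :class:`AlleleTable` — the star-allele nomenclature:
  each named allele is an exact set of SNPs carried on one chromosome, with a
  function class (rapid / slow / unknown) and an allelic-group symbol
  assigned by its signature SNP.

The bundled reference FASTA is a synthetic stand-in sequence: it has the
correct length (873 bp), starts with ATG, and carries the correct reference
base at every catalogued SNP position, but the remaining filler bases are
generated, not the GenBank AY331807 sequence.  No downstream computation
depends on the filler bases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

EXON_LENGTH = 873

#: Signature SNPs in priority order: the first one present on a haplotype
#: assigns its allelic group.  Slow signatures (191, 341, 590, 857) outrank
#: rapid ones; within the rapid block 803 outranks 481 because alleles
#: carrying both (e.g. *5B relatives stripped of 341, the *12 alleles *12C
#: and *12S) belong to the *12 group.  c.622T>C defines the *28 group.
SIGNATURE_PRIORITY: tuple[tuple[tuple[int, str], str], ...] = (
    ((191, "A"), "*14"),
    ((341, "C"), "*5"),
    ((590, "A"), "*6"),
    ((857, "A"), "*7"),
    ((803, "G"), "*12"),
    ((481, "T"), "*11"),
    ((282, "T"), "*13"),
    ((622, "C"), "*28"),
)

#: Slow-acetylation signature variants (nonsynonymous, activity-reducing).
SLOW_SIGNATURES: frozenset[tuple[int, str]] = frozenset(
    {(191, "A"), (341, "C"), (590, "A"), (857, "A")}
)

_SNP_TOKEN_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")


class ReferenceError(ValueError):
    """Raised when a reference sequence or definition table fails validation."""


def parse_snp_token(token: str) -> tuple[int, str, str]:
    """Parse an HGVS-like token such as ``c.341T>C`` into (position, ref, alt)."""
    m = _SNP_TOKEN_RE.match(token.strip())
    if not m:
        raise ReferenceError(f"malformed SNP token: {token!r}")
    pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
    if ref == alt:
        raise ReferenceError(f"SNP token {token!r} has identical ref and alt")
    return pos, ref, alt


@dataclass(frozen=True)
class ReferenceExon:
    """The 873 bp NAT2 coding sequence on the coding strand."""

    sequence: str
    source_id: str = "AY331807"

    def __post_init__(self) -> None:
        if len(self.sequence) != EXON_LENGTH:
            raise ReferenceError(
                f"reference exon must be {EXON_LENGTH} bp, got {len(self.sequence)}"
            )
        if not self.sequence.startswith("ATG"):
            raise ReferenceError("reference exon must start with ATG")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ReferenceError(f"reference contains non-ACGT characters: {sorted(bad)}")

    def base_at(self, c_position: int) -> str:
        """Reference base at a 1-based c.-coordinate."""
        if not 1 <= c_position <= EXON_LENGTH:
            raise ReferenceError(f"c.{c_position} outside [1, {EXON_LENGTH}]")
        return self.sequence[c_position - 1]


@dataclass(frozen=True)
class SnpDef:
    """A catalogued coding-exon substitution in c.-coordinates."""

    c_position: int
    ref_base: str
    alt_base: str
    rsid: Optional[str] = None
    effect: str = "unknown"  # synonymous | nonsynonymous | unknown
    aa_change: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ReferenceError(f"c.{self.c_position}: ref equals alt")
        if self.effect not in ("synonymous", "nonsynonymous", "unknown"):
            raise ReferenceError(f"c.{self.c_position}: bad effect {self.effect!r}")

    @property
    def token(self) -> str:
        return f"c.{self.c_position}{self.ref_base}>{self.alt_base}"

    def validate_against(self, reference: ReferenceExon) -> None:
        obs = reference.base_at(self.c_position)
        if obs != self.ref_base:
            raise ReferenceError(
                f"{self.token}: reference carries {obs} at c.{self.c_position}, "
                f"not {self.ref_base}"
            )


class SnpCatalog:
    """Ordered catalogue of known SNPs, keyed by c.-position."""

    def __init__(self, snps: Iterable[SnpDef], reference: Optional[ReferenceExon] = None):
        self._by_pos: dict[int, SnpDef] = {}
        for snp in snps:
            if snp.c_position in self._by_pos:
                raise ReferenceError(f"duplicate catalogue entry at c.{snp.c_position}")
            if reference is not None:
                snp.validate_against(reference)
            self._by_pos[snp.c_position] = snp
        self._by_pos = dict(sorted(self._by_pos.items()))

    def __len__(self) -> int:
        return len(self._by_pos)

    def __iter__(self):
        return iter(self._by_pos.values())

    def __contains__(self, c_position: int) -> bool:
        return c_position in self._by_pos

    def get(self, c_position: int) -> Optional[SnpDef]:
        return self._by_pos.get(c_position)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(self._by_pos)


@dataclass(frozen=True, order=True)
class Haplotype:
    """The set of alt alleles carried on one chromosome, in canonical order.

    ``variants`` is a sorted tuple of ``(c_position, alt_base)``; the empty
    tuple is the reference haplotype (NAT2*4).
    """

    variants: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.variants]
        if len(set(positions)) != len(positions):
            raise ReferenceError("haplotype carries two alt alleles at one position")
        canon = tuple(sorted(self.variants))
        if canon != self.variants:
            object.__setattr__(self, "variants", canon)

    @classmethod
    def from_tokens(cls, tokens: Iterable[str]) -> "Haplotype":
        return cls(tuple((p, a) for p, _r, a in map(parse_snp_token, tokens)))

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.variants)

    def alt_at(self, c_position: int) -> Optional[str]:
        for p, a in self.variants:
            if p == c_position:
                return a
        return None

    def tokens(self, catalog: Optional[SnpCatalog] = None) -> tuple[str, ...]:
        out = []
        for p, a in self.variants:
            snp = catalog.get(p) if catalog else None
            ref = snp.ref_base if snp else "N"
            out.append(f"c.{p}{ref}>{a}")
        return tuple(out)

    def __str__(self) -> str:
        return "+".join(f"{p}{a}" for p, a in self.variants) or "(ref)"


@dataclass(frozen=True)
class AlleleDef:
    """A named star allele: exact haplotype plus function and group."""

    name: str
    haplotype: Haplotype
    group: str
    function: str  # rapid | slow | unknown

    def __post_init__(self) -> None:
        if self.function not in ("rapid", "slow", "unknown"):
            raise ReferenceError(f"{self.name}: bad function {self.function!r}")


class AlleleTable:
    """Star-allele nomenclature table with signature-group bookkeeping."""

    def __init__(
        self,
        entries: Iterable[AlleleDef],
        signature_priority: tuple[tuple[tuple[int, str], str], ...] = SIGNATURE_PRIORITY,
    ):
        self.entries: list[AlleleDef] = list(entries)
        self.signature_priority = signature_priority
        self.signature_map: dict[tuple[int, str], str] = dict(signature_priority)
        self._by_name: dict[str, AlleleDef] = {}
        self._by_haplotype: dict[Haplotype, AlleleDef] = {}
        for entry in self.entries:
            if entry.name in self._by_name:
                raise ReferenceError(f"duplicate allele name {entry.name}")
            if entry.haplotype in self._by_haplotype:
                other = self._by_haplotype[entry.haplotype].name
                raise ReferenceError(
                    f"{entry.name} and {other} share an identical haplotype"
                )
            self._by_name[entry.name] = entry
            self._by_haplotype[entry.haplotype] = entry
        ref_entry = self._by_name.get("NAT2*4")
        if ref_entry is None or ref_entry.haplotype.variants or ref_entry.function != "rapid":
            raise ReferenceError(
                "allele table must contain the reference entry NAT2*4 "
                "(empty haplotype, function rapid)"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, name: str) -> Optional[AlleleDef]:
        return self._by_name.get(name)

    def lookup(self, haplotype: Haplotype) -> Optional[AlleleDef]:
        return self._by_haplotype.get(haplotype)

    def names(self) -> tuple[str, ...]:
        return tuple(self._by_name)

    def to_tsv(self, path: str | Path, catalog: Optional[SnpCatalog] = None) -> None:
        rows = []
        for e in self.entries:
            snps = ",".join(e.haplotype.tokens(catalog)) if e.haplotype.variants else "(none)"
            rows.append({"name": e.name, "snps": snps, "function": e.function,
                         "group": e.group})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_reference(path: str | Path) -> ReferenceExon:
    """Load and validate the reference coding exon from a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ReferenceError(f"no FASTA record found in {path}")
    if len(records) > 1:
        raise ReferenceError(f"expected a single FASTA record in {path}, got {len(records)}")
    return ReferenceExon(sequence=str(records[0].seq).upper(), source_id=records[0].id)


def load_snp_catalog(path: str | Path, reference: Optional[ReferenceExon] = None) -> SnpCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    snps = []
    for _, row in df.iterrows():
        snps.append(
            SnpDef(
                c_position=int(row["c_position"]),
                ref_base=row["ref"],
                alt_base=row["alt"],
                rsid=row.get("rsid") or None,
                effect=row.get("effect") or "unknown",
                aa_change=row.get("aa_change") or None,
            )
        )
    return SnpCatalog(snps, reference=reference)


def load_allele_table(
    path: str | Path,
    reference: Optional[ReferenceExon] = None,
    signature_priority: tuple[tuple[tuple[int, str], str], ...] = SIGNATURE_PRIORITY,
) -> AlleleTable:
    """Load star-allele definitions, validating each SNP token against the reference."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = []
    for _, row in df.iterrows():
        raw = row["snps"].strip()
        if raw in ("", "(none)", "-"):
            hap = Haplotype()
        else:
            tokens = [t for t in raw.split(",") if t.strip()]
            parsed = [parse_snp_token(t) for t in tokens]
            if reference is not None:
                for pos, ref_base, _alt in parsed:
                    obs = reference.base_at(pos)
                    if obs != ref_base:
                        raise ReferenceError(
                            f"allele {row['name']}: token c.{pos} claims ref "
                            f"{ref_base} but reference carries {obs}"
                        )
            hap = Haplotype(tuple((p, a) for p, _r, a in parsed))
        entries.append(
            AlleleDef(name=row["name"], haplotype=hap, group=row["group"],
                      function=row["function"])
        )
    return AlleleTable(entries, signature_priority=signature_priority)


def _data_path(name: str) -> Path:
    return Path(resources.files("nat2typer.data") / name)  # type: ignore[arg-type]


def default_reference() -> ReferenceExon:
    """The bundled synthetic stand-in reference exon."""
    return load_reference(_data_path("nat2_reference_synthetic.fasta"))


def default_snp_catalog(reference: Optional[ReferenceExon] = None) -> SnpCatalog:
    return load_snp_catalog(_data_path("snp_catalog.tsv"),
                            reference=reference or default_reference())


def default_allele_table(reference: Optional[ReferenceExon] = None) -> AlleleTable:
    return load_allele_table(_data_path("allele_definitions.tsv"),
                             reference=reference or default_reference())


def regional_frequency_path() -> Path:
    return _data_path("regional_haplotype_frequencies.tsv")


def common_genotype_table_path() -> Path:
    return _data_path("common_genotypes_brazil.tsv")


def interethnic_table_path() -> Path:
    return _data_path("interethnic_group_frequencies.tsv")
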
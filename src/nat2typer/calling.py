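"""Diploid genotype calling from Sanger-style consensus sequences.

A sample arrives as a single consensus sequence of the NAT2 coding exon (or
as two overlapping sequencing fragments read in opposite directions), with
heterozygous positions encoded as two-base IUPAC ambiguity codes (R, Y, S,
W, K, M).  Calling proceeds in three steps:

1. optionally merge forward/reverse fragments into one consensus;
2. globally align the consensus to the reference exon, producing a monotone
   map between sample indices and c.-coordinates;
3. at every catalogued SNP position, decode the sample character into an
   unordered diploid base pair — a plain base is a homozygote, a compatible
   two-base code a heterozygote, anything else (N, three/four-base codes,
   gaps, third alleles) goes to ``missing_sites``.

Substitutions at uncatalogued positions are reported as novel-variant
warnings but never used for typing: validating a new polymorphism requires
re-sequencing, which is outside what sequence analysis alone can do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .reference import ReferenceExon, SnpCatalog

#: IUPAC nucleotide codes mapped to their base sets.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: Reverse lookup for two-base ambiguity codes.
AMBIGUITY_CODE: dict[frozenset[str], str] = {
    v: k for k, v in IUPAC_SETS.items() if len(v) == 2
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_ALPHABET = "ACGTRYSWKMBDHVN"


class SequenceError(ValueError):
    """Raised for malformed sample sequences."""


class MergeError(ValueError):
    """Raised when forward/reverse fragments cannot be merged."""


class AlignmentQualityError(ValueError):
    """Raised when a sample aligns to the reference below the identity floor."""


@dataclass(frozen=True)
class SampleSequence:
    """One sample's consensus (or fragment) sequence, IUPAC codes allowed."""

    sample_id: str
    sequence: str
    stratum: Optional[str] = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set(_ALPHABET)
        if bad:
            raise SequenceError(
                f"{self.sample_id}: invalid sequence characters {sorted(bad)}"
            )

    def check_length(self, min_len: int = 500, max_len: int = 1100) -> None:
        if not min_len <= len(self.sequence) <= max_len:
            raise SequenceError(
                f"{self.sample_id}: length {len(self.sequence)} outside "
                f"[{min_len}, {max_len}]"
            )


@dataclass
class UnphasedGenotype:
    """Per-site diploid calls for one sample at catalogued SNP positions."""

    sample_id: str
    calls: dict[int, tuple[str, str]]  # c_position -> sorted base pair
    het_count: int
    missing_sites: list[int]
    novel_variants: list[tuple[int, str, str]] = field(default_factory=list)
    stratum: Optional[str] = None

    def __post_init__(self) -> None:
        observed_het = sum(1 for a, b in self.calls.values() if a != b)
        if observed_het != self.het_count:
            raise ValueError(
                f"{self.sample_id}: het_count {self.het_count} != observed {observed_het}"
            )

    @property
    def het_positions(self) -> tuple[int, ...]:
        return tuple(p for p, (a, b) in sorted(self.calls.items()) if a != b)


def reverse_complement(sequence: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(sequence.upper()))


def _compatible(a: str, b: str) -> bool:
    return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


def _resolve(a: str, b: str) -> str:
    """Overlap-resolution rule: agree -> base; base vs compatible IUPAC -> the
    more ambiguous code; incompatible -> N."""
    if a == b:
        return a
    sa, sb = IUPAC_SETS[a], IUPAC_SETS[b]
    if sa & sb:
        return a if len(sa) >= len(sb) else b
    return "N"


def merge_fragments(
    forward: SampleSequence,
    reverse: SampleSequence,
    min_overlap: int = 30,
) -> SampleSequence:
    """Merge a forward fragment with a reverse-orientation fragment.

    The reverse fragment is supplied in sequencing orientation and is
    reverse-complemented first.  The merge seeks the longest suffix/prefix
    overlap (>= ``min_overlap``) in which at least 80% of positions are
    IUPAC-compatible; within the overlap, disagreements resolve per
    :func:`_resolve`.
    """
    fwd = forward.sequence
    rev = reverse_complement(reverse.sequence)
    best = None
    for overlap in range(min(len(fwd), len(rev)), min_overlap - 1, -1):
        tail, head = fwd[-overlap:], rev[:overlap]
        n_ok = sum(_compatible(a, b) for a, b in zip(tail, head))
        if n_ok / overlap >= 0.8:
            best = overlap
            break
    if best is None:
        raise MergeError(
            f"{forward.sample_id}: no overlap of >= {min_overlap} compatible bases"
        )
    merged_overlap = "".join(_resolve(a, b) for a, b in zip(fwd[-best:], rev[:best]))
    merged = fwd[:-best] + merged_overlap + rev[best:]
    sample_id = forward.sample_id.removesuffix("_F")
    return SampleSequence(sample_id=sample_id, sequence=merged, stratum=forward.stratum)


def _aligner() -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            matrix[a, b] = 1.0 if _compatible(a, b) else -1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


_SHARED_ALIGNER = _aligner()


@dataclass(frozen=True)
class AlignmentMap:
    """Monotone bidirectional map between sample indices and c.-positions."""

    sample_to_c: dict[int, int]  # 0-based sample index -> 1-based c position
    identity: float

    def c_to_sample(self) -> dict[int, int]:
        return {c: i for i, c in self.sample_to_c.items()}


def align_to_reference(
    sample: SampleSequence,
    ref: ReferenceExon,
    min_identity: float = 0.80,
) -> AlignmentMap:
    """Global pairwise alignment of a sample consensus to the reference exon.

    IUPAC codes score as matches against any compatible base (match +1,
    mismatch -1, gap open -5, gap extend -1).  Raises
    :class:`AlignmentQualityError` if the fraction of compatible aligned
    columns falls below ``min_identity``.
    """
    if not sample.sequence:
        raise SequenceError(f"{sample.sample_id}: empty sequence")
    alignment = _SHARED_ALIGNER.align(ref.sequence, sample.sequence)[0]
    sample_to_c: dict[int, int] = {}
    n_cols = 0
    n_ok = 0
    ref_blocks, smp_blocks = alignment.aligned
    for (r0, r1), (s0, s1) in zip(ref_blocks, smp_blocks):
        for r, s in zip(range(r0, r1), range(s0, s1)):
            sample_to_c[s] = r + 1
            n_cols += 1
            n_ok += _compatible(ref.sequence[r], sample.sequence[s])
    identity = n_ok / n_cols if n_cols else 0.0
    if identity < min_identity:
        raise AlignmentQualityError(
            f"{sample.sample_id}: alignment identity {identity:.2%} below "
            f"{min_identity:.0%}"
        )
    return AlignmentMap(sample_to_c=sample_to_c, identity=identity)


def call_genotype(
    sample: SampleSequence,
    ref: ReferenceExon,
    catalog: SnpCatalog,
    min_identity: float = 0.80,
) -> UnphasedGenotype:
    """Call an unphased diploid genotype at every catalogued SNP position."""
    amap = align_to_reference(sample, ref, min_identity=min_identity)
    c_to_sample = amap.c_to_sample()

    calls: dict[int, tuple[str, str]] = {}
    missing: list[int] = []
    novel: list[tuple[int, str, str]] = []

    catalogued = set(catalog.positions)
    for snp in catalog:
        idx = c_to_sample.get(snp.c_position)
        if idx is None:
            missing.append(snp.c_position)
            continue
        observed = IUPAC_SETS[sample.sequence[idx]]
        site_alleles = {snp.ref_base, snp.alt_base}
        if observed == {snp.ref_base}:
            calls[snp.c_position] = (snp.ref_base, snp.ref_base)
        elif observed == {snp.alt_base}:
            calls[snp.c_position] = (snp.alt_base, snp.alt_base)
        elif observed == site_alleles:
            calls[snp.c_position] = tuple(sorted(site_alleles))  # type: ignore[assignment]
        else:
            missing.append(snp.c_position)

    # Uncatalogued mismatches: report, never type.
    for idx, c_pos in amap.sample_to_c.items():
        if c_pos in catalogued:
            continue
        ref_base = ref.sequence[c_pos - 1]
        obs = sample.sequence[idx]
        if obs != ref_base and IUPAC_SETS[obs] != {ref_base}:
            novel.append((c_pos, ref_base, obs))

    het = sum(1 for a, b in calls.values() if a != b)
    return UnphasedGenotype(
        sample_id=sample.sample_id,
        calls=calls,
        het_count=het,
        missing_sites=sorted(missing),
        novel_variants=sorted(novel),
        stratum=sample.stratum,
    )


def table_to_genotypes(df, catalog: SnpCatalog) -> list[UnphasedGenotype]:
    """Rebuild :class:`UnphasedGenotype` objects from a VCF-like long table."""
    out = []
    for (sample, stratum), sub in df.groupby(["sample", "stratum"], sort=False):
        calls: dict[int, tuple[str, str]] = {}
        missing: list[int] = []
        for _, row in sub.iterrows():
            snp = catalog.get(int(row["c_position"]))
            gt = row["genotype"]
            if gt == "./.":
                missing.append(snp.c_position)
                continue
            dosage = gt.count("1")
            pair = {
                0: (snp.ref_base, snp.ref_base),
                1: tuple(sorted((snp.ref_base, snp.alt_base))),
                2: (snp.alt_base, snp.alt_base),
            }[dosage]
            calls[snp.c_position] = pair  # type: ignore[assignment]
        het = sum(1 for a, b in calls.values() if a != b)
        out.append(UnphasedGenotype(str(sample), calls, het, sorted(missing),
                                    stratum=str(stratum) or None))
    return out


def genotypes_to_table(genotypes: Iterable[UnphasedGenotype], catalog: SnpCatalog):
    """VCF-like long table (one row per sample x catalogued site)."""
    import pandas as pd

    rows = []
    for g in genotypes:
        for snp in catalog:
            pos = snp.c_position
            if pos in g.calls:
                a, b = g.calls[pos]
                dosage = (a != snp.ref_base) + (b != snp.ref_base)
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[dosage]
            else:
                gt = "./."
            rows.append({
                "sample": g.sample_id, "stratum": g.stratum or "",
                "c_position": pos, "rsid": snp.rsid or ".",
                "ref": snp.ref_base, "alt": snp.alt_base, "genotype": gt,
            })
    return pd.DataFrame(rows)
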
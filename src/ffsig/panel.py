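"""SNP panel model: phased parental genotypes and the five-type classification.

A locus is classified purely from the equality structure of the four phased
parental alleles (M1, M2) and (P1, P2):

* Type-1: both parents homozygous, for different alleles.
* Type-2: both parents homozygous for the same allele.
* Type-3: father heterozygous, mother homozygous; subtyped by which paternal
  haplotype carries an allele absent in the mother.
* Type-4: mother heterozygous, father homozygous; subtyped alpha/beta by
  whether the father's allele equals the M1 or the M2 allele.
* Type-5: both parents heterozygous.

Y loci are presence/absence markers carrying no parental genotypes and are
kept outside the Type 1-5 system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence, Tuple

NUCLEOTIDES = frozenset("ACGT")

__all__ = [
    "NUCLEOTIDES",
    "SnpType",
    "Subtype",
    "SnpClass",
    "SnpLocus",
    "Panel",
    "classify_snp",
    "build_panel",
]


class SnpType(str, Enum):
    T1 = "T1"
    T2 = "T2"
    T3 = "T3"
    T4 = "T4"
    T5 = "T5"


class Subtype(str, Enum):
    NONE = "NONE"
    T3_P1 = "T3_P1"
    T3_P2 = "T3_P2"
    T4_ALPHA = "T4_ALPHA"
    T4_BETA = "T4_BETA"


#: Report-layer aliases matching common usage (T3 subtypes are also called
#: alpha/beta after the paternal haplotype carrying the mother-absent allele).
SUBTYPE_ALIASES = {
    Subtype.T3_P1: "T3 alpha (P1)",
    Subtype.T3_P2: "T3 beta (P2)",
    Subtype.T4_ALPHA: "T4 alpha",
    Subtype.T4_BETA: "T4 beta",
}


@dataclass(frozen=True)
class SnpClass:
    """Classification of one locus.

    ``paternal_specific_allele`` is set for Type-3 loci (the allele absent in
    the mother), ``m1_allele``/``m2_allele`` for Type-4 loci.
    """

    snp_type: SnpType
    subtype: Subtype = Subtype.NONE
    paternal_specific_allele: Optional[str] = None
    m1_allele: Optional[str] = None
    m2_allele: Optional[str] = None

    @property
    def key(self) -> Tuple[SnpType, Subtype]:
        return (self.snp_type, self.subtype)


def _check_allele(a: str) -> str:
    if not isinstance(a, str) or a.upper() not in NUCLEOTIDES:
        raise ValueError(f"invalid nucleotide: {a!r}")
    return a.upper()


def classify_snp(
    maternal_hap: Sequence[str], paternal_hap: Sequence[str]
) -> SnpClass:
    """Classify a locus from phased parental allele pairs.

    Total and deterministic over all 4^4 phased genotype combinations; only
    the equality structure of the alleles matters.

    Tri-allelic corner cases (allowed but rare in practice):

    * Type-3 with *both* paternal alleles absent in the mother is assigned
      subtype ``T3_P1`` by convention (both haplotypes are informative).
    * Type-4 with a paternal allele matching neither maternal haplotype gets
      subtype ``NONE`` and is excluded from alpha/beta estimation.
    """
    if len(maternal_hap) != 2 or len(paternal_hap) != 2:
        raise ValueError("haplotypes must be allele pairs")
    m1, m2 = (_check_allele(a) for a in maternal_hap)
    p1, p2 = (_check_allele(a) for a in paternal_hap)

    mother_hom = m1 == m2
    father_hom = p1 == p2

    if mother_hom and father_hom:
        if m1 == p1:
            return SnpClass(SnpType.T2)
        return SnpClass(SnpType.T1)

    if mother_hom and not father_hom:
        # exactly one of p1/p2 can equal the maternal allele
        if p1 != m1:
            subtype, specific = Subtype.T3_P1, p1
        else:
            subtype, specific = Subtype.T3_P2, p2
        return SnpClass(SnpType.T3, subtype, paternal_specific_allele=specific)

    if not mother_hom and father_hom:
        if p1 == m1:
            subtype = Subtype.T4_ALPHA
        elif p1 == m2:
            subtype = Subtype.T4_BETA
        else:
            subtype = Subtype.NONE
        return SnpClass(SnpType.T4, subtype, m1_allele=m1, m2_allele=m2)

    return SnpClass(SnpType.T5)


@dataclass(frozen=True)
class SnpLocus:
    """One panel SNP with phased parental genotypes.

    Y loci (``is_y_locus=True``) carry no parental alleles and no class.
    """

    snp_id: str
    chrom: str
    pos: int
    maternal_hap: Tuple[str, str] = ("A", "A")
    paternal_hap: Tuple[str, str] = ("A", "A")
    is_y_locus: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be 1-based positive")
        if not self.is_y_locus:
            # validates alleles as a side effect
            classify_snp(self.maternal_hap, self.paternal_hap)

    @property
    def classification(self) -> Optional[SnpClass]:
        if self.is_y_locus:
            return None
        return classify_snp(self.maternal_hap, self.paternal_hap)

    @property
    def expected_alleles(self) -> frozenset:
        """Alleles consistent with the parental genotypes."""
        if self.is_y_locus:
            return frozenset(NUCLEOTIDES)
        return frozenset(self.maternal_hap) | frozenset(self.paternal_hap)


class Panel:
    """Ordered collection of loci with per-class tallies and id lookup."""

    def __init__(self, loci: Iterable[SnpLocus]):
        self.loci: Tuple[SnpLocus, ...] = tuple(loci)
        if not self.loci:
            raise ValueError("empty panel")
        self._by_id = {}
        for locus in self.loci:
            if locus.snp_id in self._by_id:
                raise ValueError(f"duplicate snp_id: {locus.snp_id}")
            self._by_id[locus.snp_id] = locus

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._by_id

    def get(self, snp_id: str) -> SnpLocus:
        return self._by_id[snp_id]

    @property
    def y_loci(self) -> Tuple[SnpLocus, ...]:
        return tuple(l for l in self.loci if l.is_y_locus)

    @property
    def autosomal_like_loci(self) -> Tuple[SnpLocus, ...]:
        """All non-Y loci (an X-chromosome panel behaves like an autosomal one)."""
        return tuple(l for l in self.loci if not l.is_y_locus)

    def loci_of_class(
        self, snp_type: SnpType, subtype: Subtype = None
    ) -> Tuple[SnpLocus, ...]:
        out = []
        for locus in self.loci:
            cls = locus.classification
            if cls is None or cls.snp_type != snp_type:
                continue
            if subtype is not None and cls.subtype != subtype:
                continue
            out.append(locus)
        return tuple(out)

    @property
    def counts_by_class(self) -> dict:
        tally: dict = {}
        for locus in self.loci:
            cls = locus.classification
            key = "Y" if cls is None else (
                cls.snp_type.value
                if cls.subtype is Subtype.NONE
                else cls.subtype.value
            )
            tally[key] = tally.get(key, 0) + 1
        return tally


def build_panel(loci: Iterable[SnpLocus]) -> Panel:
    """Validate loci and assemble a :class:`Panel` (duplicate ids rejected)."""
    return Panel(loci)
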
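"""Domain types shared across the pipeline.

The vocabulary follows clinical gene-panel diagnostics: a variant is a
single called difference against the reference, carrying read support and
an annotation bundle; a gene-panel entry records which Mendelian
inheritance modes a gene is known to act under; a pedigree member carries
sex, affection status and (optionally) genotypes at candidate loci.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Effect",
    "Zygosity",
    "Genotype",
    "TriClass",
    "FinalClass",
    "InheritanceMode",
    "VariantLocus",
    "ReadSupport",
    "AnnotationBundle",
    "AnnotatedVariant",
    "GenePanelEntry",
    "TargetRegion",
    "PedigreeMember",
    "Family",
    "MarkerGenotype",
    "TRUNCATING_EFFECTS",
    "NONSYNONYMOUS_EFFECTS",
]

_VALID_BASES = set("ACGT")


class Effect(str, enum.Enum):
    """Functional consequence class of a variant."""

    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    CANONICAL_SPLICE = "canonical_splice"
    SPLICE_REGION = "splice_region"
    INTRONIC = "intronic"
    UTR = "utr"
    LARGE_DELETION = "large_deletion"


#: Effects treated as automatically pathogenic (protein-truncating or
#: canonical ±1/±2 splice disruption, plus large structural deletions).
TRUNCATING_EFFECTS = frozenset(
    {Effect.NONSENSE, Effect.FRAMESHIFT, Effect.CANONICAL_SPLICE, Effect.LARGE_DELETION}
)

#: Effects that pass the "nonsynonymous or splice site" selection outright
#: (splice_region / intronic pass only inside the acceptor/donor windows).
NONSYNONYMOUS_EFFECTS = frozenset(
    {
        Effect.MISSENSE,
        Effect.NONSENSE,
        Effect.FRAMESHIFT,
        Effect.INFRAME_INDEL,
        Effect.CANONICAL_SPLICE,
        Effect.LARGE_DELETION,
    }
)


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"


class Genotype(str, enum.Enum):
    """Genotype of a family member at a candidate locus."""

    REF_REF = "ref_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI_ALT = "hemi_alt"
    MISSING = "missing"

    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI_ALT)


class TriClass(str, enum.Enum):
    """Three-state call of a single evidence axis (in-silico tools,
    conservation, or population frequency)."""

    PATHOGENIC = "pathogenic"
    UNKNOWN = "unknown"
    BENIGN = "benign"


class FinalClass(str, enum.Enum):
    """Final pathogenicity verdict.

    ``PATHOGENIC`` is reserved for truncating / canonical-splice / large
    deletion variants; all other variants can at best reach
    ``PROBABLY_PATHOGENIC`` through the three-axis combination.
    """

    PATHOGENIC = "pathogenic"
    PROBABLY_PATHOGENIC = "probably_pathogenic"
    UNKNOWN = "unknown"
    PROBABLY_BENIGN = "probably_benign"

    def is_pathogenic_tier(self) -> bool:
        return self in (FinalClass.PATHOGENIC, FinalClass.PROBABLY_PATHOGENIC)


class InheritanceMode(str, enum.Enum):
    AR = "AR"
    AD = "AD"
    XL = "XL"


@dataclass(frozen=True, order=True)
class VariantLocus:
    """Identity of a variant: chromosome, 1-based position, ref/alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not allele:
                raise ValueError("alleles must be nonempty")
            if not (set(allele) <= _VALID_BASES or allele.startswith("<DEL")):
                raise ValueError(f"invalid allele {allele!r}")

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class ReadSupport:
    """Read-level evidence for one variant call at one site."""

    total_reads: int
    variant_reads: int
    nonduplicate_variant_reads: int
    forward_variant_reads: int
    reverse_variant_reads: int
    hq_variant_reads: int

    def __post_init__(self) -> None:
        counts = (
            self.total_reads,
            self.variant_reads,
            self.nonduplicate_variant_reads,
            self.forward_variant_reads,
            self.reverse_variant_reads,
            self.hq_variant_reads,
        )
        if any(c < 0 for c in counts):
            raise ValueError("read counts must be non-negative")
        if self.variant_reads > self.total_reads:
            raise ValueError("variant_reads exceeds total_reads")
        if self.forward_variant_reads + self.reverse_variant_reads != self.variant_reads:
            raise ValueError("forward + reverse must equal variant_reads")
        if self.nonduplicate_variant_reads > self.variant_reads:
            raise ValueError("nonduplicate_variant_reads exceeds variant_reads")
        if self.hq_variant_reads > self.variant_reads:
            raise ValueError("hq_variant_reads exceeds variant_reads")

    @property
    def variant_fraction(self) -> float:
        """Fraction of reads at the site supporting the alternate allele."""
        if self.total_reads == 0:
            return 0.0
        return self.variant_reads / self.total_reads


@dataclass(frozen=True)
class AnnotationBundle:
    """Precomputed annotations joined onto a variant.

    Splice offsets are signed distances from the nearest splice site in
    cDNA convention: acceptor offsets are negative (c.x-14 -> -14), donor
    offsets positive (c.x+3 -> +3). ``missense_calls`` are the per-tool
    (SIFT, PolyPhen, MutPred) three-state classifications; ``splice_scores``
    holds per-tool (ssf, maxent, nnsplice) wild-type / mutant score pairs.
    """

    effect: Effect
    in_dbsnp130: bool = False
    in_hgmd: bool = False
    known_blindness_mutation: bool = False
    exome_cohort_freq: float = 0.0
    disease_cohort_freq: float = 0.0
    phylop: float = 0.0
    splice_acceptor_offset: Optional[int] = None
    splice_donor_offset: Optional[int] = None
    missense_calls: Optional[tuple[TriClass, TriClass, TriClass]] = None
    splice_scores: Optional[dict[str, tuple[float, float]]] = None

    def __post_init__(self) -> None:
        for f in (self.exome_cohort_freq, self.disease_cohort_freq):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} outside [0, 1]")
        if self.missense_calls is not None and self.effect is not Effect.MISSENSE:
            raise ValueError("missense_calls only valid for missense variants")
        if self.splice_scores is not None and self.effect not in (
            Effect.SPLICE_REGION,
            Effect.INTRONIC,
        ):
            raise ValueError("splice_scores only valid for splice_region/intronic variants")


@dataclass(frozen=True)
class AnnotatedVariant:
    """A called variant with locus, gene, zygosity, support and annotation."""

    locus: VariantLocus
    gene: str
    zygosity: Zygosity
    support: ReadSupport
    annot: AnnotationBundle
    sample_id: str = ""
    rescued: bool = False

    def sort_key(self) -> tuple:
        return (self.gene, self.locus.chrom, self.locus.pos, self.locus.ref, self.locus.alt)


@dataclass(frozen=True)
class GenePanelEntry:
    """A panel gene with its allowed inheritance modes."""

    gene: str
    chrom: str
    modes: frozenset[InheritanceMode]

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError(f"gene {self.gene}: modes must be nonempty")
        if InheritanceMode.XL in self.modes and self.chrom not in ("chrX", "X"):
            raise ValueError(f"gene {self.gene}: XL mode on non-X chromosome {self.chrom}")


@dataclass(frozen=True)
class TargetRegion:
    """A capture target: 0-based half-open interval (BED convention)."""

    chrom: str
    start: int
    end: int
    gene: str
    region_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"target {self.region_id}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PedigreeMember:
    individual_id: str
    family_id: str
    sex: str  # "male" | "female"
    affected: bool
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    genotypes: dict[VariantLocus, Genotype] = field(default_factory=dict)

    def genotype_at(self, locus: VariantLocus) -> Genotype:
        return self.genotypes.get(locus, Genotype.MISSING)


@dataclass
class Family:
    family_id: str
    members: dict[str, PedigreeMember] = field(default_factory=dict)

    def add(self, member: PedigreeMember) -> None:
        self.members[member.individual_id] = member

    @property
    def proband(self) -> Optional[PedigreeMember]:
        """First affected member with both parents absent-or-present; by
        convention the first affected member listed."""
        for m in self.members.values():
            if m.affected:
                return m
        return None

    def relatives_of(self, individual_id: str) -> list[PedigreeMember]:
        return [m for m in self.members.values() if m.individual_id != individual_id]

    def parents_of(self, individual_id: str) -> tuple[Optional[PedigreeMember], Optional[PedigreeMember]]:
        m = self.members[individual_id]
        father = self.members.get(m.father_id) if m.father_id else None
        mother = self.members.get(m.mother_id) if m.mother_id else None
        return father, mother


@dataclass(frozen=True)
class MarkerGenotype:
    """One polymorphic marker typed in one individual (two allele labels)."""

    marker_id: str
    allele1: str
    allele2: str

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele1, self.allele2)
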
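"""Family-level evidence: co-segregation, de novo detection, marker-based
Mendelian consistency, compound-het phase, and multilocus flagging.

Segregation asks whether the candidate genotypes track with affection
status through a family under a stated inheritance mode, assuming
complete penetrance for dominant and X-linked-male disease. De novo
detection compares a child's genotype with both parents and is only
trusted as a confirmed de novo event when polymorphic-marker genotypes
prove Mendelian inheritance (i.e. paternity/maternity) across the trio;
without markers a de novo call is reported as apparent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .types import (
    AnnotatedVariant,
    Family,
    FinalClass,
    Genotype,
    GenePanelEntry,
    InheritanceMode,
    MarkerGenotype,
    PedigreeMember,
    VariantLocus,
    Zygosity,
)
from .prioritization import passes_inheritance_filter

__all__ = [
    "SegregationStatus",
    "SegregationVerdict",
    "check_segregation",
    "detect_de_novo",
    "mendelian_consistency",
    "check_trans_phase",
    "variant_origin",
    "detect_multilocus",
]


class SegregationStatus(str, enum.Enum):
    FULL = "full"
    PARTIAL = "partial"
    CONTRADICTED = "contradicted"
    UNTESTED = "untested"


@dataclass
class SegregationVerdict:
    status: SegregationStatus
    de_novo_loci: list[VariantLocus] = field(default_factory=list)
    notes: str = ""


def _is_biallelic(member: PedigreeMember, loci: Sequence[VariantLocus]) -> Optional[bool]:
    """Does the member carry a disease-causing allele dose (both alleles)?

    For a single candidate locus this means homozygous (or hemizygous);
    for a compound-het pair it means carrying the alternate allele at two
    or more distinct loci. None when any candidate genotype is missing.
    """
    gts = [member.genotype_at(l) for l in loci]
    if any(g is Genotype.MISSING for g in gts):
        return None
    if any(g in (Genotype.HOM_ALT, Genotype.HEMI_ALT) for g in gts):
        return True
    return sum(g.carries_alt() for g in gts) >= 2


def _carries_any(member: PedigreeMember, loci: Sequence[VariantLocus]) -> Optional[bool]:
    gts = [member.genotype_at(l) for l in loci]
    if any(g is Genotype.MISSING for g in gts):
        return None
    return any(g.carries_alt() for g in gts)


def check_segregation(
    candidate_loci: Sequence[VariantLocus],
    family: Family,
    proband_id: str,
    mode: InheritanceMode,
    gene_entry: Optional[GenePanelEntry] = None,
) -> SegregationVerdict:
    """Test co-segregation of the candidate genotypes under one mode.

    Recessive: every affected member must carry both alleles and no
    unaffected member may; dominant: every affected member carries the
    allele and no unaffected member does; X-linked: affected males are
    hemizygous carriers, unaffected males carry nothing, affected females
    carry both alleles (carrier females are permitted). A single
    inconsistent typed relative contradicts; untyped relatives degrade a
    full verdict to partial; with no typed relative the verdict is
    untested. De novo loci are recorded when both parents are typed.
    """
    if gene_entry is not None and mode not in gene_entry.modes:
        raise ValueError(f"mode {mode.value} not allowed for gene {gene_entry.gene}")
    if not candidate_loci:
        raise ValueError("no candidate loci given")
    proband = family.members[proband_id]
    relatives = family.relatives_of(proband_id)
    if not relatives:
        return SegregationVerdict(SegregationStatus.UNTESTED, notes="no relatives in pedigree")

    typed = 0
    contradiction: Optional[str] = None
    for rel in relatives:
        if mode is InheritanceMode.AR:
            status = _is_biallelic(rel, candidate_loci)
            should_carry_both = rel.affected
        elif mode is InheritanceMode.AD:
            status = _carries_any(rel, candidate_loci)
            should_carry_both = rel.affected
        else:  # XL
            if rel.sex == "male":
                status = _carries_any(rel, candidate_loci)
                should_carry_both = rel.affected
            else:
                status = _is_biallelic(rel, candidate_loci)
                should_carry_both = rel.affected
        if status is None:
            continue
        typed += 1
        if status != should_carry_both:
            contradiction = (
                f"{rel.individual_id} ({'affected' if rel.affected else 'unaffected'}) "
                f"genotype inconsistent under {mode.value}"
            )
            break

    de_novo_loci = []
    father, mother = family.parents_of(proband_id)
    if father is not None and mother is not None:
        for locus in candidate_loci:
            if (
                detect_de_novo(
                    proband.genotype_at(locus),
                    father.genotype_at(locus),
                    mother.genotype_at(locus),
                )
                is True
            ):
                de_novo_loci.append(locus)

    if contradiction:
        return SegregationVerdict(
            SegregationStatus.CONTRADICTED, de_novo_loci=de_novo_loci, notes=contradiction
        )
    if typed == 0:
        return SegregationVerdict(
            SegregationStatus.UNTESTED, de_novo_loci=de_novo_loci, notes="no typed relatives"
        )
    if typed == len(relatives):
        return SegregationVerdict(SegregationStatus.FULL, de_novo_loci=de_novo_loci)
    return SegregationVerdict(
        SegregationStatus.PARTIAL,
        de_novo_loci=de_novo_loci,
        notes=f"{typed}/{len(relatives)} relatives typed",
    )


def detect_de_novo(
    child_gt: Genotype, father_gt: Genotype, mother_gt: Genotype
) -> Optional[bool]:
    """De novo test for one locus.

    True when the child carries the allele and neither parent does; False
    when a typed parent carries it (or the child does not); None
    (untestable) when the child carries the allele but a parent genotype is
    missing — the absence of data from a parent precludes a conclusion.
    """
    if child_gt is Genotype.MISSING:
        return None
    if not child_gt.carries_alt():
        return False
    parent_carries = [g.carries_alt() for g in (father_gt, mother_gt) if g is not Genotype.MISSING]
    if any(parent_carries):
        return False
    if father_gt is Genotype.MISSING or mother_gt is Genotype.MISSING:
        return None
    return True


def mendelian_consistency(
    child: Sequence[MarkerGenotype],
    father: Sequence[MarkerGenotype],
    mother: Sequence[MarkerGenotype],
) -> tuple[int, int, bool]:
    """Marker-based Mendelian (paternity/maternity) check over a trio.

    A marker is consistent when the child's allele pair can be split into
    one allele present in the father and one present in the mother.
    Returns (consistent_count, total, confirmed); confirmed only when
    every marker is consistent.
    """
    if not child:
        raise ValueError("at least one marker required")
    f_by_id = {m.marker_id: m for m in father}
    m_by_id = {m.marker_id: m for m in mother}
    consistent = 0
    total = 0
    for cm in child:
        fm, mm = f_by_id.get(cm.marker_id), m_by_id.get(cm.marker_id)
        if fm is None or mm is None:
            continue
        total += 1
        a, b = cm.alleles
        if (a in fm.alleles and b in mm.alleles) or (b in fm.alleles and a in mm.alleles):
            consistent += 1
    if total == 0:
        raise ValueError("no markers typed in all three individuals")
    return consistent, total, consistent == total


def variant_origin(
    family: Family, proband_id: str, locus: VariantLocus
) -> str:
    """Parental origin of a heterozygous allele: 'maternal', 'paternal',
    'de_novo', or 'unknown' (ambiguous or missing parental data)."""
    father, mother = family.parents_of(proband_id)
    if father is None or mother is None:
        return "unknown"
    f = father.genotype_at(locus)
    m = mother.genotype_at(locus)
    if f is Genotype.MISSING or m is Genotype.MISSING:
        return "unknown"
    fc, mc = f.carries_alt(), m.carries_alt()
    if fc and mc:
        return "unknown"
    if fc:
        return "paternal"
    if mc:
        return "maternal"
    return "de_novo"


def check_trans_phase(
    family: Family, proband_id: str, locus1: VariantLocus, locus2: VariantLocus
) -> str:
    """Phase of two heterozygous variants in the proband: 'trans' when the
    parental origins differ (one may be de novo), 'cis' when both trace to
    the same parent, 'unknown' without informative parents."""
    o1 = variant_origin(family, proband_id, locus1)
    o2 = variant_origin(family, proband_id, locus2)
    if "unknown" in (o1, o2):
        return "unknown"
    if o1 == o2 and o1 in ("maternal", "paternal"):
        return "cis"
    if o1 == o2 == "de_novo":
        # two independent de novo events on the same haplotype cannot be
        # excluded, but origins do not trace to one parent
        return "unknown"
    return "trans"


def detect_multilocus(
    classified_by_sample: dict[str, list[tuple[AnnotatedVariant, FinalClass]]],
    panel: dict[str, GenePanelEntry],
    sex_by_sample: Optional[dict[str, str]] = None,
) -> list[tuple[str, list[str]]]:
    """Samples carrying pathogenic-tier variants in two or more genes,
    each gene's variant set separately consistent with one of the gene's
    inheritance modes (cumulative mutational load)."""
    flagged = []
    for sample_id, items in classified_by_sample.items():
        sex = (sex_by_sample or {}).get(sample_id, "female")
        by_gene: dict[str, list[AnnotatedVariant]] = {}
        for v, fc in items:
            if fc.is_pathogenic_tier():
                by_gene.setdefault(v.gene, []).append(v)
        qualifying = []
        for gene, variants in by_gene.items():
            entry = panel.get(gene)
            if entry is None:
                continue
            if passes_inheritance_filter(variants, entry, sex):
                qualifying.append(gene)
        if len(qualifying) >= 2:
            flagged.append((sample_id, sorted(qualifying)))
    return flagged
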
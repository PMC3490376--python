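"""High-quality variant designation and the six-criterion prioritization
cascade with second-allele rescue.

A called variant is first designated a *high-quality difference*; only
high-quality variants enter the cascade. The cascade then keeps a variant
when all of the following hold:

1. effect: nonsynonymous, or a splice-site variant within the 8 bp
   acceptor / 20 bp donor window;
2. novelty: not in dbSNP130, unless in HGMD or a known blindness mutation;
3. reference-cohort frequency: not above 5% in the reference exome cohort;
4. disease-cohort frequency: not above 15% within the panel cohort;
5. read support: >= 10 reads with >= 20% variant reads, or >= 5 reads with
   80-100% variant reads;
6. inheritance: genotypes consistent with the gene's known inheritance
   pattern (homozygous / compound heterozygous for recessive genes,
   heterozygous for dominant, hemizygous males or biallelic females for
   X-linked).

When a gene retains a single strong candidate allele (nonsense, frameshift
or canonical splice) in a recessively acting gene, a second-allele rescue
searches the unfiltered variant set of that gene, relaxing the novelty and
frequency criteria (effect and support are retained so that sequencing
noise cannot be rescued).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .config import ThresholdConfig
from .types import (
    AnnotatedVariant,
    Effect,
    GenePanelEntry,
    InheritanceMode,
    NONSYNONYMOUS_EFFECTS,
    PedigreeMember,
    ReadSupport,
    TRUNCATING_EFFECTS,
    Zygosity,
)

__all__ = [
    "FunnelCounts",
    "is_high_quality",
    "passes_effect_filter",
    "passes_novelty_filter",
    "passes_frequency_filters",
    "passes_support_filter",
    "passes_inheritance_filter",
    "rescue_second_allele",
    "prioritize_sample",
]

#: Effects that qualify as a "strong candidate allele" for rescue.
STRONG_CANDIDATE_EFFECTS = frozenset(
    {Effect.NONSENSE, Effect.FRAMESHIFT, Effect.CANONICAL_SPLICE}
)


@dataclass(frozen=True)
class FunnelCounts:
    """Per-stage variant counts for one sample."""

    n_auto_detected: int
    n_after_effect_novelty_frequency: int
    n_after_inheritance: int
    n_after_rescue: int
    n_selected: int

    def __post_init__(self) -> None:
        if not (
            self.n_auto_detected
            >= self.n_after_effect_novelty_frequency
            >= self.n_after_inheritance
        ):
            raise ValueError("funnel counts must be non-increasing through filtering")
        if self.n_after_rescue < self.n_after_inheritance:
            raise ValueError("rescue can only add variants")

    def __add__(self, other: "FunnelCounts") -> "FunnelCounts":
        return FunnelCounts(
            self.n_auto_detected + other.n_auto_detected,
            self.n_after_effect_novelty_frequency + other.n_after_effect_novelty_frequency,
            self.n_after_inheritance + other.n_after_inheritance,
            self.n_after_rescue + other.n_after_rescue,
            self.n_selected + other.n_selected,
        )


def is_high_quality(support: ReadSupport, cfg: ThresholdConfig | None = None) -> bool:
    """High-quality difference designation.

    True when the variant was seen in at least three nonduplicate reads
    including at least one forward and one reverse read, or in at least
    five reads with base quality above 20.
    """
    cfg = cfg or ThresholdConfig()
    rule1 = (
        support.nonduplicate_variant_reads >= cfg.hq_rule1_reads
        and support.forward_variant_reads >= 1
        and support.reverse_variant_reads >= 1
    )
    rule2 = support.hq_variant_reads >= cfg.hq_rule2_reads
    return rule1 or rule2


def passes_effect_filter(v: AnnotatedVariant, cfg: ThresholdConfig | None = None) -> bool:
    """Criterion 1: nonsynonymous, or splice variant within the windows."""
    cfg = cfg or ThresholdConfig()
    effect = v.annot.effect
    if effect in NONSYNONYMOUS_EFFECTS:
        return True
    if effect in (Effect.SPLICE_REGION, Effect.INTRONIC):
        acc, don = v.annot.splice_acceptor_offset, v.annot.splice_donor_offset
        if effect is Effect.SPLICE_REGION and acc is None and don is None:
            raise ValueError(f"{v.locus}: splice_region variant without splice offsets")
        ok_acc = acc is not None and abs(acc) <= cfg.splice_acceptor_window
        ok_don = don is not None and abs(don) <= cfg.splice_donor_window
        return ok_acc or ok_don
    return False


def passes_novelty_filter(v: AnnotatedVariant, cfg: ThresholdConfig | None = None) -> bool:
    """Criterion 2: not in dbSNP130 unless in HGMD or a known blindness mutation."""
    a = v.annot
    return (not a.in_dbsnp130) or a.in_hgmd or a.known_blindness_mutation


def passes_frequency_filters(v: AnnotatedVariant, cfg: ThresholdConfig | None = None) -> bool:
    """Criteria 3+4: cohort frequency bounds (strict greater-than exclusion)."""
    cfg = cfg or ThresholdConfig()
    return (
        v.annot.exome_cohort_freq <= cfg.exome_filter_max
        and v.annot.disease_cohort_freq <= cfg.cohort_filter_max
    )


def passes_support_filter(support: ReadSupport, cfg: ThresholdConfig | None = None) -> bool:
    """Criterion 5: depth and variant-read fraction."""
    cfg = cfg or ThresholdConfig()
    if support.total_reads == 0:
        return False
    frac = support.variant_fraction
    branch_a = support.total_reads >= cfg.support_reads_a and frac >= cfg.support_frac_a
    branch_b = support.total_reads >= cfg.support_reads_b and frac >= cfg.support_frac_b_lo
    return branch_a or branch_b


def _mode_consistent(
    variants: Sequence[AnnotatedVariant], mode: InheritanceMode, sex: str
) -> list[AnnotatedVariant]:
    """Variants in one gene consistent with one inheritance mode."""
    if mode is InheritanceMode.AD:
        return [v for v in variants if v.zygosity in (Zygosity.HET, Zygosity.HOM)]
    if mode is InheritanceMode.AR:
        homs = [v for v in variants if v.zygosity is Zygosity.HOM]
        hets = [v for v in variants if v.zygosity is Zygosity.HET]
        if homs:
            return list(variants)
        if len({v.locus for v in hets}) >= 2:
            return hets
        return []
    if mode is InheritanceMode.XL:
        if sex == "male":
            return [v for v in variants if v.zygosity is Zygosity.HEMI]
        homs = [v for v in variants if v.zygosity is Zygosity.HOM]
        hets = [v for v in variants if v.zygosity is Zygosity.HET]
        if homs:
            return [v for v in variants if v.zygosity in (Zygosity.HOM, Zygosity.HET)]
        if len({v.locus for v in hets}) >= 2:
            return hets
        return []
    raise ValueError(f"unknown inheritance mode {mode!r}")


def passes_inheritance_filter(
    variants_in_gene: Sequence[AnnotatedVariant],
    entry: GenePanelEntry,
    sex: str = "female",
) -> list[AnnotatedVariant]:
    """Criterion 6: keep the union of variants consistent with any of the
    gene's inheritance modes, preserving input order."""
    keep: set = set()
    for mode in entry.modes:
        keep.update(id(v) for v in _mode_consistent(variants_in_gene, mode, sex))
    return [v for v in variants_in_gene if id(v) in keep]


def rescue_second_allele(
    shortlist_in_gene: Sequence[AnnotatedVariant],
    unfiltered_in_gene: Sequence[AnnotatedVariant],
    entry: GenePanelEntry,
    cfg: ThresholdConfig | None = None,
) -> list[AnnotatedVariant]:
    """Manual second-allele search for a lone strong candidate allele.

    Triggered when exactly one variant survives in an AR-capable gene and
    it is a nonsense, frameshift or canonical splice variant. Returns
    additional variants from the gene's unfiltered set that pass the effect
    and support criteria (novelty and frequency relaxed), tagged rescued.
    """
    cfg = cfg or ThresholdConfig()
    if InheritanceMode.AR not in entry.modes:
        return []
    if len(shortlist_in_gene) != 1:
        return []
    survivor = shortlist_in_gene[0]
    if survivor.annot.effect not in STRONG_CANDIDATE_EFFECTS:
        return []
    kept_loci = {survivor.locus}
    rescued = []
    for v in unfiltered_in_gene:
        if v.locus in kept_loci:
            continue
        if not is_high_quality(v.support, cfg):
            continue
        if passes_effect_filter(v, cfg) and passes_support_filter(v.support, cfg):
            rescued.append(
                AnnotatedVariant(
                    locus=v.locus,
                    gene=v.gene,
                    zygosity=v.zygosity,
                    support=v.support,
                    annot=v.annot,
                    sample_id=v.sample_id,
                    rescued=True,
                )
            )
    return rescued


def prioritize_sample(
    variants: Sequence[AnnotatedVariant],
    panel: dict[str, GenePanelEntry],
    pedigree_member: Optional[PedigreeMember],
    cfg: ThresholdConfig | None = None,
) -> tuple[list[AnnotatedVariant], FunnelCounts]:
    """Run the full cascade for one sample.

    Returns the deterministic (gene, locus)-sorted shortlist and the
    per-stage funnel counts. ``n_auto_detected`` counts every called
    variant; quality designation and criteria 1-5 yield
    ``n_after_effect_novelty_frequency``; the inheritance criterion and
    second-allele rescue yield the remaining stages.
    """
    cfg = cfg or ThresholdConfig()
    n_auto = len(variants)

    if pedigree_member is None:
        sex = "female"
        if variants:
            warnings.warn(
                f"sample {variants[0].sample_id or '?'} absent from pedigree; "
                "applying mode-union inheritance with female default"
            )
    else:
        sex = pedigree_member.sex

    hq = [v for v in variants if is_high_quality(v.support, cfg)]
    passed = [
        v
        for v in hq
        if passes_effect_filter(v, cfg)
        and passes_novelty_filter(v, cfg)
        and passes_frequency_filters(v, cfg)
        and passes_support_filter(v.support, cfg)
    ]
    n_filters = len(passed)

    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in passed:
        by_gene.setdefault(v.gene, []).append(v)
    hq_by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in hq:
        hq_by_gene.setdefault(v.gene, []).append(v)

    shortlist: list[AnnotatedVariant] = []
    for gene, gene_variants in by_gene.items():
        entry = panel.get(gene)
        if entry is None:
            raise KeyError(f"gene {gene} not in the active panel")
        shortlist.extend(passes_inheritance_filter(gene_variants, entry, sex))
    n_inherit = len(shortlist)

    # second-allele rescue: lone strong candidate in an AR-capable gene
    surviving_by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in shortlist:
        surviving_by_gene.setdefault(v.gene, []).append(v)
    # genes whose variants all failed inheritance may still hold a lone
    # strong candidate: a single het truncating variant in an AR-only gene
    for gene, gene_variants in by_gene.items():
        if gene in surviving_by_gene:
            continue
        strong = [v for v in gene_variants if v.annot.effect in STRONG_CANDIDATE_EFFECTS]
        if len(gene_variants) == 1 and len(strong) == 1:
            surviving_by_gene[gene] = strong

    rescued_all: list[AnnotatedVariant] = []
    for gene, survivors in surviving_by_gene.items():
        entry = panel[gene]
        rescued = rescue_second_allele(survivors, hq_by_gene.get(gene, []), entry, cfg)
        if rescued:
            rescued_all.extend(rescued)
            for s in survivors:
                if s not in shortlist:
                    shortlist.append(s)  # the lone candidate re-enters with its partner
    shortlist.extend(rescued_all)

    n_rescue = len(shortlist)
    shortlist.sort(key=lambda v: v.sort_key())
    counts = FunnelCounts(
        n_auto_detected=n_auto,
        n_after_effect_novelty_frequency=n_filters,
        n_after_inheritance=n_inherit,
        n_after_rescue=n_rescue,
        n_selected=len(shortlist),
    )
    return shortlist, counts
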
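"""Run the six-criterion prioritization cascade on one sample.

Builds a small variant table for a proband — a planted compound-het pair
in a recessive gene among common, silent and poorly supported background
calls — and prints the funnel counts and the resulting shortlist,
including a second allele recovered by the rescue step.
"""

from rptriage.prioritization import prioritize_sample
from rptriage.types import (
    AnnotatedVariant,
    AnnotationBundle,
    Effect,
    GenePanelEntry,
    InheritanceMode,
    PedigreeMember,
    ReadSupport,
    VariantLocus,
    Zygosity,
)

GOOD = ReadSupport(30, 15, 15, 8, 7, 15)
WEAK = ReadSupport(4, 2, 2, 2, 0, 2)

panel = {
    "USH2A": GenePanelEntry("USH2A", "chr1", frozenset({InheritanceMode.AR})),
    "RHO": GenePanelEntry("RHO", "chr3", frozenset({InheritanceMode.AR, InheritanceMode.AD})),
    "CRB1": GenePanelEntry("CRB1", "chr1", frozenset({InheritanceMode.AR})),
}


def v(gene, chrom, pos, effect, zyg=Zygosity.HET, support=GOOD, **annot):
    return AnnotatedVariant(
        locus=VariantLocus(chrom, pos, "G", "A"), gene=gene, zygosity=zyg,
        support=support, annot=AnnotationBundle(effect=effect, **annot),
    )


variants = [
    # causal pair: a novel nonsense + a known (dbSNP/HGMD) missense that
    # only the rescue step can bring back
    v("USH2A", "chr1", 1_000, Effect.NONSENSE, phylop=4.2),
    v("USH2A", "chr1", 9_000, Effect.MISSENSE, in_dbsnp130=True, phylop=3.0),
    # background: common polymorphism, silent change, deep intronic,
    # low-support call, lone het in a recessive-only gene
    v("RHO", "chr3", 2_000, Effect.MISSENSE, in_dbsnp130=True, exome_cohort_freq=0.2),
    v("RHO", "chr3", 3_000, Effect.SYNONYMOUS),
    v("CRB1", "chr1", 4_000, Effect.INTRONIC, splice_acceptor_offset=-60),
    v("CRB1", "chr1", 5_000, Effect.MISSENSE, support=WEAK),
    v("CRB1", "chr1", 6_000, Effect.MISSENSE),
]

proband = PedigreeMember("S1", "F1", "female", True)
shortlist, funnel = prioritize_sample(variants, panel, proband)

print(f"auto-detected:                 {funnel.n_auto_detected}")
print(f"after effect/novelty/frequency/support: {funnel.n_after_effect_novelty_frequency}")
print(f"after inheritance filter:      {funnel.n_after_inheritance}")
print(f"after second-allele rescue:    {funnel.n_after_rescue}")
print("\nshortlist:")
for s in shortlist:
    tag = " (rescued)" if s.rescued else ""
    print(f"  {s.gene:6s} {s.locus} {s.annot.effect.value}{tag}")

print(
    "\nThe lone nonsense allele in USH2A triggered a manual-style search of\n"
    "the unfiltered calls, recovering the dbSNP-listed missense partner;\n"
    "every background call failed at least one of the six criteria."
)
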
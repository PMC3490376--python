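"""Classify single variants on the three evidence axes.

Builds three annotated variants — a truncating allele, a well-supported
rare missense change, and a common missense polymorphism — and prints
the axis calls and the final verdict for each.
"""

from rptriage.classification import (
    classify_conservation,
    classify_frequency,
    classify_variant,
    vote,
)
from rptriage.types import (
    AnnotatedVariant,
    AnnotationBundle,
    Effect,
    ReadSupport,
    TriClass,
    VariantLocus,
    Zygosity,
)

SUPPORT = ReadSupport(30, 15, 15, 8, 7, 15)


def variant(effect, **annot):
    return AnnotatedVariant(
        locus=VariantLocus("chr1", 1000, "G", "T"),
        gene="USH2A",
        zygosity=Zygosity.HET,
        support=SUPPORT,
        annot=AnnotationBundle(effect=effect, **annot),
    )


examples = {
    "nonsense": variant(Effect.NONSENSE, phylop=4.0),
    "rare missense, tools agree": variant(
        Effect.MISSENSE,
        missense_calls=(TriClass.PATHOGENIC, TriClass.PATHOGENIC, TriClass.BENIGN),
        phylop=3.1,
        exome_cohort_freq=0.001,
    ),
    "common missense": variant(
        Effect.MISSENSE,
        missense_calls=(TriClass.PATHOGENIC, TriClass.PATHOGENIC, TriClass.PATHOGENIC),
        phylop=5.0,
        exome_cohort_freq=0.05,
    ),
}

for label, v in examples.items():
    a = v.annot
    axes = ""
    if a.effect is Effect.MISSENSE:
        axes = (
            f"  tools={vote(a.missense_calls).value}"
            f"  conservation={classify_conservation(a.phylop).value}"
            f"  frequency={classify_frequency(a.exome_cohort_freq, a.disease_cohort_freq).value}"
        )
    print(f"{label:30s} -> {classify_variant(v).value}{axes}")

print(
    "\nTruncating variants are pathogenic outright; everything else is a\n"
    "majority vote of the three axes, except that a frequency above 3% in\n"
    "the reference exomes forces probably_benign regardless of the rest."
)
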
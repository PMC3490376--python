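"""Three-axis pathogenicity classification.

Truncating variants (nonsense, frameshift, canonical splice, large
deletion) are classified pathogenic outright. Every other variant is
scored on three evidence axes —

* in-silico tools: majority vote of three missense predictors (SIFT,
  PolyPhen, MutPred) or, for noncanonical splice variants, of three
  splice predictors (SpliceSiteFinder, MaxEntScan, NNSplice) compared
  wild-type vs mutant;
* evolutionary conservation: PhyloP banding (< 1 benign, > 2.5 pathogenic,
  intermediary unknown);
* population frequency: reference-exome and disease-cohort banding —

and the three axis calls are combined: a benign frequency axis overrides
everything to probably-benign; otherwise a majority vote decides, with a
three-way split mapping to unknown.

Note on MaxEntScan: the wt-mut difference is directional (loss of splice
strength). A mutant score *above* wild type therefore lands in unknown,
never pathogenic.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Iterable, Optional

from .config import ThresholdConfig
from .types import (
    AnnotatedVariant,
    Effect,
    FinalClass,
    TRUNCATING_EFFECTS,
    TriClass,
)

__all__ = [
    "vote",
    "classify_ssf",
    "classify_maxent",
    "classify_nnsplice",
    "classify_conservation",
    "classify_frequency",
    "combine",
    "classify_variant",
    "classify_missense_scores",
    "truth_table",
]


def vote(calls: Iterable[TriClass]) -> TriClass:
    """Majority vote of exactly three calls; a three-way split is unknown."""
    calls = tuple(calls)
    if len(calls) != 3:
        raise ValueError(f"vote requires exactly three calls, got {len(calls)}")
    counts = Counter(calls)
    top, n = counts.most_common(1)[0]
    return top if n >= 2 else TriClass.UNKNOWN


def classify_ssf(wt: float, mut: float, cfg: ThresholdConfig | None = None) -> TriClass:
    """SpliceSiteFinder call (0-100 scale): site lost -> pathogenic,
    weakened by more than 5 points -> unknown, else benign."""
    cfg = cfg or ThresholdConfig()
    if wt > cfg.ssf_site and mut < cfg.ssf_site:
        return TriClass.PATHOGENIC
    if wt - mut > cfg.ssf_diff:
        return TriClass.UNKNOWN
    return TriClass.BENIGN


def classify_maxent(wt: float, mut: float, cfg: ThresholdConfig | None = None) -> TriClass:
    """MaxEntScan call: score drop above 0.8 -> pathogenic, identical
    scores -> benign, anything else -> unknown."""
    cfg = cfg or ThresholdConfig()
    if wt - mut > cfg.maxent_diff:
        return TriClass.PATHOGENIC
    if wt == mut:
        return TriClass.BENIGN
    return TriClass.UNKNOWN


def classify_nnsplice(wt: float, mut: float, cfg: ThresholdConfig | None = None) -> TriClass:
    """NNSplice call (scores in [0, 1]): site lost across 0.5 -> pathogenic,
    drop above 0.05 -> unknown, else benign."""
    cfg = cfg or ThresholdConfig()
    for s in (wt, mut):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"NNSplice score {s} outside [0, 1]")
    if wt > cfg.nnsplice_site and mut < cfg.nnsplice_site:
        return TriClass.PATHOGENIC
    if wt - mut > cfg.nnsplice_diff:
        return TriClass.UNKNOWN
    return TriClass.BENIGN


def classify_conservation(phylop: float, cfg: ThresholdConfig | None = None) -> TriClass:
    """PhyloP (44-way) banding; boundary values fall in the unknown band."""
    cfg = cfg or ThresholdConfig()
    if phylop < cfg.phylop_benign_lt:
        return TriClass.BENIGN
    if phylop > cfg.phylop_patho_gt:
        return TriClass.PATHOGENIC
    return TriClass.UNKNOWN


def classify_frequency(
    exome_freq: float, disease_cohort_freq: float, cfg: ThresholdConfig | None = None
) -> TriClass:
    """Dual-cohort frequency banding.

    Benign above 3% in the reference exomes; unknown for an exome
    frequency between 1% and 3% (inclusive) or a disease-cohort frequency
    of 3% or more; pathogenic otherwise (rare in both cohorts).
    """
    cfg = cfg or ThresholdConfig()
    for f in (exome_freq, disease_cohort_freq):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"frequency {f} outside [0, 1]")
    if exome_freq > cfg.freq_benign_gt:
        return TriClass.BENIGN
    if cfg.freq_unknown_lo <= exome_freq <= cfg.freq_unknown_hi:
        return TriClass.UNKNOWN
    if disease_cohort_freq >= cfg.cohort_unknown_ge:
        return TriClass.UNKNOWN
    return TriClass.PATHOGENIC


def combine(insilico: TriClass, conservation: TriClass, frequency: TriClass) -> FinalClass:
    """Combine the three axis calls into the final verdict.

    A benign frequency axis forces probably-benign regardless of the other
    axes; otherwise a majority vote decides, with a three-way split (and a
    majority of unknown) mapping to unknown.
    """
    if frequency is TriClass.BENIGN:
        return FinalClass.PROBABLY_BENIGN
    majority = vote((insilico, conservation, frequency))
    return {
        TriClass.PATHOGENIC: FinalClass.PROBABLY_PATHOGENIC,
        TriClass.BENIGN: FinalClass.PROBABLY_BENIGN,
        TriClass.UNKNOWN: FinalClass.UNKNOWN,
    }[majority]


def _splice_vote(scores: dict[str, tuple[float, float]], cfg: ThresholdConfig) -> TriClass:
    calls = []
    for tool, fn in (("ssf", classify_ssf), ("maxent", classify_maxent), ("nnsplice", classify_nnsplice)):
        if tool not in scores:
            calls.append(TriClass.UNKNOWN)
        else:
            wt, mut = scores[tool]
            calls.append(fn(wt, mut, cfg))
    return vote(calls)


def classify_missense_scores(
    sift: Optional[float],
    polyphen: Optional[float],
    mutpred: Optional[float],
    sift_damaging_le: float = 0.05,
    polyphen_damaging_ge: float = 0.85,
    polyphen_benign_le: float = 0.15,
    mutpred_damaging_ge: float = 0.75,
    mutpred_benign_le: float = 0.25,
) -> tuple[TriClass, TriClass, TriClass]:
    """Optionally map raw missense tool scores to three-state calls.

    The pipeline normally consumes tool *classifications*; these score
    thresholds are implementation conveniences for users who only have raw
    scores (SIFT <= 0.05 damaging; PolyPhen / MutPred banded with an
    intermediate unknown zone). Missing scores map to unknown.
    """

    def band(score: Optional[float], hi: float, lo: float) -> TriClass:
        if score is None:
            return TriClass.UNKNOWN
        if score >= hi:
            return TriClass.PATHOGENIC
        if score <= lo:
            return TriClass.BENIGN
        return TriClass.UNKNOWN

    sift_call = (
        TriClass.UNKNOWN
        if sift is None
        else (TriClass.PATHOGENIC if sift <= sift_damaging_le else TriClass.BENIGN)
    )
    return (
        sift_call,
        band(polyphen, polyphen_damaging_ge, polyphen_benign_le),
        band(mutpred, mutpred_damaging_ge, mutpred_benign_le),
    )


def classify_variant(v: AnnotatedVariant, cfg: ThresholdConfig | None = None) -> FinalClass:
    """Classify one annotated variant.

    Truncating / canonical-splice / large-deletion -> pathogenic. Missense
    variants use the missense tool vote for the in-silico axis; noncanonical
    splice variants the splice tool vote. A variant that is both missense
    and near a splice site uses the missense vote. Variants with neither
    tool family (e.g. in-frame indels) carry an unknown in-silico axis.
    """
    cfg = cfg or ThresholdConfig()
    a = v.annot
    if a.effect in TRUNCATING_EFFECTS:
        return FinalClass.PATHOGENIC

    if a.effect is Effect.MISSENSE:
        if a.missense_calls is None:
            warnings.warn(f"{v.locus}: missense variant without tool calls; in-silico axis unknown")
            insilico = TriClass.UNKNOWN
        else:
            insilico = vote(a.missense_calls)
    elif a.effect in (Effect.SPLICE_REGION, Effect.INTRONIC) and a.splice_scores:
        insilico = _splice_vote(a.splice_scores, cfg)
    else:
        insilico = TriClass.UNKNOWN

    conservation = classify_conservation(a.phylop, cfg)
    frequency = classify_frequency(a.exome_cohort_freq, a.disease_cohort_freq, cfg)
    return combine(insilico, conservation, frequency)


def truth_table() -> list[tuple[TriClass, TriClass, TriClass, FinalClass]]:
    """The full 27-row combination table (for audit / ``--truth-table``)."""
    rows = []
    for i in TriClass:
        for c in TriClass:
            for f in TriClass:
                rows.append((i, c, f, combine(i, c, f)))
    return rows
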
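"""Per-sample diagnosis calls and cohort-level yield statistics.

The funnel arithmetic reproduces standard diagnostic-yield reporting
conventions: detection rate (individual known mutations recovered),
solved rate (probands diagnosed, integer percent), filtering reduction,
enrichment of true mutations among retained variants, Sanger-confirmation
accounting, and the cohort-extrapolation of diagnostic yield.

Rounding conventions are pinned per statistic: detection/reduction to one
decimal; solved/confirmation/projection as integer percent (round half
up); enrichment truncated toward zero at one decimal for values of 1% or
more, rounded to two decimals below 1% (so 20/48 -> 41.6 and
21/14,144 -> 0.15).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .prioritization import FunnelCounts
from .segregation import SegregationStatus, SegregationVerdict
from .types import AnnotatedVariant, FinalClass, InheritanceMode

__all__ = [
    "DiagnosisResult",
    "CohortSummary",
    "detection_rate",
    "solved_rate",
    "reduction_percent",
    "enrichment_percent",
    "projected_yield",
    "summarize_cohort",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class DiagnosisResult:
    """The diagnostic outcome for one proband."""

    sample_id: str
    solved: bool
    gene: Optional[str] = None
    variants: list[tuple[AnnotatedVariant, FinalClass]] = field(default_factory=list)
    mode: Optional[InheritanceMode] = None
    segregation: Optional[SegregationVerdict] = None
    de_novo: bool = False

    def __post_init__(self) -> None:
        if self.solved:
            if not any(fc.is_pathogenic_tier() for _, fc in self.variants):
                raise ValueError(f"{self.sample_id}: solved without pathogenic-tier variant")
            if (
                self.segregation is not None
                and self.segregation.status is SegregationStatus.CONTRADICTED
            ):
                raise ValueError(f"{self.sample_id}: solved with contradicted segregation")


@dataclass
class CohortSummary:
    n_samples: int
    funnel: FunnelCounts
    mean_auto_detected_per_sample: int
    mean_selected_per_sample: float
    solved_rate: int
    reduction: float
    detection_rate: Optional[float] = None
    enrichment_before: Optional[float] = None
    enrichment_after: Optional[float] = None
    confirmation_rate: Optional[int] = None
    projected_yield: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("solved_rate", "reduction", "detection_rate", "confirmation_rate", "projected_yield"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")


def detection_rate(n_detected: int, n_known: int) -> float:
    """Percent of known mutations recovered, to one decimal."""
    if n_known <= 0:
        raise ValueError("n_known must be positive")
    if not 0 <= n_detected <= n_known:
        raise ValueError("n_detected must lie in [0, n_known]")
    return round(100.0 * n_detected / n_known, 1)


def solved_rate(n_solved: int, n_samples: int) -> int:
    """Percent of probands with a molecular diagnosis, integer percent."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if not 0 <= n_solved <= n_samples:
        raise ValueError("n_solved must lie in [0, n_samples]")
    return _round_half_up(100.0 * n_solved / n_samples)


def reduction_percent(n_before: int, n_after: int) -> float:
    """Percent reduction of candidate variants through filtering, one decimal."""
    if n_before <= 0:
        raise ValueError("n_before must be positive")
    if n_after > n_before or n_after < 0:
        raise ValueError("n_after must lie in [0, n_before]")
    return round(100.0 * (1.0 - n_after / n_before), 1)


def enrichment_percent(n_true_retained: int, n_retained: int) -> float:
    """Percent of retained variants that are true disease mutations.

    Truncated toward zero at one decimal when >= 1%, rounded to two
    decimals below 1%.
    """
    if n_retained <= 0:
        raise ValueError("n_retained must be positive")
    if not 0 <= n_true_retained <= n_retained:
        raise ValueError("n_true_retained must lie in [0, n_retained]")
    pct = 100.0 * n_true_retained / n_retained
    if pct < 1.0:
        return round(pct, 2)
    return math.floor(pct * 10.0) / 10.0


def projected_yield(
    n_prev_solved: int,
    prev_rate: float,
    n_ngs_solved: int,
    n_untested: int,
    ngs_rate: float,
    n_total: int,
) -> int:
    """Extrapolated diagnostic yield for an unscreened cohort.

    Combines the previously solved cases scaled by the validation solved
    rate, the NGS-diagnosed cases, and the untested cases scaled by the
    NGS diagnosis rate; intermediate terms are rounded to whole patients
    and the result is an integer percent.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    for r in (prev_rate, ngs_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate {r} outside [0, 1]")
    term_prev = _round_half_up(n_prev_solved * prev_rate)
    term_untested = _round_half_up(n_untested * ngs_rate)
    return _round_half_up(100.0 * (term_prev + n_ngs_solved + term_untested) / n_total)


def summarize_cohort(
    funnels: Sequence[FunnelCounts],
    diagnoses: Sequence[DiagnosisResult],
    confirmed_flags: Optional[Sequence[bool]] = None,
    n_known_mutations: Optional[int] = None,
    n_detected_known: Optional[int] = None,
    n_true_before: Optional[int] = None,
    n_true_after: Optional[int] = None,
    projection: Optional[dict] = None,
) -> CohortSummary:
    """Aggregate per-sample funnels and diagnoses into cohort statistics.

    ``confirmed_flags`` carries one Sanger-confirmation flag per selected
    variant; ``n_true_before`` / ``n_true_after`` are the known-mutation
    counts before filtering and after (they are carried separately because
    filtering may eliminate a true mutation); ``projection`` holds the
    keyword arguments of :func:`projected_yield`.
    """
    if not funnels:
        raise ValueError("empty cohort")
    total = funnels[0]
    for f in funnels[1:]:
        total = total + f
    n = len(funnels)
    n_solved = sum(1 for d in diagnoses if d.solved)

    confirmation = None
    if confirmed_flags is not None and len(confirmed_flags) > 0:
        confirmation = _round_half_up(100.0 * sum(confirmed_flags) / len(confirmed_flags))

    det = None
    if n_known_mutations is not None and n_detected_known is not None:
        det = detection_rate(n_detected_known, n_known_mutations)

    enr_before = enr_after = None
    if n_true_before is not None:
        enr_before = enrichment_percent(n_true_before, total.n_auto_detected)
    if n_true_after is not None:
        enr_after = enrichment_percent(n_true_after, total.n_selected)

    proj = projected_yield(**projection) if projection else None

    return CohortSummary(
        n_samples=n,
        funnel=total,
        mean_auto_detected_per_sample=_round_half_up(total.n_auto_detected / n),
        mean_selected_per_sample=round(total.n_selected / n, 1),
        solved_rate=solved_rate(n_solved, n),
        reduction=reduction_percent(total.n_auto_detected, total.n_selected)
        if total.n_auto_detected
        else 0.0,
        detection_rate=det,
        enrichment_before=enr_before,
        enrichment_after=enr_after,
        confirmation_rate=confirmation,
        projected_yield=proj,
    )
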
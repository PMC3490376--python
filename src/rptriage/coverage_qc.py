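"""Coverage quality control for target-capture sequencing.

Per-target and per-sample statistics over per-base depth tracks: median
target coverage, fraction of bases covered at least k-fold, the evenness
score of Mokry-style cumulative coverage, poor-target flagging, and
near-target base accounting (bases mapped within a window around a target
but outside every target).

The evenness score summarises how uniformly coverage is distributed:

    E = 100 / ceil(m) * sum_{i=1..ceil(m)} P(depth >= i)

with m the mean depth over all target bases and P the empirical fraction
of bases at depth >= i. Perfectly uniform coverage scores 100; any
non-uniform profile scores strictly less.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .config import ThresholdConfig
from .types import TargetRegion

__all__ = [
    "DepthTrack",
    "CoverageReport",
    "target_median_coverage",
    "fraction_bases_at_least",
    "evenness_score",
    "flag_poor_targets",
    "near_target_bases",
    "coverage_report",
]


@dataclass(frozen=True)
class DepthTrack:
    """Per-base coverage over one capture target."""

    region_id: str
    depths: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.depths):
            raise ValueError(f"track {self.region_id}: negative depth")

    @classmethod
    def from_list(cls, region_id: str, depths: Sequence[int]) -> "DepthTrack":
        return cls(region_id=region_id, depths=tuple(int(d) for d in depths))


@dataclass
class CoverageReport:
    per_target_median: dict[str, float]
    mean_coverage: float
    frac_ge_10x: float
    evenness: float
    poor_targets: list[str]
    near_target_bases: Optional[int] = None
    mean_of_target_medians: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_ge_10x <= 1.0:
            raise ValueError("frac_ge_10x outside [0, 1]")
        if not 0.0 <= self.evenness <= 100.0 + 1e-9:
            raise ValueError("evenness outside [0, 100]")


def target_median_coverage(track: DepthTrack) -> float:
    """Median per-base depth of one target (mean of central pair when even)."""
    if not track.depths:
        raise ValueError(f"track {track.region_id}: empty depth track")
    return float(np.median(track.depths))


def _all_depths(tracks: Iterable[DepthTrack]) -> np.ndarray:
    arrays = [np.asarray(t.depths) for t in tracks]
    if not arrays:
        raise ValueError("no depth tracks supplied")
    return np.concatenate(arrays)


def fraction_bases_at_least(tracks: Iterable[DepthTrack], k: int) -> float:
    """Fraction of all target bases covered at depth >= k."""
    if k < 0:
        raise ValueError("k must be >= 0")
    depths = _all_depths(tracks)
    return float(np.mean(depths >= k))


def evenness_score(tracks: Iterable[DepthTrack]) -> float:
    """Evenness of coverage in percent (100 = perfectly uniform)."""
    depths = _all_depths(tracks)
    m = depths.mean()
    if m <= 0:
        raise ValueError("evenness undefined for all-zero coverage")
    ceil_m = math.ceil(m)
    # P(depth >= i) for i = 1..ceil(m), computed from one histogram pass
    capped = np.minimum(depths, ceil_m)
    counts = np.bincount(capped, minlength=ceil_m + 1)
    ge = depths.size - np.cumsum(counts)[:-1]  # ge[i-1] = #bases with depth >= i
    return float(100.0 * ge.sum() / (ceil_m * depths.size))


def flag_poor_targets(
    per_target_median: Mapping[str, float], cfg: ThresholdConfig | None = None
) -> list[str]:
    """Region ids whose median coverage falls below the poor-target cutoff."""
    cfg = cfg or ThresholdConfig()
    return sorted(
        rid for rid, med in per_target_median.items() if med < cfg.poor_target_median_lt
    )


def near_target_bases(
    read_intervals: Iterable[tuple[str, int, int]],
    targets: Sequence[TargetRegion],
    cfg: ThresholdConfig | None = None,
) -> int:
    """Count read bases mapped within the near-target window of a target.

    A base is near-target when it lies within ``near_target_bp`` of some
    target but inside no target. ``read_intervals`` are (chrom, start, end)
    half-open read placements.
    """
    cfg = cfg or ThresholdConfig()
    flank: dict[str, IntervalTree] = {}
    on_target: dict[str, IntervalTree] = {}
    for t in targets:
        flank.setdefault(t.chrom, IntervalTree()).addi(
            max(0, t.start - cfg.near_target_bp), t.end + cfg.near_target_bp
        )
        on_target.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end)
    for tree in (*flank.values(), *on_target.values()):
        tree.merge_overlaps()

    def _overlap(tree: Optional[IntervalTree], start: int, end: int) -> int:
        if tree is None:
            return 0
        return sum(min(iv.end, end) - max(iv.begin, start) for iv in tree.overlap(start, end))

    total = 0
    for chrom, start, end in read_intervals:
        total += _overlap(flank.get(chrom), start, end) - _overlap(
            on_target.get(chrom), start, end
        )
    return total


def coverage_report(
    tracks: Sequence[DepthTrack],
    cfg: ThresholdConfig | None = None,
    read_intervals: Optional[Iterable[tuple[str, int, int]]] = None,
    targets: Optional[Sequence[TargetRegion]] = None,
) -> CoverageReport:
    """Full per-sample coverage report.

    Both the mean of per-target medians and the overall per-base mean are
    reported, since "average coverage per exon" can be read either way.
    Near-target accounting is included only when read placements are given;
    depth tracks alone cannot distinguish near-target bases.
    """
    cfg = cfg or ThresholdConfig()
    medians = {t.region_id: target_median_coverage(t) for t in tracks}
    depths = _all_depths(tracks)
    near = None
    if read_intervals is not None and targets is not None:
        near = near_target_bases(read_intervals, targets, cfg)
    return CoverageReport(
        per_target_median=medians,
        mean_coverage=float(depths.mean()),
        frac_ge_10x=fraction_bases_at_least(tracks, 10),
        evenness=evenness_score(tracks),
        poor_targets=flag_poor_targets(medians, cfg),
        near_target_bases=near,
        mean_of_target_medians=float(np.mean(list(medians.values()))),
    )
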
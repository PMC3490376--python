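"""Threshold configuration.

Every constant used by a filter or classifier lives here, with the default
equal to the published cutoff it implements (e.g. the 8 bp acceptor /
20 bp donor splice windows, the 5% exome and 15% disease-cohort frequency
bounds, the PhyloP 1.0 / 2.5 conservation bands). Users can override any
value through a YAML file passed to the CLI or to ``ThresholdConfig.from_yaml``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["ThresholdConfig"]


@dataclass(frozen=True)
class ThresholdConfig:
    # prioritization: effect filter splice windows (bp from the exon
    # boundary on the intronic side)
    splice_acceptor_window: int = 8
    splice_donor_window: int = 20
    # prioritization: frequency filters (strict "greater than" exclusion)
    exome_filter_max: float = 0.05
    cohort_filter_max: float = 0.15
    # prioritization: read-support filter, two alternative branches
    support_reads_a: int = 10
    support_frac_a: float = 0.20
    support_reads_b: int = 5
    support_frac_b_lo: float = 0.80
    # high-quality difference designation
    hq_rule1_reads: int = 3
    hq_rule2_reads: int = 5
    hq_rule2_qual: int = 20
    # classification: conservation bands (PhyloP, 44-way)
    phylop_benign_lt: float = 1.0
    phylop_patho_gt: float = 2.5
    # classification: frequency bands
    freq_benign_gt: float = 0.03
    freq_unknown_lo: float = 0.01
    freq_unknown_hi: float = 0.03
    cohort_unknown_ge: float = 0.03
    # classification: splice-tool cutoffs
    ssf_site: float = 50.0
    ssf_diff: float = 5.0
    maxent_diff: float = 0.8
    nnsplice_site: float = 0.5
    nnsplice_diff: float = 0.05
    # coverage QC
    poor_target_median_lt: float = 5.0
    near_target_bp: int = 500

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise TypeError(f"{f.name} must be numeric, got {v!r}")
        count_fields = (
            "splice_acceptor_window",
            "splice_donor_window",
            "support_reads_a",
            "support_reads_b",
            "hq_rule1_reads",
            "hq_rule2_reads",
            "near_target_bp",
        )
        for name in count_fields:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        """Load a config from YAML; keys not present keep their defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
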
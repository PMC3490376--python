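"""Deterministic, seeded generator of synthetic gene-panel cohorts.

The generator emulates every input the pipeline consumes — gene panel,
capture targets, per-base depth, pedigrees, marker genotypes, and fully
annotated per-sample variant tables — with causal genotypes planted under
recessive (homozygous and compound-heterozygous), dominant (inherited and
de novo), and X-linked scenarios, next to a majority of unsolved samples.

Defaults mirror the published study conditions: 111 panel genes over
2,011 capture targets of 250 bp, ~26x mean coverage with 15 poorly
covered targets, an average of 1,274 background variants per sample, and
a 100-sample cohort resolving into 27 recessive, 3 X-linked and 6
dominant diagnoses (3 of them de novo) with 64 samples unsolved.

Background variants are drawn from explicit annotation strata (dbSNP
membership, frequency bands, conservation, tool calls) and are non-causal
by construction: any draw that would classify pathogenic-tier is redrawn,
so that the funnel reduction is the emergent consequence of the filters
while unsolved samples can never produce a false diagnosis. Planted
causal variants are asserted post-generation to pass all six
prioritization criteria and classify pathogenic-tier.

All randomness flows from one seed; per-sample substreams are derived by
stable hashing of sample ids, so outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import panel_io
from .classification import classify_variant
from .config import ThresholdConfig
from .prioritization import (
    is_high_quality,
    passes_effect_filter,
    passes_frequency_filters,
    passes_novelty_filter,
    passes_support_filter,
)
from .types import (
    AnnotatedVariant,
    AnnotationBundle,
    Effect,
    Family,
    FinalClass,
    Genotype,
    GenePanelEntry,
    InheritanceMode,
    MarkerGenotype,
    PedigreeMember,
    ReadSupport,
    TargetRegion,
    TriClass,
    VariantLocus,
    Zygosity,
)

__all__ = [
    "SimulationConfig",
    "PlantedVariant",
    "TruthRecord",
    "simulate_cohort",
    "plant_de_novo",
    "degrade_targets",
    "validation_fixture_config",
    "read_truth",
]

_SCENARIOS = ("AR_hom", "AR_compound_het", "AD_inherited", "AD_de_novo", "XL", "unsolved")

_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_samples: int = 100
    n_genes: int = 111
    n_targets: int = 2011
    target_length: int = 250
    mean_background_variants: float = 1274.0
    # fraction of background calls present in dbSNP130: targeted capture at
    # ~26x overwhelmingly re-discovers known polymorphisms, which is what
    # lets the novelty criterion remove >99% of calls
    fraction_dbsnp: float = 0.96
    fraction_false_indels: float = 0.21
    poor_target_count: int = 15
    scenario_mix: dict = field(
        default_factory=lambda: {
            "AR_hom": 0.13,
            "AR_compound_het": 0.14,
            "AD_inherited": 0.03,
            "AD_de_novo": 0.03,
            "XL": 0.03,
            "unsolved": 0.64,
        }
    )
    de_novo_marker_count: int = 16
    mean_depth: float = 26.0
    n_multilocus: int = 1
    # validation-fixture planting of undetectable mutations: degraded pairs
    # fall in one sample's zero-coverage target, low-support singles in
    # further samples
    undetectable_degraded: int = 0
    undetectable_low_support: int = 0
    emit_depth: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.scenario_mix.values()) - 1.0) > 1e-9:
            raise ValueError("scenario_mix proportions must sum to 1")
        unknown = set(self.scenario_mix) - set(_SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")
        for name in ("n_samples", "n_genes", "n_targets", "target_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.poor_target_count > self.n_targets:
            raise ValueError("poor_target_count exceeds n_targets")


@dataclass
class PlantedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    zygosity: str
    effect: str
    intended_class: str
    de_novo: bool = False
    detectable: bool = True
    drop_reason: Optional[str] = None  # "degraded_target" | "low_support"

    def locus(self) -> VariantLocus:
        return VariantLocus(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TruthRecord:
    sample_id: str
    family_id: str
    scenario: str
    gene: Optional[str]
    mode: Optional[str]
    planted: list[PlantedVariant] = field(default_factory=list)
    expected_solved: bool = False
    multilocus_genes: list[str] = field(default_factory=list)
    n_background: int = 0
    n_background_confirmed: int = 0


def validation_fixture_config(seed: int = 0) -> SimulationConfig:
    """The 12-sample validation preset: every sample carries a planted
    compound-heterozygous pair (24 known mutations), with three mutations
    rendered undetectable — two by a zero-coverage high-GC target (both in
    one sample) and one by sub-threshold read support (another sample)."""
    return SimulationConfig(
        seed=seed,
        n_samples=12,
        scenario_mix={"AR_compound_het": 1.0},
        n_multilocus=0,
        undetectable_degraded=2,
        undetectable_low_support=1,
    )


# ---------------------------------------------------------------------------
# panel / target scaffolding
# ---------------------------------------------------------------------------

def _build_panel(cfg: SimulationConfig, rng: np.random.Generator) -> list[GenePanelEntry]:
    n_xl = max(3, round(0.05 * cfg.n_genes))
    entries = []
    for i in range(cfg.n_genes):
        gene = f"GENE{i + 1:03d}"
        if i < n_xl:
            entries.append(GenePanelEntry(gene, "chrX", frozenset({InheritanceMode.XL})))
            continue
        chrom = _AUTOSOMES[i % len(_AUTOSOMES)]
        u = rng.random()
        if u < 0.70:
            modes = frozenset({InheritanceMode.AR})
        elif u < 0.90:
            modes = frozenset({InheritanceMode.AR, InheritanceMode.AD})
        else:
            modes = frozenset({InheritanceMode.AD})
        entries.append(GenePanelEntry(gene, chrom, modes))
    return entries


def _build_targets(cfg: SimulationConfig, panel: Sequence[GenePanelEntry]) -> list[TargetRegion]:
    targets = []
    per_gene: dict[str, int] = {e.gene: 0 for e in panel}
    gene_base = {e.gene: 1_000_000 * (i + 1) for i, e in enumerate(panel)}
    for t in range(cfg.n_targets):
        entry = panel[t % len(panel)]
        j = per_gene[entry.gene]
        per_gene[entry.gene] += 1
        start = gene_base[entry.gene] + j * (cfg.target_length + 1000)
        targets.append(
            TargetRegion(
                chrom=entry.chrom,
                start=start,
                end=start + cfg.target_length,
                gene=entry.gene,
                region_id=f"{entry.gene}_t{j}",
            )
        )
    return targets


def degrade_targets(
    tracks: dict[str, np.ndarray],
    region_ids: Sequence[str],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Force the designated targets' per-base depths below the poor-median
    threshold (near-zero coverage, as for a high-GC or repeat-rich exon)."""
    out = dict(tracks)
    for rid in region_ids:
        if rid not in out:
            raise KeyError(f"unknown target {rid}")
        out[rid] = rng.poisson(0.8, size=len(out[rid])).astype(np.int64)
    return out


def _sample_depth_tracks(
    cfg: SimulationConfig,
    targets: Sequence[TargetRegion],
    poor_ids: Sequence[str],
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Per-base depth per target plus per-target mean used for read support."""
    tracks: dict[str, np.ndarray] = {}
    means: dict[str, float] = {}
    # per-target capture efficiency: gamma around the sample mean depth,
    # floored away from the poor-target cutoff so only designated targets
    # flag as poor
    for t in targets:
        mean = max(8.0, rng.gamma(12.0, cfg.mean_depth / 12.0))
        means[t.region_id] = mean
        tracks[t.region_id] = rng.poisson(mean, size=t.length).astype(np.int64)
    tracks = degrade_targets(tracks, poor_ids, rng)
    for rid in poor_ids:
        means[rid] = 0.8
    return tracks, means


# ---------------------------------------------------------------------------
# annotation strata
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _random_snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _background_effect(rng: np.random.Generator) -> Effect:
    r = rng.random()
    if r < 0.28:
        return Effect.SYNONYMOUS
    if r < 0.58:
        return Effect.INTRONIC
    if r < 0.73:
        return Effect.UTR
    if r < 0.88:
        return Effect.MISSENSE
    if r < 0.93:
        return Effect.SPLICE_REGION
    if r < 0.95:
        return Effect.INFRAME_INDEL
    if r < 0.98:
        return Effect.FRAMESHIFT
    return Effect.NONSENSE


def _background_annotation(rng: np.random.Generator, cfg: SimulationConfig) -> AnnotationBundle:
    """One draw from the non-causal background strata (no pathogenic-tier
    guarantee yet; the caller rejection-samples)."""
    effect = _background_effect(rng)
    truncating = effect in (Effect.NONSENSE, Effect.FRAMESHIFT)
    # truncating background calls are common annotation artifacts: always
    # known dbSNP entries without disease-database flags
    in_dbsnp = True if truncating else bool(rng.random() < cfg.fraction_dbsnp)

    if in_dbsnp:
        exome_freq = float(np.clip(rng.beta(0.8, 3.0), 0.0, 0.95))
        cohort_freq = float(np.clip(exome_freq * rng.uniform(0.5, 1.5), 0.0, 0.95))
    else:
        exome_freq = float(rng.choice([0.0, 0.0, 0.0, 0.012], p=[0.6, 0.2, 0.1, 0.1]))
        cohort_freq = float(rng.choice([0.01, 0.02, 0.04], p=[0.7, 0.2, 0.1]))

    phylop = float(rng.normal(0.3, 1.1))
    if effect is Effect.MISSENSE:
        phylop = float(rng.normal(0.8, 1.2))

    acc_off = don_off = None
    if effect is Effect.INTRONIC:
        if rng.random() < 0.5:
            acc_off = -int(rng.integers(25, 500))
        else:
            don_off = int(rng.integers(30, 500))
    elif effect is Effect.SPLICE_REGION:
        if rng.random() < 0.5:
            acc_off = -int(rng.integers(3, 30))
        else:
            don_off = int(rng.integers(3, 30))

    missense_calls = None
    if effect is Effect.MISSENSE:
        missense_calls = tuple(
            TriClass(
                str(
                    rng.choice(
                        [TriClass.PATHOGENIC.value, TriClass.UNKNOWN.value, TriClass.BENIGN.value],
                        p=[0.1, 0.3, 0.6],
                    )
                )
            )
            for _ in range(3)
        )

    splice_scores = None
    if effect is Effect.SPLICE_REGION or (
        effect is Effect.INTRONIC and (acc_off is not None and acc_off >= -30 or don_off is not None and don_off <= 40)
    ):
        wt = float(rng.uniform(40, 95))
        splice_scores = {
            "ssf": (wt, wt - float(rng.uniform(-2, 4))),
            "maxent": (8.0, 8.0 - float(rng.uniform(0, 0.6))),
            "nnsplice": (0.8, float(np.clip(0.8 - rng.uniform(0, 0.04), 0, 1))),
        }

    return AnnotationBundle(
        effect=effect,
        in_dbsnp130=in_dbsnp,
        in_hgmd=False,
        known_blindness_mutation=False,
        exome_cohort_freq=exome_freq,
        disease_cohort_freq=cohort_freq,
        phylop=phylop,
        splice_acceptor_offset=acc_off,
        splice_donor_offset=don_off,
        missense_calls=missense_calls,
        splice_scores=splice_scores,
    )


def _benign_fallback(effect: Effect, annot: AnnotationBundle) -> AnnotationBundle:
    """Deterministically non-pathogenic version of a background draw."""
    return AnnotationBundle(
        effect=Effect.SYNONYMOUS,
        in_dbsnp130=True,
        exome_cohort_freq=0.1,
        disease_cohort_freq=0.1,
        phylop=0.0,
    )


def _good_support(
    rng: np.random.Generator, zygosity: Zygosity, site_mean: float
) -> ReadSupport:
    total = int(max(10, rng.poisson(max(site_mean, 12.0))))
    if zygosity is Zygosity.HET:
        variant = int(rng.binomial(total, 0.5))
        variant = max(variant, max(3, -(-total // 4)))  # keep fraction comfortably >= 25%
        variant = min(variant, total)
    else:
        variant = total
    fwd = max(1, variant // 2)
    rev = variant - fwd
    if rev == 0:
        fwd, rev = variant - 1, 1
    return ReadSupport(
        total_reads=total,
        variant_reads=variant,
        nonduplicate_variant_reads=variant,
        forward_variant_reads=fwd,
        reverse_variant_reads=rev,
        hq_variant_reads=variant,
    )


def _background_support(
    rng: np.random.Generator, zygosity: Zygosity, site_mean: float
) -> ReadSupport:
    total = int(rng.poisson(max(site_mean, 4.0)))
    total = max(total, 1)
    if zygosity is Zygosity.HET:
        variant = int(rng.binomial(total, 0.45))
        variant = max(1, variant)
    else:
        variant = max(1, int(rng.binomial(total, 0.95)))
    variant = min(variant, total)
    nondup = variant - int(rng.binomial(variant, 0.05))
    fwd = int(rng.binomial(variant, 0.5))
    rev = variant - fwd
    hq = int(rng.binomial(variant, 0.85))
    return ReadSupport(
        total_reads=total,
        variant_reads=variant,
        nonduplicate_variant_reads=nondup,
        forward_variant_reads=fwd,
        reverse_variant_reads=rev,
        hq_variant_reads=hq,
    )


_LOW_SUPPORT = ReadSupport(
    total_reads=4,
    variant_reads=2,
    nonduplicate_variant_reads=2,
    forward_variant_reads=2,
    reverse_variant_reads=0,
    hq_variant_reads=2,
)


# ---------------------------------------------------------------------------
# causal planting
# ---------------------------------------------------------------------------

_CAUSAL_EFFECTS = (
    (Effect.NONSENSE, 0.30),
    (Effect.FRAMESHIFT, 0.20),
    (Effect.CANONICAL_SPLICE, 0.15),
    (Effect.MISSENSE, 0.35),
)


def _causal_annotation(rng: np.random.Generator, effect: Effect) -> AnnotationBundle:
    """Annotation for a planted causal allele: rare in both cohorts,
    conserved, and (for missense) supported by the prediction tools."""
    known = bool(rng.random() < 0.3)
    kwargs = dict(
        effect=effect,
        in_dbsnp130=known,
        in_hgmd=known,
        known_blindness_mutation=known,
        exome_cohort_freq=0.0,
        disease_cohort_freq=0.01,
        phylop=float(rng.uniform(2.8, 6.0)),
    )
    if effect is Effect.MISSENSE:
        kwargs["missense_calls"] = (
            TriClass.PATHOGENIC,
            TriClass.PATHOGENIC,
            TriClass.PATHOGENIC if rng.random() < 0.5 else TriClass.UNKNOWN,
        )
    if effect is Effect.CANONICAL_SPLICE:
        kwargs["splice_donor_offset"] = int(rng.choice([1, 2]))
    return AnnotationBundle(**kwargs)


def _pick_causal_effect(rng: np.random.Generator) -> Effect:
    effects, weights = zip(*_CAUSAL_EFFECTS)
    return effects[rng.choice(len(effects), p=np.array(weights) / sum(weights))]


def _pick_locus(
    rng: np.random.Generator,
    gene: str,
    targets_by_gene: dict[str, list[TargetRegion]],
    used: set,
    avoid_ids: set[str] = frozenset(),
    force_target: Optional[TargetRegion] = None,
) -> VariantLocus:
    for _ in range(200):
        if force_target is not None:
            t = force_target
        else:
            choices = [t for t in targets_by_gene[gene] if t.region_id not in avoid_ids]
            t = choices[rng.integers(len(choices))]
        pos = int(t.start + 1 + rng.integers(t.length))
        ref, alt = _random_snv(rng)
        locus = VariantLocus(t.chrom, pos, ref, alt)
        if locus.key() not in used:
            used.add(locus.key())
            return locus
    raise RuntimeError("could not place a unique locus")


def plant_de_novo(
    family: Family,
    gene_entry: GenePanelEntry,
    targets_by_gene: dict[str, list[TargetRegion]],
    rng: np.random.Generator,
    used: set,
    mode: InheritanceMode = InheritanceMode.AD,
    marker_count: int = 16,
    avoid_ids: set[str] = frozenset(),
) -> tuple[list[PlantedVariant], dict[str, dict[VariantLocus, Genotype]], dict[str, list[MarkerGenotype]]]:
    """Plant a de novo event in a trio.

    Dominant mode: the child carries a single de novo heterozygous
    truncating allele, both parents reference. Recessive mode: the child
    is compound heterozygous, one allele maternal and one de novo. A fully
    Mendelian-consistent marker set over the trio is generated alongside
    (the paternity evidence). Raises when the family is not a full trio.
    """
    proband = family.proband
    if proband is None:
        raise ValueError("family has no affected proband")
    father, mother = family.parents_of(proband.individual_id)
    if father is None or mother is None:
        raise ValueError("de novo planting requires a full trio")

    genotypes: dict[str, dict[VariantLocus, Genotype]] = {
        m: {} for m in family.members
    }
    planted: list[PlantedVariant] = []

    def _add(locus: VariantLocus, effect: Effect, child_gt: Genotype,
             father_gt: Genotype, mother_gt: Genotype, de_novo: bool) -> None:
        genotypes[proband.individual_id][locus] = child_gt
        genotypes[father.individual_id][locus] = father_gt
        genotypes[mother.individual_id][locus] = mother_gt
        zyg = {"het": "het", "hom_alt": "hom", "hemi_alt": "hemi"}[child_gt.value]
        planted.append(
            PlantedVariant(
                chrom=locus.chrom,
                pos=locus.pos,
                ref=locus.ref,
                alt=locus.alt,
                gene=gene_entry.gene,
                zygosity=zyg,
                effect=effect.value,
                intended_class=(
                    FinalClass.PATHOGENIC.value
                    if effect in (Effect.NONSENSE, Effect.FRAMESHIFT, Effect.CANONICAL_SPLICE)
                    else FinalClass.PROBABLY_PATHOGENIC.value
                ),
                de_novo=de_novo,
            )
        )

    if mode is InheritanceMode.AD:
        locus = _pick_locus(rng, gene_entry.gene, targets_by_gene, used, avoid_ids=avoid_ids)
        _add(locus, Effect.NONSENSE, Genotype.HET, Genotype.REF_REF, Genotype.REF_REF, True)
    elif mode is InheritanceMode.AR:
        l1 = _pick_locus(rng, gene_entry.gene, targets_by_gene, used, avoid_ids=avoid_ids)
        l2 = _pick_locus(rng, gene_entry.gene, targets_by_gene, used, avoid_ids=avoid_ids)
        _add(l1, _pick_causal_effect(rng), Genotype.HET, Genotype.REF_REF, Genotype.HET, False)
        _add(l2, _pick_causal_effect(rng), Genotype.HET, Genotype.REF_REF, Genotype.REF_REF, True)
    else:
        raise ValueError(f"de novo planting not defined for mode {mode}")

    markers: dict[str, list[MarkerGenotype]] = {m: [] for m in (proband.individual_id, father.individual_id, mother.individual_id)}
    for k in range(marker_count):
        mid = f"MK{k + 1:02d}"
        pool = [f"a{j}" for j in range(1, 9)]
        fa = list(rng.choice(pool, size=2, replace=True))
        mo = list(rng.choice(pool, size=2, replace=True))
        child = [fa[rng.integers(2)], mo[rng.integers(2)]]
        markers[father.individual_id].append(MarkerGenotype(mid, *fa))
        markers[mother.individual_id].append(MarkerGenotype(mid, *mo))
        markers[proband.individual_id].append(MarkerGenotype(mid, *child))
    return planted, genotypes, markers


# ---------------------------------------------------------------------------
# the cohort simulator
# ---------------------------------------------------------------------------

def _scenario_counts(cfg: SimulationConfig) -> list[str]:
    """Deterministic largest-remainder allocation of scenarios to samples."""
    props = [(s, cfg.scenario_mix.get(s, 0.0)) for s in _SCENARIOS]
    raw = [(s, p * cfg.n_samples) for s, p in props]
    counts = {s: int(x) for s, x in raw}
    short = cfg.n_samples - sum(counts.values())
    remainders = sorted(raw, key=lambda sx: -(sx[1] - int(sx[1])))
    for s, _ in remainders[:short]:
        counts[s] += 1
    out = []
    for s in _SCENARIOS:
        out.extend([s] * counts[s])
    return out


def _sample_rng(cfg: SimulationConfig, sample_id: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, zlib.crc32(sample_id.encode())])


def _genes_for(panel: Sequence[GenePanelEntry], mode: InheritanceMode) -> list[GenePanelEntry]:
    return [e for e in panel if mode in e.modes]


def simulate_cohort(cfg: SimulationConfig, out_dir: str | Path) -> list[TruthRecord]:
    """Generate a full synthetic cohort on disk.

    Emits ``panel.tsv``, ``targets.bed``, ``cohort.ped``,
    ``relative_genotypes.tsv``, ``markers.tsv``, ``truth.json`` and, per
    sample, ``<sid>.vcf``, ``<sid>.support.tsv``, ``<sid>.annot.tsv`` and
    (when ``emit_depth``) ``<sid>.depth.tsv``. Returns the truth records.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 0xC0FFEE])
    thresholds = ThresholdConfig()

    panel = _build_panel(cfg, rng)
    panel_by_gene = {e.gene: e for e in panel}
    targets = _build_targets(cfg, panel)
    targets_by_gene: dict[str, list[TargetRegion]] = {}
    for t in targets:
        targets_by_gene.setdefault(t.gene, []).append(t)
    target_by_id = {t.region_id: t for t in targets}

    poor_idx = rng.choice(cfg.n_targets, size=cfg.poor_target_count, replace=False)
    poor_ids = sorted(targets[i].region_id for i in poor_idx)
    if cfg.undetectable_degraded > 0:
        # the zero-coverage target that swallows a planted compound-het
        # pair must sit in a recessive-capable autosomal gene
        def _ar_autosomal(rid: str) -> bool:
            t = target_by_id[rid]
            return t.chrom != "chrX" and InheritanceMode.AR in panel_by_gene[t.gene].modes

        if not any(_ar_autosomal(r) for r in poor_ids):
            replacement = next(
                t.region_id
                for t in targets
                if t.chrom != "chrX"
                and InheritanceMode.AR in panel_by_gene[t.gene].modes
                and t.region_id not in poor_ids
            )
            poor_ids[-1] = replacement
        poor_ids.sort(key=lambda r: (not _ar_autosomal(r), r))
    poor_id_set = set(poor_ids)

    panel_io.write_panel(panel, out_dir / "panel.tsv")
    panel_io.write_targets(targets, out_dir / "targets.bed")

    scenarios = _scenario_counts(cfg)
    ar_genes = [e for e in _genes_for(panel, InheritanceMode.AR) if e.chrom != "chrX"]
    ad_genes = [e for e in _genes_for(panel, InheritanceMode.AD) if e.chrom != "chrX"]
    xl_genes = _genes_for(panel, InheritanceMode.XL)
    ad_only = [e for e in ad_genes if InheritanceMode.AR not in e.modes] or ad_genes

    families: dict[str, Family] = {}
    all_genotypes: dict[tuple[str, str], dict[VariantLocus, Genotype]] = {}
    all_markers: dict[tuple[str, str], list[MarkerGenotype]] = {}
    truth: list[TruthRecord] = []
    multilocus_left = cfg.n_multilocus
    degraded_left = cfg.undetectable_degraded
    low_support_left = cfg.undetectable_low_support

    for i, scenario in enumerate(scenarios):
        sid = f"S{i + 1:03d}"
        fid = f"F{i + 1:03d}"
        srng = _sample_rng(cfg, sid)
        proband_sex = "male" if scenario == "XL" or srng.random() < 0.5 else "female"

        fam = Family(family_id=fid)
        father = PedigreeMember(f"{sid}-F", fid, "male", False)
        mother = PedigreeMember(f"{sid}-M", fid, "female", False)
        proband = PedigreeMember(
            sid, fid, proband_sex, True, father_id=father.individual_id, mother_id=mother.individual_id
        )
        for m in (father, mother, proband):
            fam.add(m)
        families[fid] = fam

        used: set = set()
        planted: list[PlantedVariant] = []
        genotypes: dict[str, dict[VariantLocus, Genotype]] = {m: {} for m in fam.members}
        record = TruthRecord(sample_id=sid, family_id=fid, scenario=scenario, gene=None, mode=None)

        if scenario == "AR_hom":
            entry = ar_genes[srng.integers(len(ar_genes))]
            locus = _pick_locus(srng, entry.gene, targets_by_gene, used,
                                avoid_ids=poor_id_set)
            effect = _pick_causal_effect(srng)
            planted.append(
                PlantedVariant(locus.chrom, locus.pos, locus.ref, locus.alt, entry.gene,
                               "hom", effect.value,
                               FinalClass.PATHOGENIC.value
                               if effect is not Effect.MISSENSE
                               else FinalClass.PROBABLY_PATHOGENIC.value)
            )
            genotypes[sid][locus] = Genotype.HOM_ALT
            genotypes[father.individual_id][locus] = Genotype.HET
            genotypes[mother.individual_id][locus] = Genotype.HET
            record.gene, record.mode, record.expected_solved = entry.gene, "AR", True
            if multilocus_left > 0:
                # cumulative mutational load: an additional known dominant
                # missense in a second gene
                entry2 = ad_only[srng.integers(len(ad_only))]
                locus2 = _pick_locus(srng, entry2.gene, targets_by_gene, used,
                                     avoid_ids=poor_id_set)
                planted.append(
                    PlantedVariant(locus2.chrom, locus2.pos, locus2.ref, locus2.alt,
                                   entry2.gene, "het", Effect.MISSENSE.value,
                                   FinalClass.PROBABLY_PATHOGENIC.value)
                )
                genotypes[sid][locus2] = Genotype.HET
                genotypes[father.individual_id][locus2] = Genotype.REF_REF
                genotypes[mother.individual_id][locus2] = Genotype.REF_REF
                record.multilocus_genes = sorted([entry.gene, entry2.gene])
                multilocus_left -= 1
        elif scenario == "AR_compound_het":
            entry = ar_genes[srng.integers(len(ar_genes))]
            force = None
            if degraded_left >= 2:
                # both alleles fall in a zero-coverage target (high-GC exon)
                force = target_by_id[poor_ids[0]]
                entry = panel_by_gene[force.gene]
            loci = [
                _pick_locus(srng, entry.gene, targets_by_gene, used,
                            avoid_ids=poor_id_set if force is None else frozenset(),
                            force_target=force)
                for _ in range(2)
            ]
            for k, locus in enumerate(loci):
                effect = _pick_causal_effect(srng)
                pv = PlantedVariant(locus.chrom, locus.pos, locus.ref, locus.alt,
                                    entry.gene, "het", effect.value,
                                    FinalClass.PATHOGENIC.value
                                    if effect is not Effect.MISSENSE
                                    else FinalClass.PROBABLY_PATHOGENIC.value)
                if force is not None:
                    pv.detectable = False
                    pv.drop_reason = "degraded_target"
                planted.append(pv)
                genotypes[sid][locus] = Genotype.HET
                carrier = father if k == 0 else mother
                other = mother if k == 0 else father
                genotypes[carrier.individual_id][locus] = Genotype.HET
                genotypes[other.individual_id][locus] = Genotype.REF_REF
            if force is not None:
                degraded_left -= 2
                record.expected_solved = False
            elif low_support_left > 0:
                planted[0].detectable = False
                planted[0].drop_reason = "low_support"
                low_support_left -= 1
                record.expected_solved = False
            else:
                record.expected_solved = True
            record.gene, record.mode = entry.gene, "AR"
        elif scenario == "AD_inherited":
            entry = ad_genes[srng.integers(len(ad_genes))]
            locus = _pick_locus(srng, entry.gene, targets_by_gene, used,
                                avoid_ids=poor_id_set)
            planted.append(
                PlantedVariant(locus.chrom, locus.pos, locus.ref, locus.alt, entry.gene,
                               "het", Effect.MISSENSE.value,
                               FinalClass.PROBABLY_PATHOGENIC.value)
            )
            carrier = father if srng.random() < 0.5 else mother
            carrier.affected = True
            genotypes[sid][locus] = Genotype.HET
            genotypes[carrier.individual_id][locus] = Genotype.HET
            other = mother if carrier is father else father
            genotypes[other.individual_id][locus] = Genotype.REF_REF
            record.gene, record.mode, record.expected_solved = entry.gene, "AD", True
        elif scenario == "AD_de_novo":
            entry = ad_genes[srng.integers(len(ad_genes))]
            planted, genotypes_dn, markers = plant_de_novo(
                fam, entry, targets_by_gene, srng, used,
                mode=InheritanceMode.AD, marker_count=cfg.de_novo_marker_count,
                avoid_ids=poor_id_set,
            )
            for ind, loci in genotypes_dn.items():
                genotypes[ind].update(loci)
            for ind, ms in markers.items():
                all_markers[(fid, ind)] = ms
            record.gene, record.mode, record.expected_solved = entry.gene, "AD", True
        elif scenario == "XL":
            entry = xl_genes[srng.integers(len(xl_genes))]
            locus = _pick_locus(srng, entry.gene, targets_by_gene, used,
                                avoid_ids=poor_id_set)
            effect = _pick_causal_effect(srng)
            planted.append(
                PlantedVariant(locus.chrom, locus.pos, locus.ref, locus.alt, entry.gene,
                               "hemi", effect.value,
                               FinalClass.PATHOGENIC.value
                               if effect is not Effect.MISSENSE
                               else FinalClass.PROBABLY_PATHOGENIC.value)
            )
            genotypes[sid][locus] = Genotype.HEMI_ALT
            genotypes[mother.individual_id][locus] = Genotype.HET
            genotypes[father.individual_id][locus] = Genotype.REF_REF
            record.gene, record.mode, record.expected_solved = entry.gene, "XL", True

        record.planted = planted
        for ind, loci in genotypes.items():
            if loci:
                all_genotypes[(fid, ind)] = loci
                fam.members[ind].genotypes.update(loci)
        truth.append(record)

    panel_io.write_pedigree(families, out_dir / "cohort.ped")
    panel_io.write_family_genotypes(all_genotypes, out_dir / "relative_genotypes.tsv")
    panel_io.write_markers(all_markers, out_dir / "markers.tsv")

    # per-sample variant tables + depth
    target_list_nonpoor = [t for t in targets if t.region_id not in poor_id_set]
    for record in truth:
        sid = record.sample_id
        srng = _sample_rng(cfg, sid + ":variants")
        drng = _sample_rng(cfg, sid + ":depth")
        tracks, site_means = _sample_depth_tracks(cfg, targets, poor_ids, drng)
        if cfg.emit_depth:
            panel_io.write_depth(
                {rid: tracks[rid] for rid in sorted(tracks)}, out_dir / f"{sid}.depth.tsv"
            )

        sex = families[record.family_id].members[sid].sex
        used_keys: set = {
            (pv.chrom, pv.pos, pv.ref, pv.alt) for pv in record.planted
        }
        variants: list[AnnotatedVariant] = []

        # planted causal alleles
        for pv in record.planted:
            if pv.drop_reason == "degraded_target":
                continue  # zero coverage: never called
            effect = Effect(pv.effect)
            annot = _causal_annotation(srng, effect)
            zyg = Zygosity(pv.zygosity)
            if pv.drop_reason == "low_support":
                support = _LOW_SUPPORT
            else:
                target_mean = site_means.get(
                    _containing_region(pv, targets_by_gene), cfg.mean_depth
                )
                support = _good_support(srng, zyg, target_mean)
            v = AnnotatedVariant(
                locus=pv.locus(), gene=pv.gene, zygosity=zyg,
                support=support, annot=annot, sample_id=sid,
            )
            if pv.detectable:
                _assert_planted_passes(v, thresholds)
            variants.append(v)

        # background variants
        n_bg = int(srng.poisson(cfg.mean_background_variants))
        record.n_background = n_bg
        n_confirmed = 0
        idx = srng.integers(len(target_list_nonpoor), size=n_bg)
        for j in range(n_bg):
            t = target_list_nonpoor[idx[j]]
            pos = int(t.start + 1 + srng.integers(t.length))
            ref, alt = _random_snv(srng)
            key = (t.chrom, pos, ref, alt)
            if key in used_keys:
                continue
            used_keys.add(key)
            annot = _background_annotation(srng, cfg)
            if t.chrom == "chrX" and sex == "male":
                zyg = Zygosity.HEMI
            else:
                zyg = Zygosity.HOM if srng.random() < 0.1 else Zygosity.HET
            support = _background_support(srng, zyg, site_means[t.region_id])
            v = AnnotatedVariant(
                locus=VariantLocus(t.chrom, pos, ref, alt), gene=t.gene,
                zygosity=zyg, support=support, annot=annot, sample_id=sid,
            )
            # non-causal by construction: redraw any pathogenic-tier draw
            tries = 0
            while classify_variant(v, thresholds).is_pathogenic_tier():
                tries += 1
                annot = (
                    _background_annotation(srng, cfg)
                    if tries < 20
                    else _benign_fallback(annot.effect, annot)
                )
                v = AnnotatedVariant(
                    locus=v.locus, gene=v.gene, zygosity=zyg,
                    support=support, annot=annot, sample_id=sid,
                )
            if srng.random() >= cfg.fraction_false_indels:
                n_confirmed += 1
            variants.append(v)
        record.n_background_confirmed = n_confirmed

        panel_io.write_variants(
            variants, sid,
            out_dir / f"{sid}.vcf",
            out_dir / f"{sid}.support.tsv",
            out_dir / f"{sid}.annot.tsv",
        )

    _write_truth(truth, out_dir / "truth.json")
    return truth


def _containing_region(pv: PlantedVariant, targets_by_gene: dict[str, list[TargetRegion]]) -> str:
    for t in targets_by_gene.get(pv.gene, []):
        if t.start < pv.pos <= t.end:
            return t.region_id
    return ""


def _assert_planted_passes(v: AnnotatedVariant, cfg: ThresholdConfig) -> None:
    ok = (
        is_high_quality(v.support, cfg)
        and passes_effect_filter(v, cfg)
        and passes_novelty_filter(v, cfg)
        and passes_frequency_filters(v, cfg)
        and passes_support_filter(v.support, cfg)
        and classify_variant(v, cfg).is_pathogenic_tier()
    )
    if not ok:
        raise AssertionError(f"planted causal variant {v.locus} fails its construction contract")


def _write_truth(truth: list[TruthRecord], path: Path) -> None:
    payload = [asdict(t) for t in truth]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path: str | Path) -> list[TruthRecord]:
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for item in payload:
        planted = [PlantedVariant(**p) for p in item.pop("planted")]
        out.append(TruthRecord(planted=planted, **item))
    return out
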
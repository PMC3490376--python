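"""End-to-end orchestration: from called variants to a diagnosis per
sample and cohort statistics.

``diagnose_sample`` chains the prioritization cascade, the three-axis
classifier and the family-level segregation checks into a
``DiagnosisResult``: a sample is solved when one gene carries
pathogenic-tier variants in a dose consistent with one of the gene's
inheritance modes (homozygous or compound heterozygous for recessive,
heterozygous for dominant, hemizygous males for X-linked) and segregation
in available relatives does not contradict the call. Untested segregation
does not block a diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import panel_io
from .classification import classify_variant
from .cohort_report import DiagnosisResult
from .config import ThresholdConfig
from .prioritization import FunnelCounts, prioritize_sample
from .segregation import (
    SegregationStatus,
    SegregationVerdict,
    check_segregation,
    mendelian_consistency,
)
from .types import (
    AnnotatedVariant,
    Family,
    FinalClass,
    GenePanelEntry,
    InheritanceMode,
    MarkerGenotype,
    VariantLocus,
    Zygosity,
)

__all__ = ["SampleResult", "diagnose_sample", "run_cohort"]


@dataclass
class SampleResult:
    sample_id: str
    shortlist: list[AnnotatedVariant]
    classified: list[tuple[AnnotatedVariant, FinalClass]]
    funnel: FunnelCounts
    diagnosis: DiagnosisResult


def _dose_consistent(
    variants: Sequence[AnnotatedVariant], mode: InheritanceMode, sex: str
) -> bool:
    """Do these pathogenic-tier variants provide a disease-causing dose?"""
    homs = [v for v in variants if v.zygosity is Zygosity.HOM]
    hets = [v for v in variants if v.zygosity is Zygosity.HET]
    hemis = [v for v in variants if v.zygosity is Zygosity.HEMI]
    if mode is InheritanceMode.AR:
        return bool(homs) or len({v.locus for v in hets}) >= 2
    if mode is InheritanceMode.AD:
        return bool(homs or hets)
    if mode is InheritanceMode.XL:
        if sex == "male":
            return bool(hemis)
        return bool(homs) or len({v.locus for v in hets}) >= 2
    raise ValueError(mode)


_MODE_ORDER = [InheritanceMode.XL, InheritanceMode.AR, InheritanceMode.AD]


def diagnose_sample(
    variants: Sequence[AnnotatedVariant],
    panel: dict[str, GenePanelEntry],
    family: Optional[Family],
    proband_id: str,
    cfg: ThresholdConfig | None = None,
    markers: Optional[dict[str, list[MarkerGenotype]]] = None,
) -> SampleResult:
    """Prioritize, classify and segregate one sample.

    ``markers`` maps individual id -> marker genotypes for the proband's
    family; when present, a de novo call additionally requires full
    Mendelian marker consistency across the trio.
    """
    cfg = cfg or ThresholdConfig()
    member = None
    if family is not None and proband_id in family.members:
        member = family.members[proband_id]
    shortlist, funnel = prioritize_sample(variants, panel, member, cfg)
    classified = [(v, classify_variant(v, cfg)) for v in shortlist]

    sex = member.sex if member is not None else "female"
    patho_by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v, fc in classified:
        if fc.is_pathogenic_tier():
            patho_by_gene.setdefault(v.gene, []).append(v)

    solved_gene: Optional[str] = None
    solved_mode: Optional[InheritanceMode] = None
    verdict: Optional[SegregationVerdict] = None
    de_novo = False

    # a recessive biallelic diagnosis outranks a single dominant allele
    # (hemizygous X-linked first): try modes in that order across genes
    for mode in _MODE_ORDER:
        for gene in sorted(patho_by_gene):
            entry = panel[gene]
            gene_variants = patho_by_gene[gene]
            if mode not in entry.modes:
                continue
            if not _dose_consistent(gene_variants, mode, sex):
                continue
            loci = sorted({v.locus for v in gene_variants})
            if family is not None and proband_id in family.members:
                v_segr = check_segregation(loci, family, proband_id, mode, entry)
            else:
                v_segr = SegregationVerdict(SegregationStatus.UNTESTED, notes="no pedigree")
            if v_segr.status is SegregationStatus.CONTRADICTED:
                continue
            if v_segr.de_novo_loci and markers:
                v_segr = _confirm_de_novo(v_segr, family, proband_id, markers)
            solved_gene, solved_mode, verdict = gene, mode, v_segr
            de_novo = bool(v_segr.de_novo_loci)
            break
        if solved_gene:
            break

    diagnosis = DiagnosisResult(
        sample_id=proband_id,
        solved=solved_gene is not None,
        gene=solved_gene,
        variants=[(v, fc) for v, fc in classified if solved_gene and v.gene == solved_gene],
        mode=solved_mode,
        segregation=verdict,
        de_novo=de_novo,
    )
    return SampleResult(
        sample_id=proband_id,
        shortlist=shortlist,
        classified=classified,
        funnel=funnel,
        diagnosis=diagnosis,
    )


def _confirm_de_novo(
    verdict: SegregationVerdict,
    family: Family,
    proband_id: str,
    markers: dict[str, list[MarkerGenotype]],
) -> SegregationVerdict:
    """Keep de novo loci only when trio markers confirm Mendelian
    inheritance (paternity/maternity); otherwise mark them apparent."""
    father, mother = family.parents_of(proband_id)
    child_m = markers.get(proband_id)
    f_m = markers.get(father.individual_id) if father else None
    m_m = markers.get(mother.individual_id) if mother else None
    if not (child_m and f_m and m_m):
        verdict.notes = (verdict.notes + "; " if verdict.notes else "") + "apparent de novo (no markers)"
        return verdict
    _, _, confirmed = mendelian_consistency(child_m, f_m, m_m)
    if not confirmed:
        verdict.de_novo_loci = []
        verdict.notes = (verdict.notes + "; " if verdict.notes else "") + "marker inconsistency: de novo not confirmed"
    return verdict


def run_cohort(
    cohort_dir: str | Path,
    cfg: ThresholdConfig | None = None,
    sample_ids: Optional[Sequence[str]] = None,
) -> list[SampleResult]:
    """Run the full pipeline over a simulated/on-disk cohort directory
    (the layout written by ``synthetic_cohort.simulate_cohort``)."""
    cohort_dir = Path(cohort_dir)
    cfg = cfg or ThresholdConfig()
    panel = {e.gene: e for e in panel_io.read_panel(cohort_dir / "panel.tsv")}
    families = panel_io.read_pedigree(cohort_dir / "cohort.ped")
    geno_path = cohort_dir / "relative_genotypes.tsv"
    if geno_path.exists():
        panel_io.attach_genotypes(families, panel_io.read_family_genotypes(geno_path))
    marker_path = cohort_dir / "markers.tsv"
    markers_by_family: dict[str, dict[str, list[MarkerGenotype]]] = {}
    if marker_path.exists():
        for (fam_id, ind_id), ms in panel_io.read_markers(marker_path).items():
            markers_by_family.setdefault(fam_id, {})[ind_id] = ms

    family_of = {
        m.individual_id: fam for fam in families.values() for m in fam.members.values()
    }
    if sample_ids is None:
        sample_ids = sorted(p.stem for p in cohort_dir.glob("S*.vcf"))

    results = []
    for sid in sample_ids:
        variants = panel_io.read_variants(
            cohort_dir / f"{sid}.vcf",
            cohort_dir / f"{sid}.support.tsv",
            cohort_dir / f"{sid}.annot.tsv",
            sample_id=sid,
        )
        fam = family_of.get(sid)
        markers = markers_by_family.get(fam.family_id) if fam else None
        results.append(diagnose_sample(variants, panel, fam, sid, cfg, markers))
    return results
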
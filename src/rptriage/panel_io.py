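"""Readers and writers for every external format the pipeline touches.

Formats
-------
* gene panel: TSV with columns ``gene, chrom, modes`` (modes comma-separated
  from {AR, AD, XL})
* capture targets: BED (0-based half-open) with name field ``gene|region_id``
* variant calls: VCF v4.x, one sample per file; zygosity from the GT field
  (haploid ``1`` on chrX in males -> hemizygous)
* per-variant read support and annotations: TSV keyed by
  (chrom, pos, ref, alt)
* pedigrees: 6-column PED (family, individual, father, mother, sex, phenotype)
* per-base depth: TSV ``region_id, offset, depth``
* candidate-locus genotypes of relatives and polymorphic-marker genotypes:
  small TSV dialects documented in the reader docstrings

Thresholds (``ThresholdConfig``) are re-exported here so that callers can
treat this module as the single entry point for configuration + I/O.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam

from .config import ThresholdConfig
from .types import (
    AnnotatedVariant,
    AnnotationBundle,
    Effect,
    Family,
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
    "ThresholdConfig",
    "read_panel",
    "write_panel",
    "read_targets",
    "write_targets",
    "read_variants",
    "write_variants",
    "read_pedigree",
    "write_pedigree",
    "read_depth",
    "write_depth",
    "read_family_genotypes",
    "write_family_genotypes",
    "attach_genotypes",
    "read_markers",
    "write_markers",
]

SUPPORT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "total_reads",
    "variant_reads",
    "nonduplicate_variant_reads",
    "forward_variant_reads",
    "reverse_variant_reads",
    "hq_variant_reads",
]

ANNOT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "splice_acceptor_offset",
    "splice_donor_offset",
    "in_dbsnp130",
    "in_hgmd",
    "known_blindness_mutation",
    "exome_cohort_freq",
    "disease_cohort_freq",
    "phylop",
    "sift_class",
    "polyphen_class",
    "mutpred_class",
    "ssf_wt",
    "ssf_mut",
    "maxent_wt",
    "maxent_mut",
    "nnsplice_wt",
    "nnsplice_mut",
]


# ---------------------------------------------------------------------------
# gene panel
# ---------------------------------------------------------------------------

def read_panel(path: str | Path) -> list[GenePanelEntry]:
    """Read the gene panel TSV (columns: gene, chrom, modes)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene", "chrom", "modes"} - set(df.columns)
    if missing:
        raise ValueError(f"panel file missing columns: {sorted(missing)}")
    entries = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        tokens = [t.strip() for t in str(row.modes).split(",") if t.strip()]
        try:
            modes = frozenset(InheritanceMode(t.upper()) for t in tokens)
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: unknown inheritance mode in {tokens!r}") from exc
        entries.append(GenePanelEntry(gene=row.gene, chrom=row.chrom, modes=modes))
    return entries


def write_panel(entries: Iterable[GenePanelEntry], path: str | Path) -> None:
    rows = [
        {
            "gene": e.gene,
            "chrom": e.chrom,
            "modes": ",".join(sorted(m.value for m in e.modes)),
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=["gene", "chrom", "modes"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# capture targets (BED)
# ---------------------------------------------------------------------------

def read_targets(path: str | Path) -> list[TargetRegion]:
    """Read capture targets from BED; the name column is ``gene|region_id``."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"], dtype=str
    )
    targets = []
    for row in df.itertuples(index=False):
        gene, _, region_id = str(row.name).partition("|")
        targets.append(
            TargetRegion(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                gene=gene,
                region_id=region_id or gene,
            )
        )
    return targets


def write_targets(targets: Iterable[TargetRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in targets:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene}|{t.region_id}\n")


# ---------------------------------------------------------------------------
# variants: VCF + support + annotation join
# ---------------------------------------------------------------------------

def _tri(value: object) -> Optional[TriClass]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return TriClass(str(value))


def _zygosity_from_gt(gt: tuple, chrom: str) -> Optional[Zygosity]:
    alleles = [a for a in gt if a is not None]
    if not alleles or all(a == 0 for a in alleles):
        return None
    if len(alleles) == 1:
        return Zygosity.HEMI
    if all(a > 0 for a in alleles):
        return Zygosity.HOM
    return Zygosity.HET


def _annotation_from_row(row: pd.Series) -> AnnotationBundle:
    effect = Effect(row["effect"])

    def _opt_int(name: str) -> Optional[int]:
        v = row.get(name)
        return None if v is None or pd.isna(v) else int(v)

    missense_calls = None
    calls = [_tri(row.get(c)) for c in ("sift_class", "polyphen_class", "mutpred_class")]
    if any(c is not None for c in calls):
        missense_calls = tuple(c if c is not None else TriClass.UNKNOWN for c in calls)

    splice_scores = None
    pairs = {}
    for tool in ("ssf", "maxent", "nnsplice"):
        wt, mut = row.get(f"{tool}_wt"), row.get(f"{tool}_mut")
        if wt is not None and mut is not None and not (pd.isna(wt) or pd.isna(mut)):
            pairs[tool] = (float(wt), float(mut))
    if pairs:
        splice_scores = pairs

    return AnnotationBundle(
        effect=effect,
        splice_acceptor_offset=_opt_int("splice_acceptor_offset"),
        splice_donor_offset=_opt_int("splice_donor_offset"),
        in_dbsnp130=bool(row["in_dbsnp130"]),
        in_hgmd=bool(row["in_hgmd"]),
        known_blindness_mutation=bool(row["known_blindness_mutation"]),
        exome_cohort_freq=float(row["exome_cohort_freq"]),
        disease_cohort_freq=float(row["disease_cohort_freq"]),
        phylop=float(row["phylop"]),
        missense_calls=missense_calls,
        splice_scores=splice_scores,
    )


def read_variants(
    vcf_path: str | Path,
    support_path: str | Path,
    annot_path: str | Path,
    sample_id: Optional[str] = None,
) -> list[AnnotatedVariant]:
    """Join a single-sample VCF with its support and annotation tables.

    Multi-allelic records are split into one variant per alternate allele.
    An annotation row without a VCF record is skipped with a warning; a VCF
    record without an annotation raises (the pipeline requires complete
    annotation).
    """
    support = pd.read_csv(support_path, sep="\t", dtype={"chrom": str})
    annot = pd.read_csv(annot_path, sep="\t", dtype={"chrom": str})
    support_by_key = {
        (r.chrom, int(r.pos), r.ref, r.alt): r for r in support.itertuples(index=False)
    }
    annot.set_index(["chrom", "pos", "ref", "alt"], inplace=True, drop=False)

    variants: list[AnnotatedVariant] = []
    seen_keys: set[tuple] = set()
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        if sample_id is None:
            if len(samples) != 1:
                raise ValueError("sample_id required for multi-sample VCF")
            sample_id = samples[0]
        for rec in vcf:
            gt = rec.samples[sample_id].get("GT", ())
            for ai, alt in enumerate(rec.alts or (), start=1):
                zyg = _zygosity_from_gt(
                    tuple(a if a is None else int(a == ai) for a in gt), rec.chrom
                )
                if zyg is None:
                    continue
                key = (rec.chrom, rec.pos, rec.ref, alt)
                seen_keys.add(key)
                try:
                    arow = annot.loc[key]
                except KeyError:
                    raise ValueError(f"VCF record {key} has no annotation row")
                if isinstance(arow, pd.DataFrame):
                    arow = arow.iloc[0]
                srow = support_by_key.get(key)
                if srow is None:
                    raise ValueError(f"VCF record {key} has no read-support row")
                variants.append(
                    AnnotatedVariant(
                        locus=VariantLocus(rec.chrom, rec.pos, rec.ref, alt),
                        gene=str(arow["gene"]),
                        zygosity=zyg,
                        support=ReadSupport(
                            total_reads=int(srow.total_reads),
                            variant_reads=int(srow.variant_reads),
                            nonduplicate_variant_reads=int(srow.nonduplicate_variant_reads),
                            forward_variant_reads=int(srow.forward_variant_reads),
                            reverse_variant_reads=int(srow.reverse_variant_reads),
                            hq_variant_reads=int(srow.hq_variant_reads),
                        ),
                        annot=_annotation_from_row(arow),
                        sample_id=sample_id,
                    )
                )
    unmatched = len(annot) - len(
        seen_keys & set(map(tuple, annot[["chrom", "pos", "ref", "alt"]].itertuples(index=False)))
    )
    if unmatched > 0:
        warnings.warn(f"{unmatched} annotation rows had no VCF record and were skipped")
    return variants


_CONTIGS = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]


def write_variants(
    variants: list[AnnotatedVariant],
    sample_id: str,
    vcf_path: str | Path,
    support_path: str | Path,
    annot_path: str | Path,
) -> None:
    """Emit the VCF + support + annotation triple that ``read_variants`` reads."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for contig in _CONTIGS:
        header.contigs.add(contig)
    header.add_sample(sample_id)
    ordered = sorted(variants, key=lambda v: (_CONTIGS.index(v.locus.chrom), v.locus.pos))
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
        for v in ordered:
            rec = vcf.new_record(
                contig=v.locus.chrom,
                start=v.locus.pos - 1,
                alleles=(v.locus.ref, v.locus.alt),
            )
            if v.zygosity is Zygosity.HEMI:
                rec.samples[sample_id]["GT"] = (1,)
            elif v.zygosity is Zygosity.HOM:
                rec.samples[sample_id]["GT"] = (1, 1)
            else:
                rec.samples[sample_id]["GT"] = (0, 1)
            vcf.write(rec)

    srows, arows = [], []
    for v in ordered:
        base = dict(chrom=v.locus.chrom, pos=v.locus.pos, ref=v.locus.ref, alt=v.locus.alt)
        s = v.support
        srows.append(
            {
                **base,
                "total_reads": s.total_reads,
                "variant_reads": s.variant_reads,
                "nonduplicate_variant_reads": s.nonduplicate_variant_reads,
                "forward_variant_reads": s.forward_variant_reads,
                "reverse_variant_reads": s.reverse_variant_reads,
                "hq_variant_reads": s.hq_variant_reads,
            }
        )
        a = v.annot
        mc = a.missense_calls or (None, None, None)
        ss = a.splice_scores or {}
        arows.append(
            {
                **base,
                "gene": v.gene,
                "effect": a.effect.value,
                "splice_acceptor_offset": a.splice_acceptor_offset,
                "splice_donor_offset": a.splice_donor_offset,
                "in_dbsnp130": a.in_dbsnp130,
                "in_hgmd": a.in_hgmd,
                "known_blindness_mutation": a.known_blindness_mutation,
                "exome_cohort_freq": a.exome_cohort_freq,
                "disease_cohort_freq": a.disease_cohort_freq,
                "phylop": a.phylop,
                "sift_class": mc[0].value if mc[0] else None,
                "polyphen_class": mc[1].value if mc[1] else None,
                "mutpred_class": mc[2].value if mc[2] else None,
                "ssf_wt": ss.get("ssf", (None, None))[0],
                "ssf_mut": ss.get("ssf", (None, None))[1],
                "maxent_wt": ss.get("maxent", (None, None))[0],
                "maxent_mut": ss.get("maxent", (None, None))[1],
                "nnsplice_wt": ss.get("nnsplice", (None, None))[0],
                "nnsplice_mut": ss.get("nnsplice", (None, None))[1],
            }
        )
    pd.DataFrame(srows, columns=SUPPORT_COLUMNS).to_csv(support_path, sep="\t", index=False)
    pd.DataFrame(arows, columns=ANNOT_COLUMNS).to_csv(annot_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pedigrees (PED)
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> dict[str, Family]:
    """Read a 6-column PED file into per-family graphs.

    PED conventions: father/mother "0" = not recorded; sex 1=male 2=female;
    phenotype 2=affected, 1=unaffected.
    """
    families: dict[str, Family] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path} line {lineno}: expected 6 columns")
            fam_id, ind_id, father, mother, sex, pheno = parts
            if sex not in ("1", "2"):
                raise ValueError(f"{path} line {lineno}: sex code {sex!r} not in {{1,2}}")
            member = PedigreeMember(
                individual_id=ind_id,
                family_id=fam_id,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex="male" if sex == "1" else "female",
                affected=pheno == "2",
            )
            families.setdefault(fam_id, Family(family_id=fam_id)).add(member)
    for fam in families.values():
        _check_pedigree(fam)
    return families


def _check_pedigree(fam: Family) -> None:
    for m in fam.members.values():
        for pid in (m.father_id, m.mother_id):
            if pid is not None and pid not in fam.members:
                warnings.warn(
                    f"family {fam.family_id}: parent {pid} of {m.individual_id} not in pedigree"
                )
    # cycle detection via ancestor walk
    for m in fam.members.values():
        seen = {m.individual_id}
        stack = [p for p in (m.father_id, m.mother_id) if p in fam.members]
        while stack:
            cur = stack.pop()
            if cur in seen:
                raise ValueError(f"family {fam.family_id}: cyclic parentage at {cur}")
            seen.add(cur)
            cm = fam.members[cur]
            stack.extend(p for p in (cm.father_id, cm.mother_id) if p in fam.members)


def write_pedigree(families: dict[str, Family], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fam in families.values():
            for m in fam.members.values():
                fh.write(
                    "\t".join(
                        [
                            fam.family_id,
                            m.individual_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            "1" if m.sex == "male" else "2",
                            "2" if m.affected else "1",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# per-base depth
# ---------------------------------------------------------------------------

def read_depth(path: str | Path) -> dict[str, list[int]]:
    """Read per-base depth TSV (region_id, offset, depth) into per-target lists."""
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str})
    tracks: dict[str, list[int]] = {}
    for region_id, grp in df.groupby("region_id", sort=False):
        grp = grp.sort_values("offset")
        tracks[str(region_id)] = grp["depth"].astype(int).tolist()
    return tracks


def write_depth(tracks: dict[str, "list[int]"], path: str | Path) -> None:
    import numpy as np

    frames = []
    for region_id, depths in tracks.items():
        frames.append(
            pd.DataFrame(
                {
                    "region_id": region_id,
                    "offset": np.arange(len(depths)),
                    "depth": np.asarray(depths, dtype=int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# relative genotypes at candidate loci
# ---------------------------------------------------------------------------

def read_family_genotypes(path: str | Path) -> dict[tuple[str, str], dict[VariantLocus, Genotype]]:
    """Read TSV (family_id, individual_id, chrom, pos, ref, alt, genotype).

    Returns a map from (family_id, individual_id) to locus->genotype. These
    are the Sanger-typed genotypes of relatives at candidate loci.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "family_id": str, "individual_id": str})
    out: dict[tuple[str, str], dict[VariantLocus, Genotype]] = {}
    for r in df.itertuples(index=False):
        locus = VariantLocus(r.chrom, int(r.pos), r.ref, r.alt)
        out.setdefault((r.family_id, r.individual_id), {})[locus] = Genotype(r.genotype)
    return out


def write_family_genotypes(
    genotypes: dict[tuple[str, str], dict[VariantLocus, Genotype]], path: str | Path
) -> None:
    rows = []
    for (fam, ind), loci in genotypes.items():
        for locus, gt in loci.items():
            rows.append(
                {
                    "family_id": fam,
                    "individual_id": ind,
                    "chrom": locus.chrom,
                    "pos": locus.pos,
                    "ref": locus.ref,
                    "alt": locus.alt,
                    "genotype": gt.value,
                }
            )
    pd.DataFrame(
        rows,
        columns=["family_id", "individual_id", "chrom", "pos", "ref", "alt", "genotype"],
    ).to_csv(path, sep="\t", index=False)


def attach_genotypes(
    families: dict[str, Family],
    genotypes: dict[tuple[str, str], dict[VariantLocus, Genotype]],
) -> None:
    """Attach candidate-locus genotypes (in place) to pedigree members."""
    for (fam_id, ind_id), loci in genotypes.items():
        fam = families.get(fam_id)
        if fam is None or ind_id not in fam.members:
            warnings.warn(f"genotypes for unknown individual {fam_id}/{ind_id} ignored")
            continue
        fam.members[ind_id].genotypes.update(loci)


# ---------------------------------------------------------------------------
# polymorphic markers
# ---------------------------------------------------------------------------

def read_markers(path: str | Path) -> dict[tuple[str, str], list[MarkerGenotype]]:
    """Read marker TSV (family_id, individual_id, marker_id, allele1, allele2)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[tuple[str, str], list[MarkerGenotype]] = {}
    for r in df.itertuples(index=False):
        out.setdefault((r.family_id, r.individual_id), []).append(
            MarkerGenotype(r.marker_id, r.allele1, r.allele2)
        )
    return out


def write_markers(
    markers: dict[tuple[str, str], list[MarkerGenotype]], path: str | Path
) -> None:
    rows = [
        {
            "family_id": fam,
            "individual_id": ind,
            "marker_id": m.marker_id,
            "allele1": m.allele1,
            "allele2": m.allele2,
        }
        for (fam, ind), ms in markers.items()
        for m in ms
    ]
    pd.DataFrame(
        rows, columns=["family_id", "individual_id", "marker_id", "allele1", "allele2"]
    ).to_csv(path, sep="\t", index=False)
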
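# rptriage

Gene-panel molecular diagnostics for retinitis pigmentosa (RP) as a
reusable, testable pipeline. RP is an inherited retinal degeneration with
extreme locus heterogeneity — more than fifty causal genes acting under
autosomal recessive, autosomal dominant and X-linked inheritance — which
makes targeted-capture sequencing of all retinal-disease genes, followed by
systematic variant triage, the natural diagnostic strategy. `rptriage`
implements that triage for anyone who has called variants on a gene panel
and needs to get from ~1,300 calls per patient to a defensible molecular
diagnosis: clinical-genetics labs prototyping filter cascades, and
methodologists who want the whole workflow reproducible on synthetic
cohorts.

## What it computes

**High-quality call designation.** A called variant is trusted when it was
seen in ≥ 3 nonduplicate reads including ≥ 1 forward and ≥ 1 reverse read,
or in ≥ 5 reads with base quality > 20.

**Six-criterion prioritization.** A variant is selected iff it is
(1) nonsynonymous or within the splice windows (8 bp acceptor / 20 bp
donor); (2) absent from dbSNP130 unless in HGMD or a known blindness
mutation; (3) ≤ 5% frequent in a reference exome cohort; (4) ≤ 15% frequent
in the disease cohort; (5) covered by ≥ 10 reads with ≥ 20% variant reads
or ≥ 5 reads with 80–100% variant reads; and (6) consistent with the
gene's inheritance pattern — homozygous or compound heterozygous for
recessive genes, heterozygous for dominant, hemizygous males for X-linked.
A lone nonsense/frameshift/canonical-splice survivor in a recessive gene
triggers a *second-allele rescue* that re-searches the unfiltered calls of
that gene with the novelty and frequency criteria relaxed.

**Three-axis pathogenicity classification.** Truncating and canonical
splice variants are pathogenic outright. Other variants are scored on
in-silico tools (majority vote of SIFT/PolyPhen/MutPred classes, or of
SpliceSiteFinder/MaxEntScan/NNSplice wt-vs-mut comparisons), conservation
(PhyloP < 1 benign, > 2.5 pathogenic) and dual-cohort frequency (> 3%
exome benign; 1–3% exome or ≥ 3% disease-cohort unknown; otherwise
pathogenic). A benign frequency axis overrides everything to
probably-benign; otherwise the three axes vote, with a three-way split
mapping to unknown.

**Segregation and de novo analysis.** Candidate genotypes are tested for
co-segregation with affection status under a stated mode; trio genotypes
yield de novo calls, confirmed (vs apparent) by Mendelian consistency of a
polymorphic marker panel; compound-het pairs are phased through parents;
samples with pathogenic-tier variants in two genes are flagged as
cumulative mutational load.

**Cohort statistics.** Detection rate, solved rate (diagnostic yield),
filtering reduction, enrichment of true mutations, Sanger-confirmation
accounting, and the cohort-extrapolated projected yield.

**Synthetic cohorts.** A seeded generator emits every input format the
pipeline reads (panel TSV, BED targets, VCF + support/annotation TSVs, PED,
depth and marker tables) with causal genotypes planted under recessive,
dominant, de novo and X-linked scenarios, plus a truth file for recovery
tests.

## Worked example

```bash
python examples/02_prioritize_sample.py
```

```
auto-detected:                 7
after effect/novelty/frequency/support: 2
after inheritance filter:      0
after second-allele rescue:    2

shortlist:
  USH2A  chr1:1000G>A nonsense
  USH2A  chr1:9000G>A missense (rescued)
```

Seven calls enter; filters 1–5 keep the novel nonsense and one novel
missense, the inheritance criterion drops both as lone heterozygotes in
recessive genes, and the rescue recovers the dbSNP-listed second allele of
the nonsense carrier — a compound-heterozygous diagnosis the plain cascade
would have missed. The other examples classify single variants
(`01_classify_variants.py`), work a trio with a confirmed de novo event
(`03_segregation_de_novo.py`), and run a 20-sample synthetic cohort
end-to-end (`04_cohort_yield.py`).

A thin CLI wraps the same functions:

```bash
rptriage simulate --seed 1 --n-samples 12 --out-dir cohort/
rptriage triage --vcf cohort/S001.vcf --support cohort/S001.support.tsv \
    --annot cohort/S001.annot.tsv --panel cohort/panel.tsv \
    --ped cohort/cohort.ped --out-prefix S001
rptriage report --cohort-dir cohort/ --out summary.json
rptriage classify --truth-table
```

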
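# Methods

## Scope and model

`rptriage` treats molecular diagnosis on a gene panel as a deterministic
decision procedure over annotated variant calls. It starts *after* read
mapping and variant calling: the inputs are per-sample variant calls with
read-support summaries, a precomputed annotation table (effect class,
database membership, cohort frequencies, conservation, prediction-tool
outputs), the gene panel with per-gene inheritance modes, capture targets,
per-base depth, and pedigrees. Nothing in the package runs an aligner, a
caller or a prediction tool; those are upstream, and their outputs are
inputs here. Consequently there is no liftover, no reference-sequence
validation of alleles and no HGVS parsing.

The pipeline has five stages, each a pure function of its inputs and the
threshold configuration:

1. **quality designation** — a call is a high-quality difference when it
   has ≥ 3 nonduplicate variant reads on both strands, or ≥ 5 variant
   reads of base quality > 20;
2. **prioritization** — the conjunction of five per-variant predicates
   (effect, novelty, reference-cohort frequency, disease-cohort frequency,
   read support) followed by a per-gene inheritance consistency filter and
   the second-allele rescue;
3. **classification** — truncating/canonical-splice/large-deletion →
   pathogenic; otherwise a combination of the in-silico, conservation and
   frequency axes;
4. **segregation** — family-level consistency of the candidate genotypes
   under the proposed mode, with de novo detection and marker-based
   paternity confirmation;
5. **reporting** — per-sample diagnosis and cohort statistics.

A sample is *solved* when one gene carries pathogenic-tier variants in a
dose consistent with one of its modes (biallelic for recessive, one allele
for dominant, hemizygous male or biallelic female for X-linked) and
segregation, where testable, does not contradict the call. Untested
segregation does not block a diagnosis; contradicted segregation does.
When several (gene, mode) candidates solve a sample, modes are tried in
the order X-linked, recessive, dominant across genes, so a biallelic
recessive diagnosis outranks a single additional dominant allele (the
cumulative-load situation, which is separately reported).

## Thresholds

All cutoffs live in `ThresholdConfig`, overridable via YAML. Defaults:

| parameter | default | role |
|---|---|---|
| splice_acceptor_window / splice_donor_window | 8 / 20 bp | intronic-side window for criterion 1 |
| exome_filter_max / cohort_filter_max | 0.05 / 0.15 | strict greater-than exclusion (boundary passes) |
| support_reads_a, support_frac_a | 10, 0.20 | support branch 1 |
| support_reads_b, support_frac_b_lo | 5, 0.80 | support branch 2 |
| hq_rule1_reads / hq_rule2_reads (qual) | 3 / 5 (>20) | quality designation |
| phylop_benign_lt / phylop_patho_gt | 1.0 / 2.5 | conservation bands (boundaries → unknown) |
| freq_benign_gt; freq_unknown_lo–hi; cohort_unknown_ge | 0.03; 0.01–0.03; 0.03 | frequency axis bands |
| ssf_site / ssf_diff | 50 / 5 | SpliceSiteFinder (0–100 scale assumed from the 50 cutoff) |
| maxent_diff | 0.8 | MaxEntScan wt−mut loss |
| nnsplice_site / nnsplice_diff | 0.5 / 0.05 | NNSplice ([0,1] scores enforced) |
| poor_target_median_lt / near_target_bp | 5 / 500 | coverage QC |

Deliberate readings where the stated rules leave room:

- Frequency criteria are strict ("greater than"): a variant at exactly 5%
  exome or 15% cohort frequency passes prioritization; conservation and
  frequency *bands* place their boundary values in the unknown class.
- Both read-support branches read "reads" as total depth with a variant
  fraction, i.e. branch 2 is ≥ 5 total reads with ≥ 80% variant reads.
  The alternative reading (≥ 5 *variant* reads) differs only on sparse
  sites and is not used.
- The splice windows are measured on the intronic side of the exon
  boundary; the canonical ±1/±2 positions are their own effect class and
  classify pathogenic regardless of windows.
- The MaxEntScan comparison is directional (wt − mut): a mutant score
  above wild type — a splice-strength *gain* — lands in unknown, never
  pathogenic. This is prominent because it is easy to get backwards.
- The second-allele rescue relaxes only the novelty and frequency
  criteria. The search set is nominally the unfiltered calls, but effect
  and support are retained so that sequencing noise cannot be "rescued"
  into a diagnosis; quality designation is likewise upstream of
  everything, including rescue.
- A tool-level three-way split votes unknown, mirroring the stated rule
  for the final three-axis combination.
- A variant that is both missense and near a splice site uses the
  missense tool vote for its in-silico axis; the splice-tool alternative
  would only matter for the rare missense call inside a splice region.
- Compound heterozygosity at the filtering stage counts distinct
  heterozygous loci without phase; phase is resolved (trans/cis/unknown)
  later from parental genotypes and reported, matching the practice of
  listing unphased pairs when parents are unavailable.
- Raw missense scores can optionally be banded into three-state calls
  (`classify_missense_scores`; SIFT ≤ 0.05 damaging, PolyPhen ≥ 0.85 /
  ≤ 0.15, MutPred ≥ 0.75 / ≤ 0.25). These score thresholds are
  implementation conveniences — the classifier's contract consumes tool
  *classifications*, not scores.

## Coverage QC

Per-target median coverage uses the mean-of-central-pair convention for
even-length targets. The evenness score is the cumulative-coverage form

E = 100 · (1/⌈m⌉) · Σ_{i=1..⌈m⌉} P(depth ≥ i),

with m the mean depth over target bases: perfectly uniform coverage gives
exactly 100, and any non-uniform profile scores strictly below 100 (both
properties are tested, the second by brute force over random profiles).
Poor targets are those with median depth < 5. "Near-target" bases (within
500 bp of a target but inside none) are counted only when read placements
are supplied — depth tracks over targets alone cannot see them — and are
otherwise omitted from the report. Because "average coverage per exon"
can mean the mean of per-target medians or the overall per-base mean, the
report carries both.

## Segregation conventions

Penetrance is assumed complete for dominant and X-linked-male disease;
carrier females and single-het carriers of recessive alleles are
unaffected by construction. A verdict is *full* when every relative is
typed and consistent, *partial* when only a subset is typed (the boundary
is a convention: all-typed vs some-typed), *contradicted* on the first
inconsistent typed relative, *untested* with no typed relative. De novo
detection returns a three-state answer: a missing parent genotype makes
the test inconclusive rather than negative. When marker genotypes are
available for a trio, a de novo call is *confirmed* only by full Mendelian
consistency across all markers; without markers it is reported as
apparent. Haplotype reconstruction around a locus (e.g. for a deceased
parent) and X-inactivation are out of scope.

## Reporting conventions

Rounding is pinned per statistic so printed values are reproducible:
detection rate and reduction to one decimal; solved, confirmation and
projected rates as integer percent (round half up); enrichment truncated
toward zero at one decimal at ≥ 1% and rounded to two decimals below 1%
(so 20/48 prints 41.6, not 41.7, and 21/14,144 prints 0.15). The
projection rounds its intermediate patient counts to whole patients
before forming the final percentage. The true-mutation counts before and
after filtering are carried separately, because filtering can eliminate a
true mutation (enrichment numerators need not be conserved).

## The synthetic cohort generator

The generator emulates the study conditions of a 100-patient panel
screen: 111 genes over 2,011 capture targets of 250 bp; per-target
capture efficiency drawn from a gamma law around a 26× mean with
Poisson per-base depth; 15 designated poor targets forced to near-zero
coverage; a Poisson(1,274) background variant count per sample; and a
scenario mix per 100 samples of 13 recessive-homozygous, 14
compound-heterozygous, 3 dominant-inherited, 3 dominant de novo, 3
X-linked and 64 unsolved probands (the recessive/dominant/X-linked solved
split of the emulated cohort; the homozygous/compound split within
recessive was fixed once from the diagnosed-cohort composition). One
sample per cohort additionally carries a known dominant allele next to
its recessive diagnosis to exercise cumulative-load detection. Each
proband comes with a trio; dominant-inherited scenarios mark one parent
affected; de novo scenarios add a 16-marker, fully Mendelian-consistent
marker set.

Background annotations are drawn from explicit strata: 96% of calls are
dbSNP members with beta-distributed cohort frequencies (targeted capture
overwhelmingly re-discovers known polymorphisms — this is what lets the
novelty criterion do most of the filtering); novel calls are rare in both
cohorts; conservation is near-neutral with a mildly shifted missense
stratum; tool calls are drawn mostly benign/unknown; truncating
background calls occur only as dbSNP-listed annotation artifacts. Two
constructions are enforced rather than emergent, and are the load-bearing
assumptions of every recovery test: (a) planted causal variants are
built to pass all six criteria and classify pathogenic-tier, and this is
asserted after generation; (b) background variants are non-causal by
construction — any annotation draw that would classify pathogenic-tier is
redrawn — so unsolved samples cannot produce a false diagnosis by design.
The funnel *reduction* (≈ 1,274 → a handful per sample) is emergent from
the filters acting on the strata; the *absence of false positives* is
not, and passing tests accordingly demonstrate correct mechanics of the
cascade, not its specificity on real data. Real data also differ in ways
the generator does not model: no read-level errors or homopolymer indel
artifacts (non-confirmation is a truth-table flag drawn at 21%, not a
mechanism), no GC model behind the poor targets, no linkage between
loci, and annotation strata that are stylized rather than fitted.

The 12-sample validation preset plants 24 compound-heterozygous mutations
and renders three undetectable upstream of filtering — two by placing a
sample's entire pair inside the zero-coverage target, one by sub-threshold
read support (2 forward-only nonduplicate reads of 4) — which fixes the
detection rate at 21/24 and the solved rate at 10/12 for every seed.

All randomness flows from a single seed; per-sample substreams are
derived by CRC-hashing sample ids, so outputs are byte-identical across
runs and insensitive to generation order.

## Numerical and degenerate-input choices

Zero total reads fail the support filter without division; empty depth
tracks, all-zero coverage, empty cohorts and zero denominators raise
rather than return sentinels; multi-allelic VCF records are split per
alternate allele before joining; missing optional annotations are absent
(None), never zero-filled; a VCF record lacking its annotation row is an
error while an unmatched annotation row is a warning-and-skip; a sample
absent from the pedigree is triaged with the mode-union inheritance
filter and a female default for the X chromosome, with a warning.

## Problem sizes used in the test suite

The session-scoped recovery fixtures run the full default cohort (100
samples, ~1,274 background variants each, ≈ 127k variants total) and the
12-sample validation preset; both complete in well under a minute. Depth
tracks are generated in memory for these runs; per-base depth TSVs are
emitted by default and in the dedicated coverage tests, where a
2,011-target, 250 bp fixture checks the poor-target accounting.
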
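"""Independent brute-force oracles used by several test modules.

These deliberately re-derive the filtering and combination semantics from
first principles (set comprehensions over plainly restated rules) rather
than calling into the package, so that the tests compare two independent
codings of the same specification.
"""

from rptriage.types import Effect, InheritanceMode, TriClass, Zygosity

ALWAYS_PASS_EFFECTS = {
    Effect.MISSENSE,
    Effect.NONSENSE,
    Effect.FRAMESHIFT,
    Effect.INFRAME_INDEL,
    Effect.CANONICAL_SPLICE,
    Effect.LARGE_DELETION,
}
STRONG = {Effect.NONSENSE, Effect.FRAMESHIFT, Effect.CANONICAL_SPLICE}


def oracle_hq(s):
    return (
        s.nonduplicate_variant_reads >= 3
        and s.forward_variant_reads >= 1
        and s.reverse_variant_reads >= 1
    ) or s.hq_variant_reads >= 5


def oracle_effect(v):
    e = v.annot.effect
    if e in ALWAYS_PASS_EFFECTS:
        return True
    if e in (Effect.SPLICE_REGION, Effect.INTRONIC):
        a, d = v.annot.splice_acceptor_offset, v.annot.splice_donor_offset
        return (a is not None and -8 <= a <= 8) or (d is not None and -20 <= d <= 20)
    return False


def oracle_novelty(v):
    a = v.annot
    return not a.in_dbsnp130 or a.in_hgmd or a.known_blindness_mutation


def oracle_frequency(v):
    return v.annot.exome_cohort_freq <= 0.05 and v.annot.disease_cohort_freq <= 0.15


def oracle_support(s):
    if s.total_reads == 0:
        return False
    f = s.variant_reads / s.total_reads
    return (s.total_reads >= 10 and f >= 0.2) or (s.total_reads >= 5 and f >= 0.8)


def oracle_inheritance(gene_variants, modes, sex):
    kept = set()
    if InheritanceMode.AD in modes:
        kept |= {
            v.locus for v in gene_variants if v.zygosity in (Zygosity.HET, Zygosity.HOM)
        }
    if InheritanceMode.AR in modes:
        homs = {v.locus for v in gene_variants if v.zygosity is Zygosity.HOM}
        hets = {v.locus for v in gene_variants if v.zygosity is Zygosity.HET}
        if homs:
            kept |= {v.locus for v in gene_variants}
        elif len(hets) >= 2:
            kept |= hets
    if InheritanceMode.XL in modes:
        if sex == "male":
            kept |= {v.locus for v in gene_variants if v.zygosity is Zygosity.HEMI}
        else:
            homs = {v.locus for v in gene_variants if v.zygosity is Zygosity.HOM}
            hets = {v.locus for v in gene_variants if v.zygosity is Zygosity.HET}
            if homs:
                kept |= homs | hets
            elif len(hets) >= 2:
                kept |= hets
    return kept


def oracle_cascade(variants, panel, sex):
    """Full brute-force cascade: returns (set of selected loci, set of
    rescued loci)."""
    hq = [v for v in variants if oracle_hq(v.support)]
    passed = [
        v
        for v in hq
        if oracle_effect(v) and oracle_novelty(v) and oracle_frequency(v) and oracle_support(v.support)
    ]
    genes = {v.gene for v in passed}
    selected = set()
    rescued = set()
    for gene in genes:
        gv = [v for v in passed if v.gene == gene]
        modes = panel[gene].modes
        kept = oracle_inheritance(gv, modes, sex)
        selected |= kept
        # second-allele rescue: a single filtered variant in the gene, it
        # is a strong truncating/canonical-splice allele, and the gene can
        # act recessively
        if InheritanceMode.AR in modes and len(gv) == 1 and gv[0].annot.effect in STRONG:
            lone = gv[0]
            partners = {
                v.locus
                for v in hq
                if v.gene == gene
                and v.locus != lone.locus
                and oracle_effect(v)
                and oracle_support(v.support)
            }
            if partners:
                rescued |= partners
                selected |= partners | {lone.locus}
    return selected, rescued


# hand-enumerated 27-row combination table: (insilico, conservation,
# frequency) -> final class, as strings
P, U, B = "pathogenic", "unknown", "benign"
PP, UN, PB = "probably_pathogenic", "unknown", "probably_benign"
COMBINATION_TABLE = {
    (P, P, P): PP, (P, P, U): PP, (P, P, B): PB,
    (P, U, P): PP, (P, U, U): UN, (P, U, B): PB,
    (P, B, P): PP, (P, B, U): UN, (P, B, B): PB,
    (U, P, P): PP, (U, P, U): UN, (U, P, B): PB,
    (U, U, P): UN, (U, U, U): UN, (U, U, B): PB,
    (U, B, P): UN, (U, B, U): UN, (U, B, B): PB,
    (B, P, P): PP, (B, P, U): UN, (B, P, B): PB,
    (B, U, P): UN, (B, U, U): UN, (B, U, B): PB,
    (B, B, P): PB, (B, B, U): PB, (B, B, B): PB,
}


def oracle_marker_consistent(child, father, mother):
    """Exhaustive allele-partition check: the child pair must equal some
    unordered pair formed from one paternal and one maternal allele."""
    possible = {
        tuple(sorted((fa, ma))) for fa in father.alleles for ma in mother.alleles
    }
    return tuple(sorted(child.alleles)) in possible
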
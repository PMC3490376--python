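import numpy as np
import pytest

from rptriage.prioritization import (
    FunnelCounts,
    is_high_quality,
    passes_effect_filter,
    passes_frequency_filters,
    passes_inheritance_filter,
    passes_novelty_filter,
    passes_support_filter,
    prioritize_sample,
    rescue_second_allele,
)
from rptriage.types import (
    AnnotationBundle,
    Effect,
    GenePanelEntry,
    InheritanceMode,
    ReadSupport,
    Zygosity,
)

from conftest import GOOD_SUPPORT, make_variant
from oracles import oracle_cascade


def support(total, variant, nondup=None, fwd=None, rev=None, hq=None):
    nondup = variant if nondup is None else nondup
    fwd = (max(1, variant // 2) if variant else 0) if fwd is None else fwd
    rev = variant - fwd if rev is None else rev
    hq = variant if hq is None else hq
    return ReadSupport(total, variant, nondup, fwd, rev, hq)


AR = GenePanelEntry("GENE1", "chr1", frozenset({InheritanceMode.AR}))
AD = GenePanelEntry("GENE2", "chr2", frozenset({InheritanceMode.AD}))
ARAD = GenePanelEntry("GENE3", "chr3", frozenset({InheritanceMode.AR, InheritanceMode.AD}))
XL = GenePanelEntry("GENEX", "chrX", frozenset({InheritanceMode.XL}))


class TestHighQuality:
    @pytest.mark.parametrize(
        "variant,nondup,fwd,rev,hq,expected",
        [
            (3, 3, 2, 1, 0, True),   # three nonduplicate reads, both strands
            (5, 2, 1, 4, 5, True),   # five high-quality reads despite duplicates
            (4, 3, 4, 0, 4, False),  # one strand only and too few HQ reads
            (2, 2, 1, 1, 2, False),
        ],
    )
    def test_rules(self, variant, nondup, fwd, rev, hq, expected):
        s = ReadSupport(20, variant, nondup, fwd, rev, hq)
        assert is_high_quality(s) is expected


class TestEffectFilter:
    @pytest.mark.parametrize(
        "effect",
        [Effect.MISSENSE, Effect.NONSENSE, Effect.FRAMESHIFT, Effect.INFRAME_INDEL,
         Effect.CANONICAL_SPLICE, Effect.LARGE_DELETION],
    )
    def test_nonsynonymous_always_pass(self, effect):
        assert passes_effect_filter(make_variant(effect=effect))

    @pytest.mark.parametrize("effect", [Effect.SYNONYMOUS, Effect.UTR])
    def test_silent_classes_fail(self, effect):
        assert not passes_effect_filter(make_variant(effect=effect))

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            # 14 bp into the acceptor is outside the 8 bp window
            (dict(effect=Effect.INTRONIC, splice_acceptor_offset=-14), False),
            (dict(effect=Effect.INTRONIC, splice_acceptor_offset=-8), True),
            # +3 of the donor is inside the 20 bp window
            (dict(effect=Effect.INTRONIC, splice_donor_offset=3), True),
            (dict(effect=Effect.INTRONIC, splice_donor_offset=21), False),
            (dict(effect=Effect.SPLICE_REGION, splice_donor_offset=20), True),
        ],
    )
    def test_splice_windows(self, kwargs, expected):
        assert passes_effect_filter(make_variant(**kwargs)) is expected

    def test_splice_region_without_offsets_errors(self):
        with pytest.raises(ValueError, match="offsets"):
            passes_effect_filter(make_variant(effect=Effect.SPLICE_REGION))


class TestNoveltyFilter:
    @pytest.mark.parametrize(
        "dbsnp,hgmd,known,expected",
        [(False, False, False, True), (True, True, False, True),
         (True, False, True, True), (True, False, False, False)],
    )
    def test_dbsnp_exception_rules(self, dbsnp, hgmd, known, expected):
        v = make_variant(in_dbsnp130=dbsnp, in_hgmd=hgmd, known_blindness_mutation=known)
        assert passes_novelty_filter(v) is expected


class TestFrequencyFilters:
    @pytest.mark.parametrize(
        "exome,cohort,expected",
        [(0.04, 0.10, True), (0.06, 0.01, False), (0.05, 0.15, True),
         (0.01, 0.16, False)],
    )
    def test_strict_greater_than_bounds(self, exome, cohort, expected):
        v = make_variant(exome_cohort_freq=exome, disease_cohort_freq=cohort)
        assert passes_frequency_filters(v) is expected


class TestSupportFilter:
    @pytest.mark.parametrize(
        "total,variant,expected",
        [(10, 2, True), (5, 4, True), (9, 5, False), (4, 4, False), (0, 0, False),
         (10, 1, False), (5, 5, True)],
    )
    def test_two_branches(self, total, variant, expected):
        assert passes_support_filter(support(total, variant)) is expected


class TestInheritanceFilter:
    def test_single_het_in_recessive_gene_dropped(self):
        v = make_variant(gene="GENE1")
        assert passes_inheritance_filter([v], AR) == []

    def test_compound_het_pair_kept(self):
        v1 = make_variant(gene="GENE1", pos=100)
        v2 = make_variant(gene="GENE1", pos=200)
        assert passes_inheritance_filter([v1, v2], AR) == [v1, v2]

    def test_hom_in_recessive_gene_kept(self):
        v = make_variant(gene="GENE1", zygosity=Zygosity.HOM)
        assert passes_inheritance_filter([v], AR) == [v]

    def test_het_in_dominant_gene_kept(self):
        v = make_variant(gene="GENE2")
        assert passes_inheritance_filter([v], AD) == [v]

    def test_xlinked_male_requires_hemizygous(self):
        hemi = make_variant(gene="GENEX", chrom="chrX", zygosity=Zygosity.HEMI)
        het = make_variant(gene="GENEX", chrom="chrX", pos=2000)
        assert passes_inheritance_filter([hemi, het], XL, sex="male") == [hemi]

    def test_xlinked_female_requires_two_alleles(self):
        het = make_variant(gene="GENEX", chrom="chrX")
        assert passes_inheritance_filter([het], XL, sex="female") == []
        het2 = make_variant(gene="GENEX", chrom="chrX", pos=3000)
        assert passes_inheritance_filter([het, het2], XL, sex="female") == [het, het2]

    def test_multi_mode_gene_keeps_union(self):
        v = make_variant(gene="GENE3")
        assert passes_inheritance_filter([v], ARAD) == [v]  # kept via AD


class TestRescue:
    def _nonsense(self, **kw):
        return make_variant(gene="GENE1", effect=Effect.NONSENSE, **kw)

    def test_dbsnp_partner_rescued_for_lone_nonsense(self):
        lone = self._nonsense(pos=100)
        partner = make_variant(gene="GENE1", pos=200, in_dbsnp130=True)
        got = rescue_second_allele([lone], [lone, partner], AR)
        assert [v.locus for v in got] == [partner.locus]
        assert got[0].rescued

    def test_missense_survivor_triggers_no_rescue(self):
        lone = make_variant(gene="GENE1", pos=100)
        partner = make_variant(gene="GENE1", pos=200, in_dbsnp130=True)
        assert rescue_second_allele([lone], [lone, partner], AR) == []

    def test_no_other_variants_yields_empty(self):
        lone = self._nonsense(pos=100)
        assert rescue_second_allele([lone], [lone], AR) == []

    def test_dominant_only_gene_never_rescued(self):
        lone = make_variant(gene="GENE2", effect=Effect.NONSENSE, pos=100)
        partner = make_variant(gene="GENE2", pos=200, in_dbsnp130=True)
        assert rescue_second_allele([lone], [lone, partner], AD) == []

    def test_rescue_retains_effect_and_support_criteria(self):
        lone = self._nonsense(pos=100)
        silent = make_variant(gene="GENE1", pos=200, effect=Effect.SYNONYMOUS)
        weak = make_variant(gene="GENE1", pos=300, support=support(4, 2, fwd=1, rev=1, hq=2))
        got = rescue_second_allele([lone], [lone, silent, weak], AR)
        assert got == []


def _random_variant(rng, genes, panel):
    gene = genes[rng.integers(len(genes))]
    entry = panel[gene]
    effect = [
        Effect.MISSENSE, Effect.NONSENSE, Effect.SYNONYMOUS, Effect.INTRONIC,
        Effect.SPLICE_REGION, Effect.FRAMESHIFT, Effect.UTR,
    ][rng.integers(7)]
    kwargs = {}
    if effect in (Effect.INTRONIC, Effect.SPLICE_REGION):
        if rng.random() < 0.5:
            kwargs["splice_acceptor_offset"] = -int(rng.integers(1, 30))
        else:
            kwargs["splice_donor_offset"] = int(rng.integers(1, 40))
    if entry.chrom == "chrX":
        zyg = [Zygosity.HEMI, Zygosity.HET, Zygosity.HOM][rng.integers(3)]
    else:
        zyg = [Zygosity.HET, Zygosity.HET, Zygosity.HOM][rng.integers(3)]
    total = int(rng.integers(0, 40))
    variant = int(rng.integers(0, total + 1))
    fwd = int(rng.integers(0, variant + 1))
    return make_variant(
        gene=gene,
        chrom=entry.chrom,
        pos=int(rng.integers(1, 10_000_000)),
        zygosity=zyg,
        effect=effect,
        support=ReadSupport(
            total, variant, int(rng.integers(0, variant + 1)), fwd, variant - fwd,
            int(rng.integers(0, variant + 1)),
        ),
        in_dbsnp130=bool(rng.random() < 0.5),
        in_hgmd=bool(rng.random() < 0.2),
        known_blindness_mutation=bool(rng.random() < 0.1),
        exome_cohort_freq=float(rng.choice([0.0, 0.01, 0.05, 0.06, 0.2])),
        disease_cohort_freq=float(rng.choice([0.0, 0.05, 0.15, 0.16])),
        **kwargs,
    )


class TestCascade:
    PANEL = {"GENE1": AR, "GENE2": AD, "GENE3": ARAD, "GENEX": XL}

    def test_empty_sample(self):
        shortlist, funnel = prioritize_sample([], self.PANEL, None)
        assert shortlist == []
        assert funnel == FunnelCounts(0, 0, 0, 0, 0)

    def test_matches_brute_force_oracle_on_random_tables(self):
        """Cascade output must equal an independently coded truth-table
        evaluation of the six criteria plus rescue."""
        rng = np.random.default_rng(123)
        genes = list(self.PANEL)
        for trial in range(200):
            sex = "male" if rng.random() < 0.5 else "female"
            n = int(rng.integers(1, 14))
            variants = [_random_variant(rng, genes, self.PANEL) for _ in range(n)]
            # de-duplicate loci
            seen, unique = set(), []
            for v in variants:
                if v.locus.key() not in seen:
                    seen.add(v.locus.key())
                    unique.append(v)
            expected_sel, expected_resc = oracle_cascade(unique, self.PANEL, sex)
            member = None
            shortlist, funnel = prioritize_sample(
                unique, self.PANEL, _member(sex), None
            )
            got_sel = {v.locus for v in shortlist}
            got_resc = {v.locus for v in shortlist if v.rescued}
            assert got_sel == expected_sel, f"trial {trial}"
            assert got_resc == expected_resc, f"trial {trial}"
            assert funnel.n_selected == len(shortlist)

    def test_funnel_counts_are_monotone_and_rescue_only_adds(self):
        rng = np.random.default_rng(77)
        genes = list(self.PANEL)
        for _ in range(50):
            variants = [_random_variant(rng, genes, self.PANEL) for _ in range(10)]
            shortlist, funnel = prioritize_sample(variants, self.PANEL, _member("female"))
            assert funnel.n_auto_detected >= funnel.n_after_effect_novelty_frequency
            assert funnel.n_after_effect_novelty_frequency >= funnel.n_after_inheritance
            assert funnel.n_after_rescue >= funnel.n_after_inheritance
            assert {v.locus for v in shortlist} >= {
                v.locus for v in shortlist if not v.rescued
            }

    def test_shortlist_is_sorted_and_deterministic(self):
        rng = np.random.default_rng(5)
        variants = [_random_variant(rng, list(self.PANEL), self.PANEL) for _ in range(30)]
        s1, _ = prioritize_sample(variants, self.PANEL, _member("female"))
        s2, _ = prioritize_sample(list(reversed(variants)), self.PANEL, _member("female"))
        assert [v.locus for v in s1] == [v.locus for v in s2]
        keys = [v.sort_key() for v in s1]
        assert keys == sorted(keys)

    def test_sample_missing_from_pedigree_warns_and_runs(self):
        v = make_variant(gene="GENE2")
        with pytest.warns(UserWarning, match="absent from pedigree"):
            shortlist, _ = prioritize_sample([v], self.PANEL, None)
        assert shortlist == [v]


def _member(sex):
    from rptriage.types import PedigreeMember

    return PedigreeMember("S1", "F1", sex, True)
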
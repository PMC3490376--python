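import numpy as np
import pytest

from rptriage.segregation import (
    SegregationStatus,
    check_segregation,
    check_trans_phase,
    detect_de_novo,
    detect_multilocus,
    mendelian_consistency,
    variant_origin,
)
from rptriage.types import (
    Family,
    FinalClass,
    Genotype,
    GenePanelEntry,
    InheritanceMode,
    MarkerGenotype,
    PedigreeMember,
    VariantLocus,
    Zygosity,
)

from conftest import make_variant
from oracles import oracle_marker_consistent

L1 = VariantLocus("chr1", 100, "A", "G")
L2 = VariantLocus("chr1", 900, "C", "T")


def trio(child_sex="female", child_affected=True):
    fam = Family("F1")
    fam.add(PedigreeMember("DAD", "F1", "male", False))
    fam.add(PedigreeMember("MOM", "F1", "female", False))
    fam.add(
        PedigreeMember("KID", "F1", child_sex, child_affected, father_id="DAD", mother_id="MOM")
    )
    return fam


def set_gt(fam, individual, gts):
    fam.members[individual].genotypes.update(gts)


class TestCheckSegregation:
    def test_classic_recessive_trio_fully_segregates(self):
        fam = trio()
        set_gt(fam, "KID", {L1: Genotype.HOM_ALT})
        set_gt(fam, "DAD", {L1: Genotype.HET})
        set_gt(fam, "MOM", {L1: Genotype.HET})
        v = check_segregation([L1], fam, "KID", InheritanceMode.AR)
        assert v.status is SegregationStatus.FULL

    def test_dominant_variant_in_unaffected_sibling_contradicts(self):
        fam = trio()
        fam.add(PedigreeMember("SIB", "F1", "male", False, father_id="DAD", mother_id="MOM"))
        set_gt(fam, "KID", {L1: Genotype.HET})
        set_gt(fam, "DAD", {L1: Genotype.HET})
        fam.members["DAD"].affected = True
        set_gt(fam, "MOM", {L1: Genotype.REF_REF})
        set_gt(fam, "SIB", {L1: Genotype.HET})
        v = check_segregation([L1], fam, "KID", InheritanceMode.AD)
        assert v.status is SegregationStatus.CONTRADICTED

    def test_no_relatives_is_untested(self):
        fam = Family("F1")
        fam.add(PedigreeMember("KID", "F1", "female", True))
        fam.members["KID"].genotypes[L1] = Genotype.HOM_ALT
        v = check_segregation([L1], fam, "KID", InheritanceMode.AR)
        assert v.status is SegregationStatus.UNTESTED

    def test_untyped_relative_degrades_full_to_partial(self):
        fam = trio()
        set_gt(fam, "KID", {L1: Genotype.HOM_ALT})
        set_gt(fam, "DAD", {L1: Genotype.HET})
        # MOM left untyped
        v = check_segregation([L1], fam, "KID", InheritanceMode.AR)
        assert v.status is SegregationStatus.PARTIAL

    def test_one_inconsistent_relative_contradicts_despite_others(self):
        fam = trio()
        set_gt(fam, "KID", {L1: Genotype.HOM_ALT})
        set_gt(fam, "DAD", {L1: Genotype.HET})
        set_gt(fam, "MOM", {L1: Genotype.HOM_ALT})  # unaffected biallelic carrier
        v = check_segregation([L1], fam, "KID", InheritanceMode.AR)
        assert v.status is SegregationStatus.CONTRADICTED

    def test_compound_het_recessive_uses_both_loci(self):
        fam = trio()
        set_gt(fam, "KID", {L1: Genotype.HET, L2: Genotype.HET})
        set_gt(fam, "DAD", {L1: Genotype.HET, L2: Genotype.REF_REF})
        set_gt(fam, "MOM", {L1: Genotype.REF_REF, L2: Genotype.HET})
        v = check_segregation([L1, L2], fam, "KID", InheritanceMode.AR)
        assert v.status is SegregationStatus.FULL

    def test_xlinked_trio_with_carrier_mother(self):
        fam = trio(child_sex="male")
        lx = VariantLocus("chrX", 100, "A", "G")
        set_gt(fam, "KID", {lx: Genotype.HEMI_ALT})
        set_gt(fam, "MOM", {lx: Genotype.HET})
        set_gt(fam, "DAD", {lx: Genotype.REF_REF})
        v = check_segregation([lx], fam, "KID", InheritanceMode.XL)
        assert v.status is SegregationStatus.FULL

    def test_mode_incompatible_with_panel_entry_rejected(self):
        fam = trio()
        entry = GenePanelEntry("G1", "chr1", frozenset({InheritanceMode.AR}))
        with pytest.raises(ValueError, match="not allowed"):
            check_segregation([L1], fam, "KID", InheritanceMode.AD, entry)

    def test_de_novo_locus_recorded(self):
        fam = trio()
        set_gt(fam, "KID", {L1: Genotype.HET})
        set_gt(fam, "DAD", {L1: Genotype.REF_REF})
        set_gt(fam, "MOM", {L1: Genotype.REF_REF})
        v = check_segregation([L1], fam, "KID", InheritanceMode.AD)
        assert v.de_novo_loci == [L1]


class TestDeNovo:
    def test_child_het_parents_ref_is_de_novo(self):
        assert detect_de_novo(Genotype.HET, Genotype.REF_REF, Genotype.REF_REF) is True

    def test_inherited_from_mother_is_not(self):
        assert detect_de_novo(Genotype.HET, Genotype.REF_REF, Genotype.HET) is False

    def test_missing_parent_is_untestable(self):
        assert detect_de_novo(Genotype.HET, Genotype.MISSING, Genotype.REF_REF) is None

    def test_missing_parent_with_carrier_other_parent_is_inherited(self):
        assert detect_de_novo(Genotype.HET, Genotype.MISSING, Genotype.HET) is False

    def test_child_without_allele_is_not_de_novo(self):
        assert detect_de_novo(Genotype.REF_REF, Genotype.REF_REF, Genotype.REF_REF) is False

    def test_symmetric_in_parents(self):
        gts = [Genotype.REF_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.MISSING]
        for f in gts:
            for m in gts:
                assert detect_de_novo(Genotype.HET, f, m) == detect_de_novo(
                    Genotype.HET, m, f
                )

    def test_false_whenever_a_parent_carries(self):
        carriers = [Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI_ALT]
        others = list(Genotype)
        for c in carriers:
            for o in others:
                assert detect_de_novo(Genotype.HET, c, o) is False
                assert detect_de_novo(Genotype.HET, o, c) is False


def random_marker(rng, mid, n_alleles=6):
    pool = [f"a{i}" for i in range(n_alleles)]
    return MarkerGenotype(mid, pool[rng.integers(n_alleles)], pool[rng.integers(n_alleles)])


class TestMendelianConsistency:
    def test_sixteen_consistent_markers_confirm(self):
        child, father, mother = [], [], []
        rng = np.random.default_rng(9)
        for k in range(16):
            fa = random_marker(rng, f"M{k}")
            mo = random_marker(rng, f"M{k}")
            child.append(MarkerGenotype(f"M{k}", fa.allele1, mo.allele2))
            father.append(fa)
            mother.append(mo)
        assert mendelian_consistency(child, father, mother) == (16, 16, True)

    def test_single_inconsistency_refutes(self):
        father = [MarkerGenotype("M0", "a1", "a1")]
        mother = [MarkerGenotype("M0", "a2", "a2")]
        child = [MarkerGenotype("M0", "a3", "a2")]  # paternal allele impossible
        assert mendelian_consistency(child, father, mother) == (0, 1, False)

    def test_consistent_example(self):
        father = [MarkerGenotype("M0", "A", "C")]
        mother = [MarkerGenotype("M0", "B", "D")]
        child = [MarkerGenotype("M0", "A", "B")]
        assert mendelian_consistency(child, father, mother)[2] is True

    def test_matches_exhaustive_partition_oracle_on_random_trios(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 6))
            father = [random_marker(rng, f"M{k}", 4) for k in range(n)]
            mother = [random_marker(rng, f"M{k}", 4) for k in range(n)]
            child = [random_marker(rng, f"M{k}", 4) for k in range(n)]
            cons, total, confirmed = mendelian_consistency(child, father, mother)
            expected = [
                oracle_marker_consistent(c, f, m)
                for c, f, m in zip(child, father, mother)
            ]
            assert total == n
            assert cons == sum(expected)
            assert confirmed == all(expected)


class TestTransPhase:
    def test_maternal_plus_de_novo_is_trans(self):
        fam = trio()
        set_gt(fam, "KID", {L1: Genotype.HET, L2: Genotype.HET})
        set_gt(fam, "MOM", {L1: Genotype.HET, L2: Genotype.REF_REF})
        set_gt(fam, "DAD", {L1: Genotype.REF_REF, L2: Genotype.REF_REF})
        assert variant_origin(fam, "KID", L1) == "maternal"
        assert variant_origin(fam, "KID", L2) == "de_novo"
        assert check_trans_phase(fam, "KID", L1, L2) == "trans"

    def test_both_from_father_is_cis(self):
        fam = trio()
        set_gt(fam, "DAD", {L1: Genotype.HET, L2: Genotype.HET})
        set_gt(fam, "MOM", {L1: Genotype.REF_REF, L2: Genotype.REF_REF})
        assert check_trans_phase(fam, "KID", L1, L2) == "cis"

    def test_parents_unavailable_is_unknown(self):
        fam = Family("F1")
        fam.add(PedigreeMember("KID", "F1", "female", True))
        assert check_trans_phase(fam, "KID", L1, L2) == "unknown"

    def test_untyped_parent_is_unknown(self):
        fam = trio()
        set_gt(fam, "DAD", {L1: Genotype.HET})
        # L2 untyped in both parents
        assert check_trans_phase(fam, "KID", L1, L2) == "unknown"


class TestMultilocus:
    PANEL = {
        "PDE6B_LIKE": GenePanelEntry(
            "PDE6B_LIKE", "chr4", frozenset({InheritanceMode.AR, InheritanceMode.AD})
        ),
        "PRPH2_LIKE": GenePanelEntry("PRPH2_LIKE", "chr6", frozenset({InheritanceMode.AD})),
    }

    def _hom_splice(self):
        from rptriage.types import Effect

        return make_variant(
            gene="PDE6B_LIKE", chrom="chr4", zygosity=Zygosity.HOM,
            effect=Effect.CANONICAL_SPLICE, splice_donor_offset=2,
        )

    def _het_missense(self):
        return make_variant(gene="PRPH2_LIKE", chrom="chr6", pos=5000)

    def test_two_gene_pathogenic_sample_flagged(self):
        sample = {
            "S9472": [
                (self._hom_splice(), FinalClass.PATHOGENIC),
                (self._het_missense(), FinalClass.PROBABLY_PATHOGENIC),
            ]
        }
        assert detect_multilocus(sample, self.PANEL) == [
            ("S9472", ["PDE6B_LIKE", "PRPH2_LIKE"])
        ]

    def test_single_gene_not_flagged(self):
        sample = {"S1": [(self._hom_splice(), FinalClass.PATHOGENIC)]}
        assert detect_multilocus(sample, self.PANEL) == []

    def test_unknown_class_in_second_gene_not_flagged(self):
        sample = {
            "S1": [
                (self._hom_splice(), FinalClass.PATHOGENIC),
                (self._het_missense(), FinalClass.UNKNOWN),
            ]
        }
        assert detect_multilocus(sample, self.PANEL) == []

    def test_inheritance_inconsistent_second_gene_not_flagged(self):
        # a single het in a recessive-only gene is not a qualifying dose
        panel = dict(self.PANEL)
        panel["USH2A_LIKE"] = GenePanelEntry("USH2A_LIKE", "chr1", frozenset({InheritanceMode.AR}))
        sample = {
            "S1": [
                (self._hom_splice(), FinalClass.PATHOGENIC),
                (make_variant(gene="USH2A_LIKE", pos=777), FinalClass.PROBABLY_PATHOGENIC),
            ]
        }
        assert detect_multilocus(sample, panel) == []
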
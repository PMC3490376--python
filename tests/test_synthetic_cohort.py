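import dataclasses
import filecmp
import math

import numpy as np
import pytest

from rptriage import panel_io
from rptriage.classification import classify_variant
from rptriage.coverage_qc import DepthTrack, flag_poor_targets, target_median_coverage
from rptriage.prioritization import (
    is_high_quality,
    passes_effect_filter,
    passes_frequency_filters,
    passes_novelty_filter,
    passes_support_filter,
)
from rptriage.segregation import mendelian_consistency
from rptriage.synthetic_cohort import (
    SimulationConfig,
    plant_de_novo,
    read_truth,
    simulate_cohort,
    validation_fixture_config,
)
from rptriage.types import Family, InheritanceMode, PedigreeMember


SMALL = SimulationConfig(
    seed=5,
    n_samples=6,
    n_genes=20,
    n_targets=120,
    mean_background_variants=60.0,
    poor_target_count=3,
    scenario_mix={
        "AR_hom": 1 / 6,
        "AR_compound_het": 1 / 6,
        "AD_inherited": 1 / 6,
        "AD_de_novo": 1 / 6,
        "XL": 1 / 6,
        "unsolved": 1 / 6,
    },
    n_multilocus=1,
    emit_depth=True,
    target_length=60,
)


@pytest.fixture(scope="module")
def small_cohort(tmp_path_factory):
    out = tmp_path_factory.mktemp("small")
    truth = simulate_cohort(SMALL, out)
    return out, truth


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = dataclasses.replace(SMALL, n_samples=3)
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        simulate_cohort(cfg, d1)
        simulate_cohort(cfg, d2)
        names = sorted(p.name for p in d1.iterdir())
        assert names == sorted(p.name for p in d2.iterdir())
        for name in names:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_different_seed_changes_variants(self, tmp_path):
        c1 = dataclasses.replace(SMALL, n_samples=2, emit_depth=False)
        c2 = dataclasses.replace(c1, seed=99)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(c1, d1)
        simulate_cohort(c2, d2)
        assert (d1 / "S001.annot.tsv").read_text() != (d2 / "S001.annot.tsv").read_text()


class TestScenarioConstruction:
    def test_compound_het_scenario_plants_trans_phased_pair(self, tmp_path):
        cfg = dataclasses.replace(
            SMALL, n_samples=5, scenario_mix={"AR_compound_het": 1.0}, emit_depth=False,
            n_multilocus=0,
        )
        truth = simulate_cohort(cfg, tmp_path)
        genotypes = panel_io.read_family_genotypes(tmp_path / "relative_genotypes.tsv")
        for t in truth:
            assert t.scenario == "AR_compound_het"
            assert len(t.planted) == 2
            assert len({p.gene for p in t.planted}) == 1
            assert all(p.zygosity == "het" for p in t.planted)
            # one allele per parent (trans phase via the pedigree)
            l1, l2 = (p.locus() for p in t.planted)
            dad = genotypes[(t.family_id, f"{t.sample_id}-F")]
            mom = genotypes[(t.family_id, f"{t.sample_id}-M")]
            carried_by_dad = {l for l in (l1, l2) if dad[l].carries_alt()}
            carried_by_mom = {l for l in (l1, l2) if mom[l].carries_alt()}
            assert carried_by_dad and carried_by_mom
            assert carried_by_dad.isdisjoint(carried_by_mom)

    def test_planted_causal_variants_pass_all_filters_and_classify(self, small_cohort):
        out, truth = small_cohort
        panel = {e.gene: e for e in panel_io.read_panel(out / "panel.tsv")}
        for t in truth:
            detectable = {p.locus().key() for p in t.planted if p.detectable}
            if not detectable:
                continue
            variants = panel_io.read_variants(
                out / f"{t.sample_id}.vcf",
                out / f"{t.sample_id}.support.tsv",
                out / f"{t.sample_id}.annot.tsv",
            )
            by_key = {v.locus.key(): v for v in variants}
            for key in detectable:
                v = by_key[key]
                assert is_high_quality(v.support)
                assert passes_effect_filter(v)
                assert passes_novelty_filter(v)
                assert passes_frequency_filters(v)
                assert passes_support_filter(v.support)
                assert classify_variant(v).is_pathogenic_tier()
                assert v.gene in panel

    def test_de_novo_marker_sets_always_mendelian_consistent(self, small_cohort):
        out, truth = small_cohort
        markers = panel_io.read_markers(out / "markers.tsv")
        de_novo_families = {
            (t.family_id, t.sample_id) for t in truth if t.scenario == "AD_de_novo"
        }
        assert de_novo_families
        for fid, sid in de_novo_families:
            child = markers[(fid, sid)]
            father = markers[(fid, f"{sid}-F")]
            mother = markers[(fid, f"{sid}-M")]
            assert len(child) == SMALL.de_novo_marker_count
            assert mendelian_consistency(child, father, mother) == (16, 16, True)

    def test_truth_round_trip(self, small_cohort):
        out, truth = small_cohort
        loaded = read_truth(out / "truth.json")
        assert loaded == truth


class TestDegradation:
    def test_poor_targets_flagged_by_coverage_qc(self, small_cohort):
        out, _ = small_cohort
        tracks = [
            DepthTrack.from_list(rid, depths)
            for rid, depths in panel_io.read_depth(out / "S001.depth.tsv").items()
        ]
        medians = {t.region_id: target_median_coverage(t) for t in tracks}
        assert len(flag_poor_targets(medians)) == SMALL.poor_target_count

    def test_planted_mutation_in_degraded_target_absent_from_vcf(self, tmp_path):
        cfg = dataclasses.replace(validation_fixture_config(seed=3), emit_depth=False)
        truth = simulate_cohort(cfg, tmp_path)
        dropped = [
            (t, p)
            for t in truth
            for p in t.planted
            if p.drop_reason == "degraded_target"
        ]
        assert len(dropped) == 2
        for t, p in dropped:
            variants = panel_io.read_variants(
                tmp_path / f"{t.sample_id}.vcf",
                tmp_path / f"{t.sample_id}.support.tsv",
                tmp_path / f"{t.sample_id}.annot.tsv",
            )
            assert p.locus().key() not in {v.locus.key() for v in variants}

    def test_low_support_mutation_emitted_but_not_high_quality(self, tmp_path):
        cfg = dataclasses.replace(validation_fixture_config(seed=3), emit_depth=False)
        truth = simulate_cohort(cfg, tmp_path / "v")
        weak = [
            (t, p) for t in truth for p in t.planted if p.drop_reason == "low_support"
        ]
        assert len(weak) == 1
        t, p = weak[0]
        variants = panel_io.read_variants(
            tmp_path / "v" / f"{t.sample_id}.vcf",
            tmp_path / "v" / f"{t.sample_id}.support.tsv",
            tmp_path / "v" / f"{t.sample_id}.annot.tsv",
        )
        v = {x.locus.key(): x for x in variants}[p.locus().key()]
        assert not is_high_quality(v.support)
        assert not passes_support_filter(v.support)

    def test_zero_poor_targets_leaves_tracks_unchanged(self):
        from rptriage.synthetic_cohort import degrade_targets

        rng = np.random.default_rng(1)
        tracks = {"t0": rng.poisson(20, 50)}
        assert degrade_targets(tracks, [], rng)["t0"] is tracks["t0"]


class TestBackgroundLaw:
    def test_mean_background_count_matches_configured_law(self, cohort100):
        """On the default 100-sample cohort the mean background count must
        sit within 3 standard errors of the configured mean of 1,274."""
        _, truth, _ = cohort100
        counts = [t.n_background for t in truth]
        se = math.sqrt(1274.0 / len(counts))
        assert abs(np.mean(counts) - 1274.0) < 3 * se

    def test_scenario_allocation_matches_mix(self, cohort100):
        _, truth, _ = cohort100
        from collections import Counter

        c = Counter(t.scenario for t in truth)
        assert c == {
            "AR_hom": 13, "AR_compound_het": 14, "AD_inherited": 3,
            "AD_de_novo": 3, "XL": 3, "unsolved": 64,
        }


class TestPlantDeNovo:
    def _targets(self):
        cfg = dataclasses.replace(SMALL, n_genes=4, n_targets=8)
        from rptriage.synthetic_cohort import _build_panel, _build_targets

        rng = np.random.default_rng(0)
        panel = _build_panel(cfg, rng)
        targets = _build_targets(cfg, panel)
        by_gene = {}
        for t in targets:
            by_gene.setdefault(t.gene, []).append(t)
        return panel, by_gene

    def test_single_parent_family_rejected(self):
        panel, by_gene = self._targets()
        fam = Family("F1")
        fam.add(PedigreeMember("MOM", "F1", "female", False))
        fam.add(PedigreeMember("KID", "F1", "male", True, mother_id="MOM"))
        entry = next(e for e in panel if InheritanceMode.AD in e.modes or True)
        with pytest.raises(ValueError, match="trio"):
            plant_de_novo(fam, entry, by_gene, np.random.default_rng(1), set())

    def test_recessive_mode_plants_maternal_plus_de_novo(self):
        panel, by_gene = self._targets()
        fam = Family("F1")
        fam.add(PedigreeMember("DAD", "F1", "male", False))
        fam.add(PedigreeMember("MOM", "F1", "female", False))
        fam.add(PedigreeMember("KID", "F1", "female", True, father_id="DAD", mother_id="MOM"))
        entry = next(e for e in panel if e.chrom != "chrX")
        planted, genotypes, markers = plant_de_novo(
            fam, entry, by_gene, np.random.default_rng(2), set(), mode=InheritanceMode.AR
        )
        assert len(planted) == 2
        assert sorted(p.de_novo for p in planted) == [False, True]
        inherited = next(p for p in planted if not p.de_novo)
        assert genotypes["MOM"][inherited.locus()].carries_alt()
        assert mendelian_consistency(markers["KID"], markers["DAD"], markers["MOM"])[2]
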
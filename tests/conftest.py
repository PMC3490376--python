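import pytest

from rptriage.config import ThresholdConfig
from rptriage.types import (
    AnnotatedVariant,
    AnnotationBundle,
    Effect,
    ReadSupport,
    VariantLocus,
    Zygosity,
)


GOOD_SUPPORT = ReadSupport(
    total_reads=30,
    variant_reads=15,
    nonduplicate_variant_reads=15,
    forward_variant_reads=8,
    reverse_variant_reads=7,
    hq_variant_reads=15,
)


def make_variant(
    gene="GENE1",
    chrom="chr1",
    pos=1000,
    ref="A",
    alt="G",
    zygosity=Zygosity.HET,
    effect=Effect.MISSENSE,
    support=GOOD_SUPPORT,
    sample_id="S1",
    **annot_kwargs,
):
    """Build a fully annotated variant with sensible defaults."""
    annot = AnnotationBundle(effect=effect, **annot_kwargs)
    return AnnotatedVariant(
        locus=VariantLocus(chrom, pos, ref, alt),
        gene=gene,
        zygosity=zygosity,
        support=support,
        annot=annot,
        sample_id=sample_id,
    )


@pytest.fixture(scope="session")
def cfg():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def cohort100(tmp_path_factory):
    """A full-size default cohort (100 samples, ~1,274 background variants
    each) simulated once per session, with the pipeline run over it."""
    from rptriage.pipeline import run_cohort
    from rptriage.synthetic_cohort import SimulationConfig, simulate_cohort

    out = tmp_path_factory.mktemp("cohort100")
    cfg = SimulationConfig(seed=20, emit_depth=False)
    truth = simulate_cohort(cfg, out)
    results = run_cohort(out)
    return out, truth, results


@pytest.fixture(scope="session")
def validation_fixture(tmp_path_factory):
    """The 12-sample validation cohort with 24 planted mutations, 3 of
    which are rendered undetectable upstream of filtering."""
    import dataclasses

    from rptriage.pipeline import run_cohort
    from rptriage.synthetic_cohort import simulate_cohort, validation_fixture_config

    out = tmp_path_factory.mktemp("valfix")
    cfg = dataclasses.replace(validation_fixture_config(seed=20), emit_depth=False)
    truth = simulate_cohort(cfg, out)
    results = run_cohort(out)
    return out, truth, results
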
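import pytest

from rcdpburden import (
    ClinicalStatus,
    Consequence,
    PolyphenCall,
    RunConfig,
    SiftCall,
    VariantRecord,
    build_default_table,
    paper_like_spec,
    write_fixture_bundle,
)
from rcdpburden.synthetic_data import restriction_interval


def make_variant(**overrides) -> VariantRecord:
    """A valid missense record with concordant damaging predictions."""
    base = dict(
        variant_id="rs0001",
        gene="GENE_A",
        chrom="1",
        pos=1000,
        ref="A",
        alt="T",
        consequence=Consequence.MISSENSE,
        sift_call=SiftCall.DELETERIOUS,
        polyphen_call=PolyphenCall.DAMAGING,
        clinical_status=ClinicalStatus.UNREPORTED,
        allele_count=5,
        allele_number=250_000,
        dataset="US-sim",
    )
    base.update(overrides)
    return VariantRecord(**base)


@pytest.fixture(scope="session")
def default_table():
    return build_default_table()


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Synthetic five-gene bundle plus its matching RunConfig."""
    out = tmp_path_factory.mktemp("bundle")
    spec = paper_like_spec(seed=7)
    paths = write_fixture_bundle(spec, out)
    restr = {
        g.symbol: dict(zip(("chrom", "start", "end"), restriction_interval(spec, g)))
        for g in spec.genes
        if g.restriction_fraction is not None
    }
    config = RunConfig.from_mapping(
        {
            "genes": [g.symbol for g in spec.genes],
            "dataset_region": {r.label: r.label for r in spec.regions},
            "populations": {r.label: r.population for r in spec.regions},
            "region_restrictions": restr,
        }
    )
    return {"spec": spec, "paths": paths, "config": config}
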
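import pytest

from pdburden.catalog import default_catalog
from pdburden.fixture import paper_cohort
from pdburden.io import write_cnv_table, write_manifest, write_vcf


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def fixture_cohort():
    return paper_cohort()


@pytest.fixture(scope="session")
def control_carriers(fixture_cohort):
    """variant key -> number of control carriers in the reference cohort."""
    ctrl = {s.id for s in fixture_cohort.manifest.controls}
    counts = {}
    for c in fixture_cohort.calls:
        if c.subject_id in ctrl:
            counts[c.key] = counts.get(c.key, 0) + 1
    return counts


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory, fixture_cohort):
    """The reference cohort written to disk as VCF + manifest + CNV table."""
    d = tmp_path_factory.mktemp("bundle")
    fx = fixture_cohort
    write_vcf(fx.variants, fx.calls, [s.id for s in fx.manifest.subjects], d / "cohort.vcf")
    write_manifest(fx.manifest, d / "manifest.tsv")
    write_cnv_table(fx.cnv_events, d / "cnv.tsv")
    return d
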
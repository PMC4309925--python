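from pathlib import Path

import pytest

import biodivlink as b

DATA_DIR = Path(__file__).parent / "data"

#: The default study conditions: three gut samples, one marker gene,
#: unpooled sequencing, per-sample primer pairs.
DEFAULT_SPEC = b.FixtureSpec(n_samples=3, genes_per_sample=1, seed=42)

#: Grid of fixture conditions exercised by conformance and oracle tests.
SPEC_GRID = [
    b.FixtureSpec(n, g, multiplexed=m, shared_primers=s, seed=42)
    for n in (1, 3, 10)
    for g in (1, 2)
    for m in (True, False)
    for s in (True, False)
]


@pytest.fixture(scope="session")
def vocab():
    return b.load_core_terms()


@pytest.fixture(scope="session")
def axioms(vocab):
    return b.build_axioms(vocab)


@pytest.fixture(scope="session")
def checklist():
    return b.load_checklist()


@pytest.fixture(scope="session")
def archive_factory(tmp_path_factory):
    """Generate (and cache) a synthetic archive directory per FixtureSpec."""
    cache: dict[b.FixtureSpec, Path] = {}

    def make(spec: b.FixtureSpec) -> Path:
        if spec not in cache:
            out = tmp_path_factory.mktemp(f"archive-{spec.archive_id}")
            cache[spec] = b.generate_survey_archive(spec, out)
        return cache[spec]

    return make


@pytest.fixture(scope="session")
def workflow_factory(archive_factory):
    """Parsed assay workflow graph for a FixtureSpec."""
    cache = {}

    def make(spec: b.FixtureSpec) -> b.WorkflowGraph:
        if spec not in cache:
            archive = b.read_archive(archive_factory(spec))
            cache[spec] = b.build_workflow_graph(archive.assay_tables[0])
        return cache[spec]

    return make


@pytest.fixture(scope="session")
def conversion_factory(archive_factory):
    """Converted instance graph for a FixtureSpec (fresh copy per call so
    tests may mutate)."""

    def make(spec: b.FixtureSpec) -> b.InstanceGraph:
        return b.convert_archive(archive_factory(spec))

    return make


@pytest.fixture()
def default_graph(conversion_factory):
    return conversion_factory(DEFAULT_SPEC)
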
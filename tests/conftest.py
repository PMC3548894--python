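import pytest

from tilecall import (
    IndexParams,
    RepeatRegionSpec,
    RunConfig,
    build_index,
    make_reference,
    make_repeat_reference,
)


@pytest.fixture(scope="session")
def exon_ref():
    """A 225 bp non-repetitive exon-like reference (all 15-mers unique)."""
    return make_reference(225, seed=1)


@pytest.fixture(scope="session")
def exon_index(exon_ref):
    return build_index(exon_ref, IndexParams())[0]


@pytest.fixture(scope="session")
def repeat_ref():
    """The ~200 bp five-unit repeat-region reference (wild type)."""
    return make_repeat_reference(RepeatRegionSpec(seed=5))


@pytest.fixture(scope="session")
def config():
    return RunConfig()
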
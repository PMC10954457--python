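import numpy as np
import pytest

from probescape import SequenceRecord, create_sample
from probescape.fixtures import FixtureSpec, FixtureTruth, generate_fixture


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=1, n=120)


@pytest.fixture(scope="session")
def truth(fixture_spec):
    return FixtureTruth(fixture_spec)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, fixture_spec):
    outdir = tmp_path_factory.mktemp("toyset")
    manifest = generate_fixture(fixture_spec, outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def toy_sample(fixture_dir):
    """A fully loaded sample built from the generated fixture files."""
    outdir, manifest = fixture_dir
    order = ["fasta", "ct", "varna", "shapemapper-profile", "map", "ring",
             "pair", "pairprob-dp", "pdb", "bed-narrowpeak"]
    inputs = {
        tag.replace("-", "_"): (str(outdir / manifest[tag]), tag)
        for tag in order
    }
    return create_sample("toy", inputs)


@pytest.fixture
def hairpin():
    """12-nt hairpin: GGGGAAAACCCC with stem (1,12)...(4,9)."""
    from probescape import SecondaryStructure
    seq = SequenceRecord(id="hp", residues="GGGGAAAACCCC")
    pairs = {(1, 12), (2, 11), (3, 10), (4, 9)}
    return SecondaryStructure(sequence=seq, pairs=pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(20241)
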
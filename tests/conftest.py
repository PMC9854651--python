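import pathlib
import sys

import pytest

sys.path.insert(0, str(pathlib.Path(__file__).parent))

from pigmentnet import Config, SyntheticSpec, curate, read_association_table
from pigmentnet.io import GeneCatalog
from pigmentnet.simulate import write_all


@pytest.fixture(scope="session")
def spec() -> SyntheticSpec:
    """Default synthetic study conditions (paper-scale diseasome, 4x10 PPI blocks)."""
    return SyntheticSpec()


@pytest.fixture(scope="session")
def sim_dir(spec, tmp_path_factory):
    """One shared synthetic dataset on disk."""
    outdir = tmp_path_factory.mktemp("sim")
    paths = write_all(spec, outdir)
    return paths


@pytest.fixture(scope="session")
def curated_table(sim_dir):
    raw = read_association_table(sim_dir.associations)
    catalog = GeneCatalog.from_tsv(sim_dir.catalog)
    return curate(raw, catalog)


@pytest.fixture()
def config() -> Config:
    return Config()
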
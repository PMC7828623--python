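import numpy as np
import pytest
from hypothesis import settings

from excitonuv import fixtures as fx

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tyr_params():
    return fx.make_parameter_file("TYR")


@pytest.fixture(scope="session")
def all_params():
    return {c: fx.make_parameter_file(c) for c in ("TYR", "PHE", "AMIDE")}


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One generated fixture bundle shared by the whole session."""
    root = tmp_path_factory.mktemp("bundle")
    fx.make_dipeptide_fixtures(root / "conformers")
    pdir = root / "params"
    pdir.mkdir()
    for c in ("TYR", "PHE", "AMIDE", "PHENOL"):
        fx.make_parameter_file(c, pdir / f"{c.lower()}.json")
    fx.make_protein_fixture(seed=0, path=root / "protein.pdb")
    fx.make_protein_fixture(seed=0, n_models=20, path=root / "protein20.pdb")
    return root


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
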
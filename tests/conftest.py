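import numpy as np
import pytest

from famphase.pedigree import Individual, Pedigree
from famphase.simulate import SimConfig, emit_fixture, simulate_family


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(
        [
            Individual("dad", sex="male", affection="affected"),
            Individual("mom", sex="female", affection="unaffected"),
            Individual("kid", "dad", "mom", "male", "affected"),
        ]
    )


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Reduced-size study configuration shared by the slower tests."""
    return SimConfig(
        seed=7,
        n_markers=3000,
        n_exons=800,
        cnv_events=[
            {"first_exon": 100, "n_exons": 3, "carriers": ["II-9"], "copy_number": 3},
            {"first_exon": 400, "n_exons": 2,
             "carriers": ["I-1", "II-2", "II-3", "II-5"], "copy_number": 1},
        ],
    )


@pytest.fixture(scope="session")
def sim_small(small_config):
    return simulate_family(small_config)


@pytest.fixture(scope="session")
def fixture_dir(small_config, tmp_path_factory):
    """The same small study emitted as files."""
    out = tmp_path_factory.mktemp("fixture")
    paths = emit_fixture(small_config, out)
    return paths


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
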
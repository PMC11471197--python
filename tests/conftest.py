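import pytest

from chimscreen.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """The reference synthetic dataset: 40 genes, 30 planted chimeras across
    all categories plus 3 decoys, 4 case + 4 control samples, error-free."""
    out = tmp_path_factory.mktemp("simdata")
    return simulate_dataset(SimConfig(seed=1), out)


@pytest.fixture(scope="session")
def annotation_index(sim):
    from chimscreen.formats_io import annotation_index as build

    return build(sim.annotation)
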
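import numpy as np
import pytest

from probeanova import SampleDesign, SimulationConfig, simulate_probe_dataset


def make_design(n1: int, n2: int) -> SampleDesign:
    arrays = tuple(
        [f"c{j + 1}" for j in range(n1)] + [f"t{j + 1}" for j in range(n2)]
    )
    labels = ("control",) * n1 + ("treatment",) * n2
    return SampleDesign(
        array_ids=arrays,
        treatment_of_array=dict(zip(arrays, labels)),
        levels=("control", "treatment"),
    )


@pytest.fixture
def design_3v3() -> SampleDesign:
    return make_design(3, 3)


@pytest.fixture
def design_2v2() -> SampleDesign:
    return make_design(2, 2)


@pytest.fixture
def design_4v4() -> SampleDesign:
    return make_design(4, 4)


@pytest.fixture
def small_dataset():
    """A 40-gene seeded spike-in dataset, small enough for fast tests."""
    return simulate_probe_dataset(
        SimulationConfig(n_genes=40, probes_per_gene=(4, 8), seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
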
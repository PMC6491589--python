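import numpy as np
import pytest

from adprquant import ExperimentLayout, SimulationConfig


@pytest.fixture(scope="session")
def cofactor_layout() -> ExperimentLayout:
    return ExperimentLayout.tmt6_cofactor()


@pytest.fixture(scope="session")
def inhibitor_layout() -> ExperimentLayout:
    return ExperimentLayout.tmt10_inhibitor()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cofactor_config(cofactor_layout) -> SimulationConfig:
    return SimulationConfig(
        layout=cofactor_layout,
        n_proteins=300,
        n_contaminants=5,
        n_reverse=3,
        n_only_by_site=2,
        n_low_peptide=4,
        n_with_zeros=3,
        seed=11,
    )


@pytest.fixture
def small_inhibitor_config(inhibitor_layout) -> SimulationConfig:
    return SimulationConfig(
        layout=inhibitor_layout,
        n_proteins=300,
        n_contaminants=5,
        n_reverse=3,
        n_only_by_site=2,
        n_low_peptide=4,
        n_with_zeros=3,
        seed=12,
    )
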
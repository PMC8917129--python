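import warnings

import pytest

from beegut.synthetic_data import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic experiment shared across the suite."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_experiment(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def default_loads(default_dataset):
    """qPCR chain output for the shared dataset."""
    from beegut import qpcr

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loads, curves = qpcr.quantify(
            default_dataset.cq_table, default_dataset.dilution_series
        )
    return loads, curves
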
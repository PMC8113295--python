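import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def null_field():
    """A negative-control (buffer-only) field: baseline + noise."""
    from calmea.synthetic import CaFieldConfig, generate_cell_traces

    config = CaFieldConfig(n_cells=400, seed=11)
    return generate_cell_traces(config)


@pytest.fixture
def responder_field():
    """A field where roughly half the cells are transient responders."""
    from calmea.synthetic import CaFieldConfig, generate_cell_traces

    config = CaFieldConfig(n_cells=400, p_react=0.5, kinetics="transient", seed=12)
    return generate_cell_traces(config)
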
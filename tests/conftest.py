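import numpy as np
import pytest

from ribotopo import load_condition_config, load_template_library, simulate_field
from ribotopo.field import FieldConfig
from ribotopo.topology import analyze_topology


@pytest.fixture(scope="session")
def templates():
    return load_template_library()


@pytest.fixture(scope="session")
def small_treated_field():
    """A mid-size mixed-motif field for unit tests (default noise)."""
    cfg = load_condition_config("treated", n_particles=1500, seed=42)
    return simulate_field(cfg)


@pytest.fixture(scope="session")
def treated_5000(templates):
    """The default treated-condition field at full size, fully analyzed.

    Shared by the acceptance tests so the expensive clustering runs once.
    """
    cfg = load_condition_config("treated", seed=2024)
    field = simulate_field(cfg)
    result = analyze_topology(field, templates)
    return field, result


@pytest.fixture()
def monomer_config():
    def _make(n=100, seed=0, box=(8000.0, 8000.0, 2000.0), **kw):
        return FieldConfig(
            n_particles=n,
            box=box,
            motif_weights={},
            state_global={"idle": 1.0},
            seed=seed,
            **kw,
        )

    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
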
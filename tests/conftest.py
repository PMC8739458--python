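import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from lcmsqc import datastore, synth  # noqa: E402


@pytest.fixture
def store():
    s = datastore.init_schema()
    yield s
    s.close()


@pytest.fixture
def small_config():
    """3 batches x (6 cal + 1 QC + 4 patients) x 4 compounds, no nulls."""
    return synth.GeneratorConfig(
        seed=42,
        n_batches=3,
        patients_per_batch=4,
        n_qc=1,
        missing_field_rate=0.0,
        compounds=synth.default_compound_panel(4),
    )


def load_all(batches, store):
    for parsed in batches:
        datastore.load_batch(parsed, store)
    return store


@pytest.fixture
def loaded_small(small_config, store):
    batches, truth = synth.generate_batches(small_config)
    return load_all(batches, store), batches, truth
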
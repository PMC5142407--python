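import pytest
from hypothesis import HealthCheck, settings

from pepgcm import load_parameters

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def reference():
    """Packaged reference peptide table (sequences + simulated/model energies)."""
    from pepgcm.io import reference_table

    return reference_table()
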
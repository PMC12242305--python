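import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from isocline import corrections
from isocline.data_model import (
    SourceDistribution,
    load_reference_specimens,
    load_reference_printed_se,
    load_regions,
)


@pytest.fixture(scope="session")
def regions():
    return load_regions()


@pytest.fixture(scope="session")
def reference_records():
    return load_reference_specimens()


@pytest.fixture(scope="session")
def printed_se():
    return load_reference_printed_se()


@pytest.fixture(scope="session")
def corrected_reference(reference_records, regions):
    return corrections.correct_records(reference_records, regions)


@pytest.fixture(scope="session")
def separated_sources():
    """Three well-separated sources: |Δμ| ≥ 5 s.d. in both tracers."""
    return [
        SourceDistribution("s1", "x", 10, -30.0, 0.5, 3.0, 0.5),
        SourceDistribution("s2", "x", 10, -20.0, 0.5, 8.0, 0.5),
        SourceDistribution("s3", "x", 10, -14.0, 0.5, 14.0, 0.5),
    ]
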
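import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def simple_collection():
    """Three overlapping disease gene sets used across modules."""
    from phenoshare import GeneSet, GeneSetCollection

    return GeneSetCollection(
        [
            GeneSet("Hypertension", frozenset({"ACE", "AGT", "NOS3", "GNB3"})),
            GeneSet("Myocardial Infarction", frozenset({"NOS3", "ACE", "LPL"})),
            GeneSet("Asthma", frozenset({"ADRB2", "IL13", "CD14"})),
        ]
    )
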
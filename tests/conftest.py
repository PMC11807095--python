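import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from amped.reference import AmpliconReference, make_reference


@pytest.fixture(scope="session")
def ref():
    """A 200 bp amplicon with a centred target adenosine and 50 bp guide window."""
    return make_reference(length=200, target_offset=100, guide_span=50, seed=20, name="amp")


@pytest.fixture(scope="session")
def toy_ref():
    """A small handmade amplicon used for hand-computed oracles."""
    seq = "ACGTACGTACGTACGTACGTACGTACGTAC" + "A" + "GCTAGCTAGCTAGCTAGCTAGCTAGCTAG"
    return AmpliconReference(
        name="toy", sequence=seq, target_index=30, guide_window=(16, 46)
    )
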
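import pytest

import triplef as tf


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 403-record constraint-built cohort."""
    return tf.build_fixture_cohort(seed=7)


@pytest.fixture(scope="session")
def analyzable(fixture_cohort):
    """Encounters surviving the urine-culture significance filter."""
    return [
        enc
        for enc in fixture_cohort
        if tf.classify_urine_culture(enc.urine_culture).status
        is tf.UrineStatusValue.SIGNIFICANT
    ]


@pytest.fixture(scope="session")
def classified(analyzable):
    """Classification results for every analyzable encounter."""
    return [tf.classify_encounter(enc) for enc in analyzable]
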
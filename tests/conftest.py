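import pytest

from jcs2gcs import Cohort


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Five patients spanning alert and impaired categories.

    Against the published table: rows 1, 2 and 4 match exactly; row 3
    (JCS 30, GCS 8) is off by one; row 5 (JCS 100, GCS 12) is off by five.
    """
    return Cohort.from_pairs(
        [(0, 15), (0, 15), (30, 8), (30, 9), (100, 12)], label="tiny"
    )


@pytest.fixture
def alert_free_cohort() -> Cohort:
    return Cohort.from_pairs([(30, 9), (30, 10), (100, 7)], label="no-alert")
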
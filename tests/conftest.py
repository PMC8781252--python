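import numpy as np
import pytest

from colpep import (Participant, PeptideRecord, bundled_fragment_panel,
                    bundled_reference)


@pytest.fixture(scope="session")
def reference():
    return bundled_reference()


@pytest.fixture(scope="session")
def panel():
    """Published top-10 fragment panels (long format)."""
    return bundled_fragment_panel()


@pytest.fixture
def five_ids():
    return [f"s{i}" for i in range(1, 6)]


def make_record(modified_seq, values, ids=None):
    ids = ids or [f"s{i}" for i in range(1, len(values) + 1)]
    return PeptideRecord(modified_seq,
                         {i: v for i, v in zip(ids, values) if v > 0})


@pytest.fixture
def toy_cohort():
    """Eight participants spanning the age bins, deterministic."""
    rows = [("p1", 25, 110), ("p2", 34, 95), ("p3", 45, 88), ("p4", 52, 75),
            ("p5", 63, 60), ("p6", 71, 52), ("p7", 80, 40), ("p8", 29, 120)]
    return [Participant(i, a, e) for i, a, e in rows]
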
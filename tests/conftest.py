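import random

import pytest

from scubshift.codons import STANDARD_CODE, CdsRecord


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture
def random_cds_records():
    """100 random 300-codon CDS records (pure ACGT, frame 0)."""
    rng = random.Random(20240917)
    records = []
    for i in range(100):
        seq = "".join(rng.choice("ACGT") for _ in range(900))
        records.append(CdsRecord(id=f"r{i}", sequence=seq))
    return records
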
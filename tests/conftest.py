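import random

import pytest

from apoploss.hits import HitRecord


def make_hit(query="q1", subject="s1", identity=90.0, e_value=1e-50, bits=200.0,
             aln_len=100):
    return HitRecord(
        query_id=query, subject_id=subject, pct_identity=identity, aln_len=aln_len,
        mismatches=0, gap_opens=0, q_start=1, q_end=aln_len, s_start=1, s_end=aln_len,
        e_value=e_value, bit_score=bits,
    )


@pytest.fixture
def hit_factory():
    return make_hit


@pytest.fixture
def rng():
    return random.Random(20240517)
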
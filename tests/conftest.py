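import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from repclonity import simulate
from repclonity.types import CloneRecord, Repertoire

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def germline():
    return simulate.bundled_germline()


def make_repertoire(counts, sample_id="S1", chain="IGHG", library_size=1_000_000,
                    sequences=None, v_calls=None):
    """Small repertoire with distinct placeholder sequences."""
    if sequences is None:
        sequences = ["ACGT" + format(i, "04b").replace("0", "A").replace("1", "C")
                     for i in range(len(counts))]
    clones = [
        CloneRecord(sample_id=sample_id, chain=chain, sequence=seq, count=c,
                    v_call=None if v_calls is None else v_calls[i])
        for i, (seq, c) in enumerate(zip(sequences, counts))
    ]
    return Repertoire(sample_id=sample_id, chain=chain, clones=clones,
                      library_size=library_size)


@pytest.fixture
def simple_repertoire():
    return make_repertoire([8, 1, 1])
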
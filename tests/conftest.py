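import numpy as np
import pytest
from hypothesis import settings

from qqfilter import MinimizerParams, build_index, make_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_fixture(tmp_path_factory):
    """5 random transcripts, 2 paired-end experiments at coverage 10."""
    out = tmp_path_factory.mktemp("tiny")
    return make_fixture("tiny", out, seed=3)


@pytest.fixture(scope="session")
def fc_fixture(tmp_path_factory):
    """20 x 500 nt transcripts; conditions A/B at coverages 8 and 16."""
    out = tmp_path_factory.mktemp("fc")
    return make_fixture("fc-recovery", out, seed=7)


@pytest.fixture(scope="session")
def tiny_index(tiny_fixture):
    """Auto-threshold 8-level index over the tiny fixture (k=w=19)."""
    params = MinimizerParams(k=19, w=19)
    return build_index(
        tiny_fixture["experiments"], params, 8,
        mode="auto", cutoff=1, target_fpr=0.01,
    )


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
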
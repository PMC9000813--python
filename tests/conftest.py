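import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nucsig.io import Group, SequenceSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def random_set(rng, n_seqs, min_len, max_len, group="ingroup") -> SequenceSet:
    seqs = [
        random_seq(rng, int(rng.integers(min_len, max_len + 1))) for _ in range(n_seqs)
    ]
    return SequenceSet.from_sequences(seqs, Group(group))


@pytest.fixture(scope="session")
def demo():
    """The packaged worked-example scenario (ingroup, outgroup, truth)."""
    from nucsig.synth import demo_scenario

    return demo_scenario(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
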
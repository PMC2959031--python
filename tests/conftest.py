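import hypothesis
import numpy as np
import pytest

from errormatrix import TwoByTwoTable, load_fixture

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=100,
    suppress_health_check=[hypothesis.HealthCheck.too_slow],
)
hypothesis.settings.load_profile("default")


def random_tables(n, seed=0, max_count=500, min_events=0):
    """Seeded stream of valid 2x2 tables for brute-force property checks."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        a, b, c, d = (int(x) for x in rng.integers(0, max_count + 1, size=4))
        if a + b < 1 or c + d < 1:
            continue
        if a < min_events or c < min_events:
            continue
        out.append(TwoByTwoTable(a, b, c, d))
    return out


@pytest.fixture(scope="session")
def example1():
    return load_fixture("example1")


@pytest.fixture(scope="session")
def example2():
    return load_fixture("example2")
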
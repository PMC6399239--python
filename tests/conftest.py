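import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def zeta_series(s: float, a: int = 1, terms: int = 20_000) -> float:
    """Independent Hurwitz-zeta oracle: direct summation + integral tail.

    sum_{k=a}^{N} k^(-s) + (N+1/2)^(1-s)/(s-1)  (midpoint tail bound),
    accurate to ~1e-10 for s >= 1.5 at the default number of terms.
    """
    k = np.arange(a, a + terms, dtype=float)
    partial = float((k**-s).sum())
    n_last = a + terms - 0.5
    return partial + n_last ** (1.0 - s) / (s - 1.0)


@pytest.fixture(scope="session")
def oracle_zeta():
    return zeta_series


@pytest.fixture(scope="session")
def small_fixture_sequences():
    """Twenty small degree sequences (n <= 100) with mixed tail shapes."""
    out = []
    for i in range(20):
        rng = np.random.default_rng(1000 + i)
        n = int(rng.integers(40, 101))
        kind = i % 4
        if kind == 0:
            from sftest import sample_powerlaw

            k = sample_powerlaw(n, 2.0 + 0.1 * i, 1, rng)
        elif kind == 1:
            k = rng.geometric(0.25, size=n)
        elif kind == 2:
            k = rng.poisson(8, size=n) + 1
        else:
            k = np.round(rng.lognormal(1.0, 0.8, size=n)).astype(int) + 1
        out.append(k)
    return out
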
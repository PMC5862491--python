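import numpy as np
import pytest

from bayesn.genome import MarkerMap, build_window_partition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_instance():
    """n=8, 4 SNPs in 2 windows, one strong effect — oracle-enumerable."""
    rng = np.random.default_rng(1)
    n, m = 8, 4
    Z = rng.normal(size=(n, m))
    Z -= Z.mean(axis=0)
    y = Z @ np.array([1.5, 0.0, 0.0, 0.0]) + rng.normal(size=n) * 0.5
    mp = MarkerMap(
        [f"s{i}" for i in range(m)],
        np.ones(m, dtype=int),
        np.array([100, 200, 1_000_100, 1_000_200]),
    )
    wp = build_window_partition(mp, 1_000_000)
    return {"y": y, "Z": Z, "map": mp, "windows": wp}
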
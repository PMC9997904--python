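import numpy as np
import pandas as pd
import pytest

from shapsets import Ranking, build_family


@pytest.fixture
def two_set_family():
    """The canonical 2-set fixture: P1={a,b}, P2={b}; ϕ = (3/4, 1/4)."""
    return build_family([("P1", ["a", "b"]), ("P2", ["b"])])


@pytest.fixture
def duplicate_family():
    """An exact duplicate pair plus a disjoint singleton set."""
    return build_family([("A", ["a", "b"]), ("A2", ["a", "b"]), ("C", ["c"])])


@pytest.fixture
def triangle_family():
    """Three sets, every pair overlapping in one of three elements."""
    return build_family([("X", ["a", "b"]), ("Y", ["b", "c"]), ("Z", ["c", "a"])])


@pytest.fixture
def disjoint_family():
    """Four pairwise-disjoint equal-size sets."""
    return build_family(
        [(f"D{i}", [f"d{i}a", f"d{i}b", f"d{i}c"]) for i in range(4)]
    )


def make_ranking(order, method="manual"):
    """Build a Ranking with a minimal score trace, for metric-only tests."""
    log = pd.DataFrame(
        {
            "position": np.arange(1, len(order) + 1),
            "set_index": list(order),
            "score": np.zeros(len(order)),
            "shapley": np.zeros(len(order)),
            "penalty": np.zeros(len(order)),
        }
    )
    return Ranking(method=method, order=tuple(order), iteration_log=log)


def random_family(rng, max_sets=10, max_universe=20, density=0.35):
    """A random valid family: non-empty rows, universe = union of rows."""
    n = int(rng.integers(2, max_sets + 1))
    m = int(rng.integers(2, max_universe + 1))
    inc = rng.random((n, m)) < density
    for i in range(n):  # no empty set
        if not inc[i].any():
            inc[i, rng.integers(m)] = True
    labels = [f"e{j}" for j in range(m)]
    return build_family(
        [
            (f"R{i}", [labels[j] for j in np.flatnonzero(inc[i])])
            for i in range(n)
        ]
    )
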
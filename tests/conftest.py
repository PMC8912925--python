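import numpy as np
import pytest

from phyloreg import simulate


def adjusted_rand_index(labels_a: dict, labels_b: dict) -> float:
    """ARI between two labelings given as id -> label maps."""
    ids = sorted(labels_a)
    assert sorted(labels_b) == ids
    a_vals = sorted({labels_a[i] for i in ids})
    b_vals = sorted({labels_b[i] for i in ids})
    table = np.zeros((len(a_vals), len(b_vals)), dtype=np.int64)
    ai = {v: k for k, v in enumerate(a_vals)}
    bi = {v: k for k, v in enumerate(b_vals)}
    for i in ids:
        table[ai[labels_a[i]], bi[labels_b[i]]] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    n = comb2(len(ids))
    expected = sum_a * sum_b / n
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


@pytest.fixture(scope="session")
def small_truth():
    """Three well-separated subfamilies, eight copies each."""
    cfg = simulate.SimConfig(
        seed=42, n_subfamilies=3, copies_per_subfamily=8,
        mark_probs={"markA": {"sf1": 0.9, "sf2": 0.1, "sf3": 0.1}},
    )
    return simulate.simulate_family(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
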
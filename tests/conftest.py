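import numpy as np
import pytest

from riverload.network import Reach, StreamNetwork


@pytest.fixture
def chain3() -> StreamNetwork:
    """Three-reach chain a -> b -> c with travel times 1, 1, 2 days."""
    return StreamNetwork([
        Reach("a", "b", travel_time=1.0, drainage_area=1.0),
        Reach("b", "c", travel_time=1.0, drainage_area=2.0),
        Reach("c", None, travel_time=2.0, drainage_area=3.0),
    ])


def build_random_tree(rng: np.random.Generator, n: int,
                      tt_max: float = 3.0) -> StreamNetwork:
    """Random in-tree independent of the synthetic_data generators.

    Node i (i >= 1) drains into a uniformly chosen earlier node, so the
    result is always an acyclic single-outlet tree.  Used as oracle input.
    """
    parents = [None] + [int(rng.integers(0, i)) for i in range(1, n)]
    travel = rng.uniform(0.0, tt_max, n)
    local = rng.uniform(0.5, 5.0, n)
    drainage = local.copy()
    for i in range(n - 1, 0, -1):
        drainage[parents[i]] += drainage[i]
    reaches = [
        Reach(f"n{i}",
              None if parents[i] is None else f"n{parents[i]}",
              travel_time=float(travel[i]),
              drainage_area=float(drainage[i]))
        for i in range(n)
    ]
    return StreamNetwork(reaches)


def random_field(rng: np.random.Generator, network: StreamNetwork) -> dict:
    return {rid: float(v) for rid, v in
            zip(network.reach_ids, rng.uniform(0.0, 100.0, len(network)))}
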
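import numpy as np
import pytest

from aakdyn import AffinityModel, CoarseModel, CoarseNode, ToySpec, make_toy


@pytest.fixture(scope="session")
def p3():
    """Three beads on a line, 1 A apart: the hand-solvable path graph."""
    return make_toy(ToySpec("chain", 3, spacing=1.0))


@pytest.fixture(scope="session")
def dumbbell():
    """Two-lobe toy with a designed hinge at the bridge node."""
    return make_toy(ToySpec("dumbbell", 40))


@pytest.fixture(scope="session")
def p3_affinity():
    """Path graph with unit edge weights (degrees 1, 2, 1)."""
    a = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
    return AffinityModel(a, threshold=4.0)


def model_from_coords(coords, chains=None, b_factors=None) -> CoarseModel:
    """Bare coarse model whose heavy-atom list is just the node itself."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    chains = chains or ["A"] * n
    nodes = []
    seq = {}
    for i in range(n):
        seq[chains[i]] = seq.get(chains[i], 0) + 1
        nodes.append(
            CoarseNode(
                label=f"{chains[i]}:GLY{seq[chains[i]]}",
                chain=chains[i],
                seqid=seq[chains[i]],
                kind="residue",
                coord=tuple(coords[i]),
                b_factor=None if b_factors is None else float(b_factors[i]),
                heavy_coords=(tuple(coords[i]),),
            )
        )
    return CoarseModel(nodes)


def random_connected_affinity(n, rng, extra_edges=2.0) -> AffinityModel:
    """Random weighted graph guaranteed connected via a spanning path."""
    a = np.zeros((n, n))
    for i in range(n - 1):
        w = rng.uniform(0.2, 2.0)
        a[i, i + 1] = a[i + 1, i] = w
    n_extra = int(extra_edges * n)
    for _ in range(n_extra):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            w = rng.uniform(0.2, 2.0)
            a[i, j] = a[j, i] = w
    return AffinityModel(a, threshold=4.0)


def hitting_time_first_step(affinity: AffinityModel, target: int) -> np.ndarray:
    """Independent oracle: expected steps to ``target`` from every node by
    first-step analysis, h = 1 + M^T_{-t,-t} h, never using the spectral
    formula."""
    a = affinity.affinity
    d = a.sum(axis=0)
    m = a / d[None, :]                       # m[i, j] = P(j -> i)
    n = a.shape[0]
    keep = [i for i in range(n) if i != target]
    sub = m[np.ix_(keep, keep)]
    h = np.linalg.solve(np.eye(n - 1) - sub.T, np.ones(n - 1))
    out = np.zeros(n)
    out[keep] = h
    return out
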
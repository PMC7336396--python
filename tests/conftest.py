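import numpy as np
import pytest

from dtiwlnet import DTINetwork


def random_network(rng: np.random.Generator, m: int, n: int, density: float = 0.15
                   ) -> DTINetwork:
    """Small random semi-bipartite network for property tests."""

    def sim(size: int) -> np.ndarray:
        A = rng.uniform(0.0, 1.0, size=(size, size))
        S = (A + A.T) / 2.0
        np.fill_diagonal(S, 1.0)
        return S

    Y = (rng.uniform(size=(m, n)) < density).astype(np.int8)
    drug_ids = [f"d{i}" for i in range(m)]
    target_ids = [f"t{j}" for j in range(n)]
    return DTINetwork(drug_ids, target_ids, Y, sim(m), sim(n))


@pytest.fixture
def toy_net() -> DTINetwork:
    """3x3 network with interactions {(d1,t1),(d2,t1),(d1,t2),(d3,t3)}.

    S_D[d1,d2] = 0.9 and S_T[t1,t2] = 0.2; all other off-diagonal
    similarities are 0.1 so hand traces stay unambiguous.
    """
    Y = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 1]], dtype=np.int8)
    S_D = np.full((3, 3), 0.1)
    S_D[0, 1] = S_D[1, 0] = 0.9
    np.fill_diagonal(S_D, 1.0)
    S_T = np.full((3, 3), 0.1)
    S_T[0, 1] = S_T[1, 0] = 0.2
    np.fill_diagonal(S_T, 1.0)
    return DTINetwork(["d1", "d2", "d3"], ["t1", "t2", "t3"], Y, S_D, S_T)


@pytest.fixture
def isolated_pair_net() -> DTINetwork:
    """4x4 network whose only interaction is the (d0, t0) anchor pair."""
    Y = np.zeros((4, 4), dtype=np.int8)
    Y[0, 0] = 1
    return DTINetwork(
        [f"d{i}" for i in range(4)],
        [f"t{j}" for j in range(4)],
        Y,
        np.eye(4),
        np.eye(4),
    )
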
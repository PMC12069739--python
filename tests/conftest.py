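import numpy as np
import pytest

from sleepgrey import EpochGrid, Hypnodensity, Hypnogram, ScorerPanel, SimConfig


@pytest.fixture
def grid5() -> EpochGrid:
    return EpochGrid(5)


@pytest.fixture
def simple_hd(grid5) -> Hypnodensity:
    probs = np.array(
        [
            [1.0, 0.0, 0.0, 0.0, 0.0],
            [0.2, 0.2, 0.2, 0.2, 0.2],
            [0.5, 0.3, 0.1, 0.1, 0.0],
            [0.5, 0.5, 0.0, 0.0, 0.0],
            [0.1, 0.2, 0.5, 0.1, 0.1],
        ]
    )
    return Hypnodensity(grid5, probs)


@pytest.fixture
def ten_scorer_panel() -> ScorerPanel:
    """4 epochs x 10 scorers covering unanimity, majorities, and ties."""
    labels = np.array(
        [
            [2] * 10,                      # unanimous N2
            [2] * 6 + [1] * 3 + [0],       # 6xN2, 3xN1, 1xW
            [0] * 5 + [4] * 5,             # 5xW / 5xREM tie
            [3] * 4 + [2] * 4 + [4] * 2,   # 4xN3 / 4xN2 tie, 2xREM
        ],
        dtype=np.int8,
    )
    return ScorerPanel(EpochGrid(4), labels)


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig(n_epochs=2000, seed=1)


def random_simplex(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform samples from the 4-simplex (flat Dirichlet)."""
    return rng.dirichlet(np.ones(5), size=n)
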
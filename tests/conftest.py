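import numpy as np
import pytest

from disparity import SimulationConfig, WeightsMatrix, simulate


def rook_lattice_weights(n_side: int, standardized: bool = True) -> WeightsMatrix:
    """Rook-wired square lattice weights (tests of closed-form Moran values)."""
    ids = [f"{r}-{c}" for r in range(n_side) for c in range(n_side)]
    nbrs = {i: set() for i in ids}
    for r in range(n_side):
        for c in range(n_side):
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_side and 0 <= cc < n_side:
                    nbrs[f"{r}-{c}"].add(f"{rr}-{cc}")
    return WeightsMatrix.from_neighbors(ids, nbrs, standardized=standardized)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_rows=6, n_cols=6, seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    """(lattice, truth, panel) for a 6x6 synthetic study."""
    return simulate(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
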
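"""Global Moran's I and local Moran (LISA) with permutation inference.

Global statistic, for deviations z_i = x_i - xbar and weights w_ij:

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2

Local statistic, with second moment m2 = sum_k z_k^2 / n:

    I_i = (z_i / m2) * sum_j w_ij z_j

Under row-standardized weights mean_i(I_i) = I exactly (this identity is a
regression test).  Inference is by random permutation for I and by
conditional permutation for I_i (region i's own value held fixed, the
others permuted onto its neighbour slots); pseudo p-values are
(1 + #{permuted statistics as or more extreme, toward the observed sign}) /
(n_perm + 1).  LISA quadrants (high-high, low-low, high-low, low-high) come
from the signs of z_i and its spatial lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .data_model import RegionLattice, WeightsMatrix
from .errors import DegenerateVarianceError, InsufficientDataError

QUADRANTS = {(1, 1): "high-high", (-1, -1): "low-low",
             (1, -1): "high-low", (-1, 1): "low-high"}


@dataclass
class MoranResult:
    I: float
    expected_I: float      # -1/(n-1)
    perm_mean: float
    perm_sd: float
    z_perm: float          # (I - perm_mean)/perm_sd
    pseudo_p: float
    n_perm: int
    n: int


@dataclass
class LisaResult:
    ids: list[str]
    I_local: np.ndarray
    quadrant: list[str]
    pseudo_p: np.ndarray
    significant: np.ndarray
    alpha: float
    n_perm: int
    island: np.ndarray      # True where the region has no neighbours

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "region_id": self.ids,
            "I_local": self.I_local,
            "quadrant": self.quadrant,
            "pseudo_p": self.pseudo_p,
            "significant": self.significant,
        })


def _check_input(x: np.ndarray, weights: WeightsMatrix) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if len(x) != weights.n:
        raise InsufficientDataError(
            f"{len(x)} values for {weights.n} regions")
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 regions")
    if np.ptp(x) == 0:
        raise DegenerateVarianceError("constant surface: Moran statistics undefined")
    return x


def _moran_stat(z: np.ndarray, weights: WeightsMatrix) -> float:
    lag = weights.lag(z)
    return float(len(z) / weights.S0 * (z @ lag) / (z @ z))


def morans_i(x, weights: WeightsMatrix, n_perm: int = 999,
             seed: int | None = 0) -> MoranResult:
    """Global Moran's I with seeded permutation inference."""
    x = _check_input(x, weights)
    n = len(x)
    z = x - x.mean()
    I_obs = _moran_stat(z, weights)
    rng = np.random.default_rng(seed)
    # permuted I: lag of reshuffled z, via one sparse matmul over all draws
    P = np.empty((n, n_perm))
    for k in range(n_perm):
        P[:, k] = rng.permutation(z)
    lags = weights.to_sparse() @ P
    I_perm = n / weights.S0 * np.einsum("ij,ij->j", P, lags) / (z @ z)
    E_I = -1.0 / (n - 1)
    if I_obs >= E_I:
        extreme = int(np.sum(I_perm >= I_obs))
    else:
        extreme = int(np.sum(I_perm <= I_obs))
    return MoranResult(
        I=I_obs, expected_I=E_I,
        perm_mean=float(I_perm.mean()), perm_sd=float(I_perm.std()),
        z_perm=float((I_obs - I_perm.mean()) / I_perm.std()),
        pseudo_p=(1 + extreme) / (n_perm + 1),
        n_perm=n_perm, n=n)


def local_morans(x, weights: WeightsMatrix, n_perm: int = 999,
                 seed: int | None = 0, alpha: float = 0.05,
                 fdr: bool = False) -> LisaResult:
    """Local Moran's I with conditional permutation inference.

    ``fdr=True`` applies Benjamini-Hochberg control to the pseudo p-values
    before flagging significance.
    """
    x = _check_input(x, weights)
    n = len(x)
    z = x - x.mean()
    m2 = float(z @ z) / n
    lag = weights.lag(z)
    I_loc = z / m2 * lag
    card = weights.cardinalities
    island = card == 0
    if island.any():
        warnings.warn(f"{int(island.sum())} island region(s): I_i set to 0",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    kmax = int(card.max()) if n else 0
    # one pool of shuffled other-region positions, reused across regions
    R = np.argsort(rng.random((n_perm, n - 1)), axis=1)[:, :kmax]
    pseudo_p = np.ones(n)
    others = np.arange(n - 1)
    for i in range(n):
        k = int(card[i])
        if k == 0:
            I_loc[i] = 0.0
            continue
        idx = np.where(others < i, others, others + 1)   # all regions but i
        w_i = weights.weights[i]
        draws = z[idx[R[:, :k]]]                          # (n_perm, k)
        lag_perm = draws @ w_i
        I_perm = z[i] / m2 * lag_perm
        if I_loc[i] >= 0:
            extreme = int(np.sum(I_perm >= I_loc[i]))
        else:
            extreme = int(np.sum(I_perm <= I_loc[i]))
        pseudo_p[i] = (1 + extreme) / (n_perm + 1)
    sig_p = false_discovery_control(pseudo_p, method="bh") if fdr else pseudo_p
    significant = (sig_p <= alpha) & ~island
    quadrant = []
    for i in range(n):
        if island[i]:
            quadrant.append("island")
        else:
            key = (1 if z[i] > 0 else -1, 1 if lag[i] > 0 else -1)
            quadrant.append(QUADRANTS[key])
    return LisaResult(ids=list(weights.ids), I_local=I_loc, quadrant=quadrant,
                      pseudo_p=pseudo_p, significant=significant,
                      alpha=alpha, n_perm=n_perm, island=island)


def lisa_cluster_table(result: LisaResult,
                       lattice: RegionLattice) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster-map labels per region and label counts per admin block.

    Returns (per_region, per_block): the first has region_id, label (the
    quadrant when significant, else "not significant"), the second counts
    labels within each admin_block.
    """
    block_of = dict(zip(lattice.region_ids, lattice.admin_blocks))
    labels = [q if s else "not significant"
              for q, s in zip(result.quadrant, result.significant)]
    per_region = pd.DataFrame({
        "region_id": result.ids,
        "admin_block": [block_of[rid] for rid in result.ids],
        "label": labels,
    })
    per_block = (per_region.groupby(["admin_block", "label"])
                 .size().rename("n_regions").reset_index())
    return per_region, per_block
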
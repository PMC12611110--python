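"""Space-time cube, per-bin Getis-Ord Gi*, and emerging-hotspot categories.

A space-time cube is a complete regions x years grid of bin values (here the
annual smoothed rate).  Each bin's Gi* compares the sum of values over its
spatio-temporal neighbourhood (queen-contiguous regions including self,
years within +-k_t) with the expectation under the cube-wide mean:

    Gi*(b) = [ sum_{c in N(b)} x_c - Xbar |N(b)| ]
             / [ s sqrt( (n |N(b)| - |N(b)|^2) / (n - 1) ) ]

where n is the total bin count and Xbar, s the mean and population standard
deviation over all bins.  Per-region categories follow the emerging-hotspot
taxonomy: per-step bins are hot (cold) at 90 % confidence when z >= 1.645
(z <= -1.645), and the time pattern of significant steps plus the
Mann-Kendall trend of the z series decide among new, consecutive,
intensifying, persistent, diminishing, sporadic, oscillating and historical
hot/cold spots, else "no pattern".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import RegionLattice
from .errors import DegenerateVarianceError, InsufficientDataError, ValidationError
from .trend_tests import MannKendallResult, mann_kendall

Z90 = 1.6448536269514722   # one-sided 95 % / two-sided 90 % normal quantile

HOT_90PCT = {"persistent hot spot", "intensifying hot spot", "diminishing hot spot"}
COLD_90PCT = {"persistent cold spot", "intensifying cold spot", "diminishing cold spot"}


@dataclass
class SpaceTimeCube:
    """Complete region x year grid of values with spatial neighbour structure."""

    region_ids: list[str]
    years: list[int]
    values: np.ndarray               # (n_regions, n_years)
    window_idx: list[np.ndarray]     # per region: queen neighbours incl. self
    k_t: int = 1                     # temporal half-width of the Gi* window

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_bins(self) -> int:
        return self.values.size


@dataclass
class GiStarField:
    cube: SpaceTimeCube
    z: np.ndarray          # (n_regions, n_years)
    p: np.ndarray
    mean: float            # cube-wide mean used in the statistic
    sd: float              # cube-wide population standard deviation


def build_cube(rates: pd.DataFrame, lattice: RegionLattice, indicator: str,
               value: str = "smoothed_rate", k_t: int = 1) -> SpaceTimeCube:
    """Assemble the cube for one indicator from a RatePanel frame."""
    sub = rates[rates["indicator"] == indicator]
    if sub.empty:
        raise ValidationError(f"no rates for indicator '{indicator}'")
    years = sorted(sub["year"].unique())
    wide = sub.pivot(index="region_id", columns="year", values=value)
    wide = wide.reindex(index=lattice.region_ids, columns=years)
    if wide.isna().any().any():
        gaps = [(wide.index[i], years[j]) for i, j in
                zip(*np.where(wide.isna().to_numpy()))][:5]
        raise ValidationError(f"missing bins (first few): {gaps}")
    window = [np.array(sorted([lattice.index(rid)]
                              + [lattice.index(j) for j in lattice.neighbors[rid]]))
              for rid in lattice.region_ids]
    return SpaceTimeCube(list(lattice.region_ids), [int(y) for y in years],
                         wide.to_numpy(dtype=float), window, k_t=k_t)


def gi_star(cube: SpaceTimeCube) -> GiStarField:
    """Per-bin Gi* z-scores over the spatio-temporal neighbourhood."""
    X = cube.values
    n = cube.n_bins
    xbar = X.mean()
    s = X.std()                      # population sd over all bins
    if s == 0:
        raise DegenerateVarianceError("constant cube: Gi* undefined")
    T = cube.n_years
    # spatial window sums per (region, year), then temporal window sums
    spat = np.vstack([X[w].sum(axis=0) for w in cube.window_idx])
    csum = np.concatenate([np.zeros((cube.n_regions, 1)),
                           np.cumsum(spat, axis=1)], axis=1)
    nsp = np.array([len(w) for w in cube.window_idx])
    z = np.empty_like(X)
    for t in range(T):
        lo, hi = max(0, t - cube.k_t), min(T - 1, t + cube.k_t)
        wsum = csum[:, hi + 1] - csum[:, lo]
        m = nsp * (hi - lo + 1)
        denom = s * np.sqrt((n * m - m.astype(float) ** 2) / (n - 1))
        z[:, t] = (wsum - xbar * m) / denom
    p = 2.0 * (1.0 - stats.norm.cdf(np.abs(z)))
    return GiStarField(cube=cube, z=z, p=p, mean=float(xbar), sd=float(s))


def _classify_series(z: np.ndarray, pct_threshold: float = 0.9,
                     alpha_mk: float = 0.05) -> tuple[str, MannKendallResult]:
    """Emerging-hotspot category for one region's Gi* z series."""
    mk = mann_kendall(z, method="normal")
    hot = z >= Z90
    cold = z <= -Z90
    T = len(z)

    def side(sig: np.ndarray, other: np.ndarray, label: str,
             direction: float) -> str:
        # direction: +1 for hot (|z| grows with z), -1 for cold
        pct = sig.mean()
        if other.any():
            return f"oscillating {label}"
        if pct >= pct_threshold:
            if mk.p < alpha_mk and direction * mk.S > 0:
                return f"intensifying {label}"
            if mk.p < alpha_mk and direction * mk.S < 0:
                return f"diminishing {label}"
            return f"persistent {label}"
        if not sig[:-1].any():
            return f"new {label}"
        run = 0
        for t in range(T - 1, -1, -1):
            if sig[t]:
                run += 1
            else:
                break
        if run >= 2 and not sig[:T - run].any():
            return f"consecutive {label}"
        return f"sporadic {label}"

    if hot[-1]:
        return side(hot, cold, "hot spot", +1.0), mk
    if cold[-1]:
        return side(cold, hot, "cold spot", -1.0), mk
    if hot.mean() >= pct_threshold:
        return "historical hot spot", mk
    if cold.mean() >= pct_threshold:
        return "historical cold spot", mk
    return "no pattern", mk


def classify_emerging(field: GiStarField, pct_threshold: float = 0.9,
                      alpha_mk: float = 0.05) -> pd.DataFrame:
    """Per-region emerging-hotspot categories.

    Returns a frame with region_id, category, final_z, pct_hot, pct_cold,
    mk_z, mk_p (Mann-Kendall on the region's z series).
    """
    rows = []
    for i, rid in enumerate(field.cube.region_ids):
        z = field.z[i]
        category, mk = _classify_series(z, pct_threshold, alpha_mk)
        rows.append({
            "region_id": rid,
            "category": category,
            "final_z": float(z[-1]),
            "pct_hot": float((z >= Z90).mean()),
            "pct_cold": float((z <= -Z90).mean()),
            "mk_z": mk.Z,
            "mk_p": mk.p,
        })
    return pd.DataFrame(rows)


def cube_overall_trend(cube: SpaceTimeCube, method: str = "auto") -> MannKendallResult:
    """Cube-wide trend statistic: Mann-Kendall on per-step spatial means."""
    if cube.n_years < 3:
        raise InsufficientDataError("cube needs >= 3 time steps")
    series = cube.values.mean(axis=0)
    return mann_kendall(series, method=method)
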
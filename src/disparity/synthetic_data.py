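"""Seeded synthetic health-region data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a contiguous square-cell lattice of a few hundred regions on a
planar km grid, log-normal populations of 40-79-year-olds, spatially
autocorrelated latent log-rates with macro-regional blocks (a high-South /
low-North analogue), a monotone multiplicative trend in diagnosis and
treatment with a peak in 2019 and a dip in 2020, a flat mortality trend, and
Poisson-sampled counts.  Planted blocks are recorded as ground truth so
recovery tests can score the hotspot and LISA stages.

The latent field is Gaussian-kernel-smoothed white noise (bandwidth =
``spatial_range_km``) rescaled to ``field_sd`` on the log scale — simpler
than a CAR/SAR model and sufficient to induce controllable Moran's I.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon

from .data_model import (INDICATORS, CountPanel, RegionLattice, queen_neighbors,
                         write_counts, write_regions)
from .errors import ConfigError

# default macro-region row bands (fractions of n_rows, south at the bottom)
_ADMIN_BANDS = [
    ("south", 0.00, 0.20),
    ("southeast", 0.20, 0.40),
    ("central_west", 0.40, 0.55),
    ("northeast", 0.55, 0.75),
    ("north", 0.75, 1.00),
]


@dataclass
class BlockSpec:
    """A rectangular block of lattice cells with planted effects.

    ``rate_factors`` multiply the baseline rate of each indicator inside the
    block; ``trend_factors`` multiply the annual trend (an extra per-year
    factor applied on top of the global trend).  Row/col bounds inclusive.
    """

    name: str
    row0: int
    row1: int
    col0: int
    col1: int
    rate_factors: dict[str, float] = field(default_factory=dict)
    trend_factors: dict[str, float] = field(default_factory=dict)

    def contains(self, row: int, col: int) -> bool:
        return self.row0 <= row <= self.row1 and self.col0 <= col <= self.col1


def default_blocks(n_rows: int, n_cols: int) -> list[BlockSpec]:
    """High-South / low-North regional blocks scaled to the lattice size."""
    r = n_rows - 1
    south_top = max(0, int(0.20 * r))
    candidates = [
        BlockSpec("south_high", 0, south_top, 0, n_cols - 1,
                  rate_factors={"diagnosis": 1.5, "treatment": 1.5, "death": 1.6}),
        BlockSpec("southeast_mid", south_top + 1, int(0.40 * r), 0, n_cols - 1,
                  rate_factors={"diagnosis": 1.25, "treatment": 1.25, "death": 1.2}),
        BlockSpec("northeast_low", int(0.55 * r) + 1, int(0.75 * r), 0, n_cols - 1,
                  rate_factors={"diagnosis": 0.7, "treatment": 0.7, "death": 0.75}),
        BlockSpec("north_low", max(south_top + 1, int(0.75 * r) + 1), r,
                  0, n_cols - 1,
                  rate_factors={"diagnosis": 0.55, "treatment": 0.55, "death": 0.65}),
    ]
    return [b for b in candidates if b.row0 <= b.row1]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the study conditions: a 20 x 22 lattice (440 regions,
    about the 438 health regions), years 2013-2022, baseline rates per
    100,000 in the observed national ranges (diagnosis ~24, treatment ~20,
    death ~38), a ~3.5 %/yr diagnosis and ~3 %/yr treatment trend with a
    2019 peak and 2020 dip, flat mortality, and a latent spatial field with
    a 400 km correlation length.
    """

    n_rows: int = 20
    n_cols: int = 22
    cell_km: float = 140.0
    years: tuple[int, int] = (2013, 2022)
    pop_log_mean: float = math.log(150_000.0)
    pop_log_sd: float = 0.7
    base_rate: dict[str, float] = field(default_factory=lambda: {
        "diagnosis": 24.0, "treatment": 20.0, "death": 38.0})
    blocks: list[BlockSpec] | None = None   # None -> default_blocks()
    trend_per_year: dict[str, float] = field(default_factory=lambda: {
        "diagnosis": 1.035, "treatment": 1.03, "death": 1.0})
    year_shocks: dict[str, dict[int, float]] = field(default_factory=lambda: {
        "diagnosis": {2019: 1.07, 2020: 0.90},
        "treatment": {2019: 1.07, 2020: 0.88},
        "death": {}})
    spatial_range_km: float = 400.0
    field_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ConfigError("lattice dimensions must be positive")
        if self.n_rows * self.n_cols < 9:
            raise ConfigError("lattice must have at least 9 regions")
        if self.cell_km <= 0:
            raise ConfigError("cell_km must be positive")
        y0, y1 = self.years
        if y1 - y0 + 1 < 3:
            raise ConfigError("year range must span at least 3 years")
        for v, r in self.base_rate.items():
            if r < 0:
                raise ConfigError(f"negative base rate for {v}")
        if self.field_sd < 0 or self.spatial_range_km < 0:
            raise ConfigError("field parameters must be non-negative")
        if self.blocks is None:
            self.blocks = default_blocks(self.n_rows, self.n_cols)
        for b in self.blocks:
            if not (0 <= b.row0 <= b.row1 < self.n_rows
                    and 0 <= b.col0 <= b.col1 < self.n_cols):
                raise ConfigError(f"block '{b.name}' outside the lattice")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def indicators(self) -> list[str]:
        return list(self.base_rate)


@dataclass
class GroundTruth:
    """Latent per-region log-rate surfaces and the planted blocks behind them.

    ``latent_rates[v]`` is an (n_regions, n_years) array of latent rates per
    100,000 for indicator ``v``; block membership is stored as region-id
    lists so recovery tests can score detections.
    """

    region_ids: list[str]
    years: list[int]
    latent_rates: dict[str, np.ndarray]
    planted_blocks: dict[str, dict]   # name -> {region_ids, rate_factors, trend_factors}

    def block_region_ids(self, name: str) -> list[str]:
        return list(self.planted_blocks[name]["region_ids"])


def _region_id(row: int, col: int) -> str:
    return f"R{row:03d}{col:03d}"


def _admin_band(row: int, n_rows: int) -> str:
    frac = row / n_rows
    for name, lo, hi in _ADMIN_BANDS:
        if lo <= frac < hi:
            return name
    return _ADMIN_BANDS[-1][0]


def generate_lattice(config: SimulationConfig) -> RegionLattice:
    """Square-cell lattice with queen neighbours and log-normal populations."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids, polys, blocks = [], [], []
    c = config.cell_km
    for row in range(config.n_rows):
        for col in range(config.n_cols):
            x0, y0 = col * c, row * c
            ids.append(_region_id(row, col))
            polys.append(Polygon([(x0, y0), (x0 + c, y0),
                                  (x0 + c, y0 + c), (x0, y0 + c)]))
            blocks.append(_admin_band(row, config.n_rows))
    pops = np.maximum(1, np.round(rng.lognormal(
        config.pop_log_mean, config.pop_log_sd, len(ids)))).astype(int)
    nbrs = queen_neighbors(ids, polys)
    return RegionLattice(ids, polys, pops, blocks, nbrs)


def _latent_field(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Smoothed-noise log-scale field, one (n_rows, n_cols) grid, sd=field_sd."""
    noise = rng.standard_normal((config.n_rows, config.n_cols))
    if config.field_sd == 0:
        return np.zeros_like(noise)
    sigma = config.spatial_range_km / config.cell_km
    if sigma > 0:
        noise = gaussian_filter(noise, sigma=sigma, mode="wrap")
    noise = noise - noise.mean()        # rescale the fluctuations only
    sd = noise.std()
    if sd > 0:
        noise = noise * (config.field_sd / sd)
    return noise


def generate_risk_surface(lattice: RegionLattice,
                          config: SimulationConfig) -> GroundTruth:
    """Latent log-rate per region/indicator/year.

    log rate = log(base) + block effects + spatial field
               + (year - year0) * log(global and block trend) + log(year shock)
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    years = config.year_list
    y0 = years[0]
    n = lattice.n_regions
    rows = np.array([int(rid[1:4]) for rid in lattice.region_ids])
    cols = np.array([int(rid[4:7]) for rid in lattice.region_ids])
    latent: dict[str, np.ndarray] = {}
    for v in config.indicators:
        base = config.base_rate[v]
        if base == 0:
            latent[v] = np.zeros((n, len(years)))
            continue
        fld = _latent_field(config, rng)[rows, cols]
        log_rate = np.log(base) + fld
        trend = math.log(config.trend_per_year.get(v, 1.0))
        trend_vec = np.full(n, trend)
        for b in config.blocks:
            inside = (b.row0 <= rows) & (rows <= b.row1) & \
                     (b.col0 <= cols) & (cols <= b.col1)
            log_rate = log_rate + inside * math.log(b.rate_factors.get(v, 1.0))
            trend_vec = trend_vec + inside * math.log(b.trend_factors.get(v, 1.0))
        shocks = config.year_shocks.get(v, {})
        surf = np.empty((n, len(years)))
        for t, year in enumerate(years):
            surf[:, t] = log_rate + (year - y0) * trend_vec \
                + math.log(shocks.get(year, 1.0))
        latent[v] = np.exp(surf)
    planted = {
        b.name: {
            "region_ids": [lattice.region_ids[i] for i in range(n)
                           if b.contains(rows[i], cols[i])],
            "rate_factors": dict(b.rate_factors),
            "trend_factors": dict(b.trend_factors),
        }
        for b in config.blocks
    }
    return GroundTruth(list(lattice.region_ids), years, latent, planted)


def generate_count_panel(lattice: RegionLattice, truth: GroundTruth,
                         config: SimulationConfig) -> CountPanel:
    """Poisson counts O ~ Poisson(P * rate / 1e5), complete long panel."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    records = []
    P = lattice.populations
    for v in config.indicators:
        rates = truth.latent_rates[v]
        for t, year in enumerate(truth.years):
            lam = P * rates[:, t] / 1e5
            counts = rng.poisson(lam)
            for i, rid in enumerate(lattice.region_ids):
                records.append((rid, year, v, int(counts[i]), int(P[i])))
    df = pd.DataFrame(records, columns=["region_id", "year", "indicator",
                                        "count", "population"])
    return CountPanel(df)


def simulate(config: SimulationConfig) -> tuple[RegionLattice, GroundTruth, CountPanel]:
    """Convenience wrapper: lattice, ground truth and counts in one call."""
    lattice = generate_lattice(config)
    truth = generate_risk_surface(lattice, config)
    panel = generate_count_panel(lattice, truth, config)
    return lattice, truth, panel


def write_fixture(lattice: RegionLattice, panel: CountPanel, truth: GroundTruth,
                  outdir: str | Path) -> dict[str, Path]:
    """Emit regions GeoJSON, counts CSV and ground-truth JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "regions": outdir / "regions.geojson",
        "counts": outdir / "counts.csv",
        "truth": outdir / "ground_truth.json",
    }
    write_regions(lattice, paths["regions"])
    write_counts(panel, paths["counts"])
    truth_doc = {
        "region_ids": truth.region_ids,
        "years": truth.years,
        "planted_blocks": truth.planted_blocks,
        "latent_rates": {v: a.tolist() for v, a in truth.latent_rates.items()},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh)
    return paths


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        doc = json.load(fh)
    return GroundTruth(
        doc["region_ids"], doc["years"],
        {v: np.asarray(a) for v, a in doc["latent_rates"].items()},
        doc["planted_blocks"])
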
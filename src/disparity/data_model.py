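"""Core spatial data structures and standard-format I/O.

The analysis unit is a *health region*: a polygon with a unique id, a
population at risk (residents aged 40-79), and a macro-region label.  All
coordinates are planar kilometres; neighbourhood is queen contiguity (two
regions are neighbours if their polygons share at least one boundary point).

Formats: regions travel as GeoJSON FeatureCollections, count panels as long
CSV (``region_id,year,indicator,count,population``), contiguity weights as
GAL neighbour lists.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import sparse
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

from .errors import SchemaError, ValidationError

INDICATORS = ("diagnosis", "treatment", "death")

COUNTS_COLUMNS = ["region_id", "year", "indicator", "count", "population"]


# ---------------------------------------------------------------------------
# RegionLattice
# ---------------------------------------------------------------------------


@dataclass
class RegionLattice:
    """Polygon regions with ids, centroids, populations and queen neighbours.

    ``neighbors`` maps each region_id to the *set* of region_ids whose
    polygons share at least a boundary point with it (symmetric, irreflexive).
    """

    region_ids: list[str]
    polygons: list[shapely.Polygon]
    populations: np.ndarray          # int, persons aged 40-79
    admin_blocks: list[str]          # macro-region label per region
    neighbors: dict[str, set[str]]

    def __post_init__(self) -> None:
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValidationError("region_ids are not unique")
        self.populations = np.asarray(self.populations)
        if np.any(self.populations <= 0):
            raise ValidationError("populations must be strictly positive")
        self._index = {rid: i for i, rid in enumerate(self.region_ids)}
        for rid, nbrs in self.neighbors.items():
            if rid in nbrs:
                raise ValidationError(f"region {rid} is its own neighbor")
            for other in nbrs:
                if rid not in self.neighbors[other]:
                    raise ValidationError("neighbor relation not symmetric")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index(self, region_id: str) -> int:
        return self._index[region_id]

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of polygon centroids in km."""
        return np.array([[p.centroid.x, p.centroid.y] for p in self.polygons])

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the union of all polygons."""
        bounds = np.array([p.bounds for p in self.polygons])
        return (bounds[:, 0].min(), bounds[:, 1].min(),
                bounds[:, 2].max(), bounds[:, 3].max())


def queen_neighbors(region_ids: Sequence[str],
                    polygons: Sequence[shapely.Polygon]) -> dict[str, set[str]]:
    """Queen contiguity from geometry: neighbours share >= 1 boundary point."""
    tree = shapely.STRtree(polygons)
    left, right = tree.query(polygons, predicate="intersects")
    nbrs: dict[str, set[str]] = {rid: set() for rid in region_ids}
    for i, j in zip(left, right):
        if i != j:
            nbrs[region_ids[i]].add(region_ids[j])
            nbrs[region_ids[j]].add(region_ids[i])
    return nbrs


def read_regions(path: str | Path) -> RegionLattice:
    """Load a GeoJSON FeatureCollection of regions and compute queen neighbours.

    Each feature must carry ``region_id`` (string) and ``population``
    (positive integer) properties; ``admin_block`` defaults to ``""``.
    """
    path = Path(path)
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    ids: list[str] = []
    polys: list[shapely.Polygon] = []
    pops: list[int] = []
    blocks: list[str] = []
    for k, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        if "region_id" not in props:
            raise SchemaError(f"{path}: feature {k} lacks 'region_id'")
        rid = str(props["region_id"])
        if "population" not in props:
            raise SchemaError(f"{path}: feature '{rid}' lacks 'population'")
        try:
            geom = geom_shape(feat["geometry"])
        except Exception as exc:  # noqa: BLE001 - report which feature failed
            raise SchemaError(f"{path}: feature '{rid}' has invalid geometry: {exc}")
        if geom.is_empty or not geom.is_valid:
            raise SchemaError(f"{path}: feature '{rid}' has invalid geometry")
        ids.append(rid)
        polys.append(geom)
        pops.append(int(props["population"]))
        blocks.append(str(props.get("admin_block", "")))
    nbrs = queen_neighbors(ids, polys)
    islands = [rid for rid in ids if not nbrs[rid]]
    if islands:
        warnings.warn(f"{len(islands)} island region(s) with no neighbors: "
                      f"{islands[:5]}", stacklevel=2)
    return RegionLattice(ids, polys, np.array(pops), blocks, nbrs)


def write_regions(lattice: RegionLattice, path: str | Path) -> None:
    """Write the lattice as a GeoJSON FeatureCollection."""
    features = []
    for i, rid in enumerate(lattice.region_ids):
        features.append({
            "type": "Feature",
            "geometry": geom_mapping(lattice.polygons[i]),
            "properties": {
                "region_id": rid,
                "population": int(lattice.populations[i]),
                "admin_block": lattice.admin_blocks[i],
            },
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# CountPanel
# ---------------------------------------------------------------------------


@dataclass
class CountPanel:
    """Long-format region x year x indicator panel of event counts.

    ``data`` columns: region_id, year, indicator, count, population.
    (region_id, year, indicator) is a unique key; counts are >= 0 and
    populations > 0.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"count panel lacks columns: {missing}")
        if (df["count"] < 0).any():
            bad = df.index[df["count"] < 0][0]
            raise ValidationError(f"negative count at row {bad}")
        if (df["population"] <= 0).any():
            bad = df.index[df["population"] <= 0][0]
            raise ValidationError(f"non-positive population at row {bad}")
        dup = df.duplicated(subset=["region_id", "year", "indicator"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["region_id", "year", "indicator"]]
            raise ValidationError(f"duplicate cell {tuple(key)}")
        years = np.sort(df["year"].unique())
        if len(years) > 1 and not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise ValidationError("years are not contiguous")

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data["year"].unique())

    @property
    def indicators(self) -> list[str]:
        return sorted(self.data["indicator"].unique())

    def complete(self, lattice: RegionLattice) -> bool:
        expected = lattice.n_regions * len(self.years) * len(self.indicators)
        return len(self.data) == expected


def read_counts(path: str | Path, lattice: RegionLattice) -> CountPanel:
    """Read a counts CSV and validate it against the lattice."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df["region_id"] = df["region_id"].astype(str)
    unknown = set(df["region_id"]) - set(lattice.region_ids)
    if unknown:
        raise ValidationError(f"{path}: unknown region_id(s) {sorted(unknown)[:5]}")
    panel = CountPanel(df)
    n_expected = lattice.n_regions * len(panel.years) * len(panel.indicators)
    if len(df) < n_expected:
        warnings.warn(f"{path}: panel incomplete "
                      f"({len(df)} of {n_expected} cells)", stacklevel=2)
    return panel


def write_counts(panel: CountPanel, path: str | Path) -> None:
    panel.data.to_csv(path, index=False, columns=COUNTS_COLUMNS)


def aggregate_to_regions(panel: CountPanel, mapping: Mapping[str, str]) -> CountPanel:
    """Aggregate a finer-unit panel to regions by *summing* counts and populations.

    The rate of a union of areas is the ratio of summed numerators and
    denominators; averaging sub-unit rates would weight small units
    incorrectly, so summation is the fixed semantics here.
    """
    df = panel.data.copy()
    unknown = set(df["region_id"]) - set(mapping)
    if unknown:
        raise ValidationError(f"units without region mapping: {sorted(unknown)[:5]}")
    df["region_id"] = df["region_id"].map(mapping)
    out = (df.groupby(["region_id", "year", "indicator"], as_index=False)
             [["count", "population"]].sum())
    return CountPanel(out)


# ---------------------------------------------------------------------------
# WeightsMatrix
# ---------------------------------------------------------------------------


@dataclass
class WeightsMatrix:
    """Spatial weights as per-region neighbour/weight lists.

    Binary queen weights are symmetric; row standardization rescales each
    row to sum to 1 (islands keep empty rows).
    """

    ids: list[str]
    neighbor_idx: list[np.ndarray]   # per region, indices of neighbours
    weights: list[np.ndarray]        # matching weights
    standardized: bool = False
    _csr: sparse.csr_matrix | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def S0(self) -> float:
        """Sum of all weights."""
        return float(sum(w.sum() for w in self.weights))

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbor_idx])

    def to_sparse(self) -> sparse.csr_matrix:
        if self._csr is None:
            rows, cols, vals = [], [], []
            for i, (nb, w) in enumerate(zip(self.neighbor_idx, self.weights)):
                rows.extend([i] * len(nb))
                cols.extend(nb.tolist())
                vals.extend(w.tolist())
            self._csr = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(self.n, self.n))
        return self._csr

    def lag(self, x: np.ndarray) -> np.ndarray:
        """Spatial lag W x (row-wise weighted sums of neighbour values)."""
        return self.to_sparse() @ np.asarray(x, dtype=float)

    def row_standardize(self) -> "WeightsMatrix":
        new_w = []
        for w in self.weights:
            s = w.sum()
            new_w.append(w / s if s > 0 else w.copy())
        return WeightsMatrix(self.ids, [nb.copy() for nb in self.neighbor_idx],
                             new_w, standardized=True)

    @classmethod
    def from_neighbors(cls, ids: Sequence[str],
                       neighbors: Mapping[str, Iterable[str]],
                       standardized: bool = False) -> "WeightsMatrix":
        """Binary weights from a neighbour-set mapping (optionally standardized)."""
        index = {rid: i for i, rid in enumerate(ids)}
        nb_idx = [np.array(sorted(index[j] for j in neighbors[rid]), dtype=int)
                  for rid in ids]
        w = [np.ones(len(nb)) for nb in nb_idx]
        out = cls(list(ids), nb_idx, w, standardized=False)
        return out.row_standardize() if standardized else out


def build_queen_weights(lattice: RegionLattice,
                        standardized: bool = False) -> WeightsMatrix:
    """Queen contiguity weights for a lattice (binary or row-standardized)."""
    islands = [rid for rid in lattice.region_ids if not lattice.neighbors[rid]]
    if islands:
        warnings.warn(f"weights contain {len(islands)} island(s)", stacklevel=2)
    return WeightsMatrix.from_neighbors(lattice.region_ids, lattice.neighbors,
                                        standardized=standardized)


def write_gal(weights: WeightsMatrix, path: str | Path) -> None:
    """Write weights as a GAL neighbour list (ids, not positions)."""
    with open(path, "w") as fh:
        fh.write(f"{weights.n}\n")
        for i, rid in enumerate(weights.ids):
            nb = weights.neighbor_idx[i]
            fh.write(f"{rid} {len(nb)}\n")
            fh.write(" ".join(weights.ids[j] for j in nb) + "\n")


def read_gal(path: str | Path) -> WeightsMatrix:
    """Read a GAL neighbour list back into binary weights."""
    path = Path(path)
    lines = [ln.strip() for ln in open(path)]
    if not lines:
        raise SchemaError(f"{path}: empty GAL file")
    try:
        n = int(lines[0].split()[-1])
    except ValueError:
        raise SchemaError(f"{path}: line 1: malformed header")
    ids: list[str] = []
    nbrs: dict[str, list[str]] = {}
    pos = 1
    while pos < len(lines) and lines[pos]:
        parts = lines[pos].split()
        if len(parts) != 2:
            raise SchemaError(f"{path}: line {pos + 1}: expected 'id count'")
        rid, cnt_s = parts
        try:
            cnt = int(cnt_s)
        except ValueError:
            raise SchemaError(f"{path}: line {pos + 1}: malformed count")
        if cnt > 0:
            if pos + 1 >= len(lines):
                raise SchemaError(f"{path}: line {pos + 2}: missing neighbor list")
            nb = lines[pos + 1].split()
            if len(nb) != cnt:
                raise SchemaError(
                    f"{path}: line {pos + 2}: {len(nb)} neighbors, expected {cnt}")
            pos += 2
        else:
            nb = []
            # an empty-neighbour region may or may not carry its blank line
            pos += 2 if pos + 1 < len(lines) and lines[pos + 1] == "" else 1
        ids.append(rid)
        nbrs[rid] = nb
    if len(ids) != n:
        raise SchemaError(f"{path}: header says {n} regions, found {len(ids)}")
    return WeightsMatrix.from_neighbors(ids, nbrs)


# ---------------------------------------------------------------------------
# CohortTable
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Stratified cohort counts per indicator.

    ``data`` columns: indicator, partition (e.g. "sex" or "site"), stratum,
    count.  ``totals`` maps indicator -> cohort total.  Partitions named in
    ``exhaustive`` must have strata summing exactly to the total; other
    partitions may overlap (registry site codes can assign one patient to
    several primary sites, so site counts need not partition the cohort).
    """

    data: pd.DataFrame
    totals: dict[str, int]
    exhaustive: frozenset[str] = frozenset({"sex"})

    def __post_init__(self) -> None:
        if (self.data["count"] < 0).any():
            raise ValidationError("negative cohort count")
        for (ind, part), grp in self.data.groupby(["indicator", "partition"]):
            if ind not in self.totals:
                raise ValidationError(f"no total for indicator '{ind}'")
            if part in self.exhaustive and \
                    int(grp["count"].sum()) != int(self.totals[ind]):
                raise ValidationError(
                    f"strata of {ind}/{part} sum to {grp['count'].sum()}, "
                    f"total is {self.totals[ind]}")


def _share(count: int, total: int) -> float:
    """Percentage share at two decimals, round-half-even, computed exactly."""
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def summarize_cohort(table: CohortTable) -> pd.DataFrame:
    """Per-stratum percentage shares (two decimals, round-half-even).

    Returns a frame with indicator, partition, stratum, count, total, share.
    """
    rows = []
    for _, rec in table.data.iterrows():
        total = int(table.totals[rec["indicator"]])
        if total == 0:
            raise ValidationError(
                f"undefined proportion: zero total for '{rec['indicator']}'")
        rows.append({
            "indicator": rec["indicator"],
            "partition": rec["partition"],
            "stratum": rec["stratum"],
            "count": int(rec["count"]),
            "total": total,
            "share": _share(int(rec["count"]), total),
        })
    return pd.DataFrame(rows)
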
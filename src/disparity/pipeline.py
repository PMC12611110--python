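"""End-to-end orchestration: simulate/load -> smooth -> trend -> space-time
hotspots -> LISA -> HMR, with a YAML config and deterministic file outputs."""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .data_model import (CountPanel, RegionLattice, build_queen_weights,
                         read_counts, read_regions, summarize_cohort)
from .datasets import load_rtc_cohort
from .errors import ConfigError
from .hmr_kde import (classify_hmr, compute_hmr, default_grid,
                      extract_centroids, ripley_k, select_bandwidth,
                      weighted_kde, write_asc)
from .smoothing import quinquennial_mean, spatial_eb_smooth
from .spacetime_hotspots import build_cube, classify_emerging, cube_overall_trend, gi_star
from .spatial_autocorrelation import lisa_cluster_table, local_morans, morans_i
from .synthetic_data import SimulationConfig, simulate, write_fixture
from .trend_tests import regional_trend_table

_STC_KEYS = {"k_t", "pct_threshold", "alpha_mk"}
_LISA_KEYS = {"n_perm", "seed", "alpha", "fdr"}
_HMR_KEYS = {"bandwidth", "n_cells", "weight_mode", "tolerance",
             "fallback_bandwidth"}
_TOP_KEYS = {"simulation", "inputs", "quinquennia", "stc", "lisa", "hmr",
             "output_dir"}


@dataclass
class PipelineConfig:
    """Validated run configuration; every stage seed is explicit."""

    output_dir: Path
    simulation: SimulationConfig | None = None
    regions_path: Path | None = None
    counts_path: Path | None = None
    quinquennia: list[tuple[int, int]] = field(
        default_factory=lambda: [(2013, 2017), (2018, 2022)])
    k_t: int = 1
    pct_threshold: float = 0.9
    alpha_mk: float = 0.05
    n_perm: int = 999
    lisa_seed: int = 0
    alpha: float = 0.05
    fdr: bool = False
    bandwidth: str | float = "auto"
    n_cells: int = 200
    weight_mode: str = "own"
    tolerance: float = 0.1
    fallback_bandwidth: float = 470.0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.regions_path is None):
            raise ConfigError(
                "exactly one of 'simulation' and 'inputs' must be given")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha out of range: {self.alpha}")
        if not 0 < self.alpha_mk < 1:
            raise ConfigError(f"alpha_mk out of range: {self.alpha_mk}")
        if not 0 < self.pct_threshold <= 1:
            raise ConfigError(f"pct_threshold out of range: {self.pct_threshold}")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.k_t < 0:
            raise ConfigError("k_t must be >= 0")
        if self.weight_mode not in ("own", "mortality"):
            raise ConfigError(f"unknown weight_mode: {self.weight_mode}")
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "auto":
                raise ConfigError("bandwidth must be 'auto' or a number (km)")
        elif self.bandwidth <= 0:
            raise ConfigError("bandwidth must be positive")
        if self.tolerance <= 0:
            raise ConfigError("tolerance must be positive")


def _require_keys(section: dict, allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}': {sorted(unknown)}")


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config (unknown keys rejected)."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    _require_keys(doc, _TOP_KEYS, "config")
    if "output_dir" not in doc:
        raise ConfigError("config must set 'output_dir'")
    kwargs: dict = {"output_dir": Path(doc["output_dir"])}
    if "simulation" in doc:
        sim = dict(doc["simulation"])
        if "seed" not in sim:
            raise ConfigError("simulation config must set an explicit seed")
        if "years" in sim:
            sim["years"] = tuple(sim["years"])
        try:
            kwargs["simulation"] = SimulationConfig(**sim)
        except TypeError as exc:
            raise ConfigError(f"simulation config: {exc}")
    if "inputs" in doc:
        inp = dict(doc["inputs"])
        _require_keys(inp, {"regions", "counts"}, "inputs")
        kwargs["regions_path"] = Path(inp["regions"])
        kwargs["counts_path"] = Path(inp["counts"])
    if "quinquennia" in doc:
        kwargs["quinquennia"] = [tuple(q) for q in doc["quinquennia"]]
    stc = doc.get("stc", {})
    _require_keys(stc, _STC_KEYS, "stc")
    kwargs.update({k: stc[k] for k in stc})
    lisa = doc.get("lisa", {})
    _require_keys(lisa, _LISA_KEYS, "lisa")
    if "seed" not in lisa:
        raise ConfigError("lisa config must set an explicit seed")
    kwargs["lisa_seed"] = lisa["seed"]
    kwargs.update({k: lisa[k] for k in lisa if k != "seed"})
    hmr = doc.get("hmr", {})
    _require_keys(hmr, _HMR_KEYS, "hmr")
    kwargs.update({k: hmr[k] for k in hmr})
    cfg = PipelineConfig(**kwargs)
    if cfg.simulation is not None:
        years = set(cfg.simulation.year_list)
        covered = set()
        for y0, y1 in cfg.quinquennia:
            covered |= set(range(y0, y1 + 1))
        if covered != years:
            raise ConfigError("quinquennia do not partition the year range")
    return cfg


def _lisa_geojson(lattice: RegionLattice, result, path: Path) -> None:
    from shapely.geometry import mapping as geom_mapping
    feats = []
    for i, rid in enumerate(result.ids):
        j = lattice.index(rid)
        feats.append({
            "type": "Feature",
            "geometry": geom_mapping(lattice.polygons[j]),
            "properties": {
                "region_id": rid,
                "I_local": float(result.I_local[i]),
                "quadrant": result.quadrant[i],
                "pseudo_p": float(result.pseudo_p[i]),
                "significant": bool(result.significant[i]),
            },
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact files; returns a result bundle.

    Outputs in ``config.output_dir``: rates.csv, trends.csv, emerging.csv,
    lisa_<indicator>_<period>.geojson, hmr_<period>.asc, ripley_<period>.csv,
    cohort_summary.csv, manifest.json (plus the synthetic fixture when
    simulating).  Identical config gives identical outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        lattice, truth, panel = simulate(config.simulation)
        write_fixture(lattice, panel, truth, outdir / "fixture")
    else:
        lattice = read_regions(config.regions_path)
        panel = read_counts(config.counts_path, lattice)

    weights = build_queen_weights(lattice)
    weights_std = weights.row_standardize()

    rates = spatial_eb_smooth(panel, weights)
    rates.to_csv(outdir / "rates.csv", index=False)

    trends = regional_trend_table(rates, lattice)
    trends.to_csv(outdir / "trends.csv", index=False)

    quinq = quinquennial_mean(rates, periods=config.quinquennia)
    quinq.to_csv(outdir / "quinquennial.csv", index=False)

    indicators = sorted(panel.indicators)
    periods = [f"{y0}-{y1}" for y0, y1 in config.quinquennia]

    emerging_frames = []
    cube_trends = {}
    for ind in indicators:
        cube = build_cube(rates, lattice, ind, k_t=config.k_t)
        fieldz = gi_star(cube)
        em = classify_emerging(fieldz, config.pct_threshold, config.alpha_mk)
        em.insert(0, "indicator", ind)
        emerging_frames.append(em)
        mk = cube_overall_trend(cube)
        cube_trends[ind] = {"Z": mk.Z, "p": mk.p, "tau": mk.tau, "S": mk.S}
    import pandas as pd
    emerging = pd.concat(emerging_frames, ignore_index=True)
    emerging.to_csv(outdir / "emerging.csv", index=False)

    moran = {}
    lisa_results = {}
    for ind in indicators:
        for per in periods:
            x = (quinq[(quinq["indicator"] == ind) & (quinq["period"] == per)]
                 .set_index("region_id")["mean_rate"]
                 .reindex(lattice.region_ids).to_numpy())
            mres = morans_i(x, weights_std, n_perm=config.n_perm,
                            seed=config.lisa_seed)
            moran[f"{ind}_{per}"] = {"I": mres.I, "pseudo_p": mres.pseudo_p}
            lres = local_morans(x, weights_std, n_perm=config.n_perm,
                                seed=config.lisa_seed, alpha=config.alpha,
                                fdr=config.fdr)
            lisa_results[(ind, per)] = lres
            _lisa_geojson(lattice, lres,
                          outdir / f"lisa_{ind}_{per}.geojson")
            per_region, per_block = lisa_cluster_table(lres, lattice)
            per_block.to_csv(outdir / f"lisa_{ind}_{per}_blocks.csv",
                             index=False)

    hmr_summaries = {}
    hmr_rasters = {}
    bandwidths = {}
    for per in periods:
        points, wts = extract_centroids(lattice, quinq, per)
        rip = ripley_k(points)
        pd.DataFrame({"d": rip.d, "K": rip.K, "theoretical": rip.theoretical,
                      "diff": rip.diff}).to_csv(
            outdir / f"ripley_{per}.csv", index=False)
        if config.bandwidth == "auto":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                h = select_bandwidth(rip, fallback=config.fallback_bandwidth)
        else:
            h = float(config.bandwidth)
        bandwidths[per] = h
        grid = default_grid(points, h, n_cells=config.n_cells)
        surfaces = {}
        for ind in indicators:
            w = wts["death"] if config.weight_mode == "mortality" else wts[ind]
            surfaces[ind] = weighted_kde(points, w, h, grid, indicator=ind)
        hmr = compute_hmr(surfaces["diagnosis"], surfaces["treatment"],
                          surfaces["death"])
        write_asc(grid, hmr.values, outdir / f"hmr_{per}.asc")
        hmr_rasters[per] = hmr
        hmr_summaries[per] = classify_hmr(hmr, config.tolerance)
        hmr_summaries[per].to_csv(outdir / f"hmr_{per}_bands.csv", index=False)

    cohort = summarize_cohort(load_rtc_cohort())
    cohort.to_csv(outdir / "cohort_summary.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config": _manifest_config(config),
        "cube_trends": cube_trends,
        "moran": moran,
        "bandwidth_km": bandwidths,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return {
        "lattice": lattice, "panel": panel, "rates": rates, "trends": trends,
        "quinquennial": quinq, "emerging": emerging,
        "cube_trends": cube_trends, "moran": moran, "lisa": lisa_results,
        "bandwidths": bandwidths, "hmr_bands": hmr_summaries,
        "hmr": hmr_rasters,
        "cohort": cohort, "manifest": manifest,
    }


def _manifest_config(config: PipelineConfig) -> dict:
    doc = asdict(config)
    doc["output_dir"] = str(doc["output_dir"])
    if doc["simulation"] is not None:
        sim = doc["simulation"]
        sim["years"] = list(sim["years"])
    for key in ("regions_path", "counts_path"):
        if doc[key] is not None:
            doc[key] = str(doc[key])
    doc["quinquennia"] = [list(q) for q in doc["quinquennia"]]
    return doc
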
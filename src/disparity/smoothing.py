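"""Raw rates, spatial empirical Bayes smoothing, and quinquennial means.

Small-area event rates are unstable where the population at risk is small.
The spatial (local) empirical Bayes estimator shrinks each region's raw rate
r_i = O_i / P_i toward a reference rate computed on its queen-contiguity
window W_i = {i} u neighbours(i):

    mu_i  = sum_{j in W_i} O_j / sum_{j in W_i} P_j
    A_i   = sum P_j (r_j - mu_i)^2 / sum P_j           (weighted spread)
    s2_i  = max(0, A_i - mu_i / mean_{W_i}(P))         (prior variance)
    w_i   = s2_i / (s2_i + mu_i / P_i)                 (shrinkage weight)
    theta_i = w_i r_i + (1 - w_i) mu_i

All rates are carried per-unit internally and scaled x 100,000 only on
output.  Smoothing is applied independently per year and indicator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from .data_model import CountPanel, WeightsMatrix
from .errors import ValidationError

RATE_SCALE = 1e5

RATE_COLUMNS = ["region_id", "year", "indicator", "raw_rate", "smoothed_rate",
                "mu", "s2", "shrink_w"]


def raw_rate(panel: CountPanel) -> pd.DataFrame:
    """Raw rates per 100,000: r = 1e5 * O / P.

    Returns a RatePanel frame (smoothing columns filled with the raw rate and
    degenerate shrinkage so it is usable wherever a smoothed panel is).
    """
    df = panel.data.copy()
    if (df["population"] <= 0).any():
        raise ValidationError("undefined rate: population must be positive")
    df["raw_rate"] = RATE_SCALE * df["count"] / df["population"]
    df["smoothed_rate"] = df["raw_rate"]
    df["mu"] = df["raw_rate"]
    df["s2"] = 0.0
    df["shrink_w"] = 1.0
    return df[RATE_COLUMNS]


def _window_matrix(weights: WeightsMatrix) -> sparse.csr_matrix:
    """Binary window operator: queen adjacency plus self."""
    return (weights.to_sparse() > 0).astype(float) + sparse.identity(weights.n)


def spatial_eb_smooth(panel: CountPanel, weights: WeightsMatrix) -> pd.DataFrame:
    """Spatial empirical Bayes smoothing per year and indicator.

    ``weights`` must be binary queen weights on the same regions, in the same
    order, as the panel's lattice.  Returns a RatePanel frame with columns
    region_id, year, indicator, raw_rate, smoothed_rate, mu, s2, shrink_w
    (rates per 100,000; mu and s2 also on the per-100,000 scale).
    """
    if weights.standardized:
        raise ValidationError("spatial EB smoothing requires binary weights")
    order = {rid: k for k, rid in enumerate(weights.ids)}
    W = _window_matrix(weights)
    wsize = np.asarray(W.sum(axis=1)).ravel()

    frames = []
    for (year, ind), grp in panel.data.groupby(["year", "indicator"], sort=True):
        grp = grp.sort_values("region_id", key=lambda s: s.map(order))
        if len(grp) != weights.n:
            raise ValidationError(
                f"panel for {ind}/{year} has {len(grp)} regions, weights have {weights.n}")
        O = grp["count"].to_numpy(dtype=float)
        P = grp["population"].to_numpy(dtype=float)
        r = O / P
        sumO = W @ O
        sumP = W @ P
        mu = sumO / sumP
        # weighted spread around mu_i, expanded so it is three sparse matvecs
        sum_Pr2 = W @ (P * r * r)
        sum_Pr = W @ (P * r)
        A = (sum_Pr2 - 2 * mu * sum_Pr + mu * mu * sumP) / sumP
        pbar = sumP / wsize
        s2 = np.maximum(0.0, A - mu / pbar)
        denom = s2 + mu / P
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(denom > 0, s2 / denom, 0.0)
        theta = w * r + (1 - w) * mu
        frames.append(pd.DataFrame({
            "region_id": grp["region_id"].to_numpy(),
            "year": year,
            "indicator": ind,
            "raw_rate": RATE_SCALE * r,
            "smoothed_rate": RATE_SCALE * theta,
            "mu": RATE_SCALE * mu,
            "s2": RATE_SCALE ** 2 * s2,
            "shrink_w": w,
        }))
    return pd.concat(frames, ignore_index=True)[RATE_COLUMNS]


def quinquennial_mean(rates: pd.DataFrame,
                      periods: list[tuple[int, int]] | None = None,
                      value: str = "smoothed_rate") -> pd.DataFrame:
    """Mean rate per (region, indicator, period) over five-year windows.

    Default periods are (2013, 2017) and (2018, 2022).  Every year of every
    period must be present for every region/indicator.
    """
    if periods is None:
        periods = [(2013, 2017), (2018, 2022)]
    out = []
    for y0, y1 in periods:
        want = set(range(y0, y1 + 1))
        sub = rates[rates["year"].between(y0, y1)]
        counts = sub.groupby(["region_id", "indicator"])["year"].nunique()
        short = counts[counts < len(want)]
        if len(short):
            rid, ind = short.index[0]
            have = set(sub[(sub["region_id"] == rid)
                           & (sub["indicator"] == ind)]["year"])
            raise ValidationError(
                f"region {rid}, indicator {ind}: missing year(s) "
                f"{sorted(want - have)} in period {y0}-{y1}")
        g = sub.groupby(["region_id", "indicator"], as_index=False)[value].mean()
        g["period"] = f"{y0}-{y1}"
        out.append(g.rename(columns={value: "mean_rate"}))
    return pd.concat(out, ignore_index=True)[
        ["region_id", "indicator", "period", "mean_rate"]]
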
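# disparity

Spatio-temporal disparity analysis of region-level cancer **diagnosis,
treatment and mortality** rates, built around the workflow used to study
respiratory tract cancers (ICD-10 C32/C33/C34) across Brazil's 438 health
regions, 2013–2022: rate stabilisation for small areas, trend inference,
space–time hotspot detection, spatial cluster mapping, and a kernel-density
ratio contrasting healthcare effort with mortality.  A seeded synthetic
health-region generator with planted ground truth makes every stage testable
without access to the registry extracts.

Intended users: epidemiologists and health-services researchers analysing
region × year × indicator count panels.

## What it computes

**Spatial empirical Bayes smoothing.**  Raw rates r_i = 10⁵·O_i/P_i (events
over the 40–79 population) are shrunk toward the rate of the queen-contiguity
window W_i = {i} ∪ neighbours(i):

    μ_i = ΣO_j / ΣP_j,   s²_i = max(0, A_i − μ_i / P̄_i),
    w_i = s²_i / (s²_i + μ_i / P_i),   θ̂_i = w_i r_i + (1 − w_i) μ_i

with A_i the population-weighted spread of window rates around μ_i.

**Mann–Kendall trend test.**  S = Σ_{i<j} sgn(x_j − x_i) with tie-corrected
variance, continuity-corrected Z, tau-b, and the exact null distribution of S
for short tie-free series (n ≤ 10).

**Space–time cube & emerging hotspots.**  Per-bin Getis–Ord Gi* over a
queen × (±1 year) neighbourhood, then per-region categories (new,
consecutive, intensifying, persistent, diminishing, sporadic, oscillating,
historical — hot/cold) from the time pattern of significant bins and the
Mann–Kendall trend of the z-series.

**Moran's I and LISA.**  Global I and local I_i on quinquennial mean smoothed
rates with seeded (conditional) permutation inference and high–high /
low–low / high–low / low–high cluster labels.

**Healthcare-and-mortality ratio (HMR).**  Weighted Gaussian KDE surfaces
anchored at region centroids, bandwidth from the maximum of K̂(d) − πd²
(Ripley's K), and

    HMR(x) = (KDE_diag(x) + KDE_treat(x)) / (KDE_mort(x) + 1).

## Worked example

```python
import disparity as dp

cfg = dp.SimulationConfig(seed=1)              # 20 x 22 regions, 2013-2022
lattice, truth, panel = dp.simulate(cfg)
weights = dp.build_queen_weights(lattice)
rates = dp.spatial_eb_smooth(panel, weights)

cube = dp.build_cube(rates, lattice, "diagnosis")
print(dp.cube_overall_trend(cube))             # trend of per-year means

quinq = dp.quinquennial_mean(rates)
x = (quinq.query("indicator == 'diagnosis' and period == '2013-2017'")
     .set_index("region_id")["mean_rate"].reindex(lattice.region_ids).to_numpy())
print(dp.morans_i(x, weights.row_standardize(), n_perm=999, seed=2).I)
```

prints (seed 1)

```
MannKendallResult(S=37, var_S=125.0, Z=3.2199..., tau=0.822...,
                  p=0.000358, n=10, method='exact', degenerate=False)
0.9712272287601837
```

i.e. the synthetic study reproduces the qualitative results of the real one:
a strongly significant rise in diagnosis rates over the decade and very
strong positive spatial autocorrelation of the quinquennial mean rates
(national analyses of these indicators reported Moran's I between 0.889 and
0.937, and trend statistics near 3.2 for diagnosis with a flat mortality
trend).  The descriptive cohort summary of the bundled national count table
prints, among others, a 29.91 % laryngeal share of diagnoses and a 62.78 %
male share of deaths.

The same run from the shell:

```bash
disparity run --config examples/synthetic.yaml
```

writes `rates.csv`, `trends.csv`, `emerging.csv`, per-period LISA GeoJSONs,
HMR rasters (Esri ASCII), Ripley curves and a config-echoing manifest under
`out/synthetic_demo/`.

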
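# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, the numerical conventions, and what the synthetic data
do and do not establish.

## Data model

The analysis unit is a *health region*: a polygon with a population at risk
(residents aged 40–79 — restricting to the high-incidence age band is the
only standardisation applied; no direct age adjustment is performed).  Counts
arrive as a long panel (region, year, indicator ∈ {diagnosis, treatment,
death}, count, population) with populations held constant across years within
a region, as census-based denominators effectively are over a decade.
Sub-regional inputs can be aggregated with `aggregate_to_regions`, which
**sums** counts and populations: the rate of a union of areas is the ratio of
summed numerators and denominators, whereas averaging sub-unit rates would
overweight small units.

Queen contiguity (any shared boundary point) defines all spatial
neighbourhoods, detected geometrically via an STR-tree intersection query.
Weights are binary for the empirical Bayes windows and row-standardized for
Moran/LISA.  Islands are permitted with a warning; their LISA statistic is 0
and they are never flagged significant.

Cohort tables distinguish exhaustive partitions (sex, strata must sum to the
total) from potentially overlapping ones (registry site codes can assign one
patient several primary sites, so site counts may exceed the cohort total).
Shares are percentages at two decimals, round-half-even, computed in exact
decimal arithmetic.

## Spatial empirical Bayes smoothing

The estimator is the standard *local* ("spatial") empirical Bayes form, the
one implemented by the desktop GIS tools commonly used for disease mapping.
For window W_i = {i} ∪ neighbours(i), with per-unit rates:

    μ_i  = Σ_{W_i} O_j / Σ_{W_i} P_j
    A_i  = Σ_{W_i} P_j (r_j − μ_i)² / Σ_{W_i} P_j
    s²_i = max(0, A_i − μ_i / P̄_i),   P̄_i = Σ_{W_i} P_j / |W_i|
    w_i  = s²_i / (s²_i + μ_i / P_i)
    θ̂_i = w_i r_i + (1 − w_i) μ_i

s²_i estimates the between-region variance of true rates in the window
(method of moments, truncated at zero); μ_i/P_i is the Poisson sampling
variance of r_i.  Consequences used as tests: θ̂ is a convex combination of
r and μ; a homogeneous window is a fixed point; P_i → ∞ gives θ̂ → r; when
s² + μ/P = 0 (an all-zero window) the estimate is μ.  Smoothing is applied
independently per year and indicator — required for the space–time cube to
vary by year — and rates are carried per-unit internally, scaled ×10⁵ only
on output.

## Mann–Kendall trend inference

S = Σ_{i<j} sgn(x_j − x_i); Var(S) uses the standard tie correction; Z
applies the ±1 continuity correction (at n = 10 omitting it visibly changes
p); tau is reported as tau-b, the tie-adjusted form (identical to tau-a on
tie-free series, and the convention of the common R implementations).
For tie-free series with n ≤ 10 the p-value is exact: the null pmf of S
follows from the inversion-count recursion (convolution of uniform{0..k}),
not from enumerating n! orderings; enumeration is used only as an
independent oracle in the tests.  Constant series return S = 0, p = 1 with a
degenerate-variance flag rather than an error.

Regional trend tables apply the test to yearly means of smoothed rates
across each macro-region's member regions.  The two-quinquennia comparison
uses the Wilcoxon–Mann–Whitney test (midranks, tie and continuity corrected
normal approximation; scipy provides the p-value, and the reported Z is
recomputed from U with the same corrections).

## Space–time cube and emerging hotspots

The cube is the complete regions × years grid of annual smoothed rates.
Each bin's neighbourhood is its queen-contiguous regions including itself
crossed with years within ±k_t (default 1).  Gi* compares the neighbourhood
sum with its expectation under the cube-wide mean, normalised by the
cube-wide population standard deviation:

    Gi*(b) = [Σ_{c∈N(b)} x_c − X̄·|N(b)|] / [s·√((n|N(b)| − |N(b)|²)/(n−1))]

A fixed-distance spatial band is the desktop default; queen contiguity is
used here for coherence with the rest of the pipeline and is part of the
cube structure.  Per-step bins are hot/cold at 90 % confidence
(|z| ≥ 1.645, matching sign), with no multiple-testing correction by
default.  The per-region category follows the emerging-hotspot taxonomy,
with the Mann–Kendall test on the region's z-series (normal approximation)
deciding intensifying vs persistent vs diminishing among regions significant
in ≥ 90 % of steps; oscillating takes precedence whenever a step is
significant with the opposite sign.  The cube-wide "trend statistic" is the
Mann–Kendall Z of the per-year spatial means — the natural cube-level
reading of a single national trend number per indicator.

Calibration caveat: under a pure-noise null, empirical-Bayes smoothing
correlates neighbouring rates by construction, which inflates Gi*
significance counts.  The null calibration (≈ 85–90 % of regions "no
pattern") therefore holds for raw null fields; on smoothed null fields the
stage over-flags, which is a property of smoothing-then-scanning pipelines
generally, not of this implementation.

## Moran's I and LISA

Global I = (n/S0)·Σ w_ij z_i z_j / Σ z_i², permutation inference with the
pseudo p-value (1 + #{as extreme, toward the observed sign})/(n_perm + 1),
n_perm = 999 by default and a mandatory seed.  Local
I_i = (z_i/m2)·Σ_j w_ij z_j with m2 = Σ z²/n; the n-denominator moment
convention is deliberate — it yields the exact identity mean(I_i) = I under
row-standardized weights, used as a regression test.  LISA inference is by
conditional permutation (region i's value held fixed, the others shuffled
onto its neighbour slots), quadrants from the signs of z_i and its lag,
significance at α = 0.05 on pseudo p-values, optional Benjamini–Hochberg
control.  Cluster maps are computed on quinquennial mean smoothed rates, but
the functions accept any region-indexed vector.

## HMR: weighted KDE ratio

Region centroids anchor one surface per indicator with weights equal to that
indicator's quinquennial mean smoothed rate.  (The alternative of weighting
all three surfaces by mortality rates is available as
`weight_mode="mortality"`, but it makes the three surfaces identical and the
ratio degenerate, so own-indicator weights are the default.)  The kernel
estimate is

    f̂(x) = 1/(n h²) Σ_i w_i k(‖x − x_i‖/h),  k(u) = (1/2π) e^{−u²/2}

so the plane integral of f̂ is (Σ w_i)/n — the testable mass invariant.  The
bandwidth is the distance maximizing K̂(d) − πd² (Ripley's K without edge
correction, unbiased m(m−1) pair normalisation, bounding-box area by
default, torus metric available for calibration tests); ties resolve to the
smaller distance, and a dispersed pattern (no positive excess, as with
perfectly regular synthetic centroids) falls back to a configured default of
470 km, a scale appropriate for country-wide surfaces.

HMR(x) = (f̂_diag + f̂_treat)/(f̂_mort + 1) exactly as defined, including the
unit-dependent "+1" in the mortality layer's native density units.  At
country scale with per-100,000 weights the densities are ~10⁻⁶–10⁻⁵ km⁻²,
so the denominator is ≈ 1 and absolute HMR values are small; the informative
quantities are *relative*: spatial contrasts within a period and the change
between quinquennia (the fraction of raster cells whose HMR increased).
Fixed near-parity banding around 1 is provided (`classify_hmr`, tolerance
0.1) but is only meaningful when the surfaces are on a comparable unit scale
to the offset.  Rasters default to ~200 cells across with a 2-bandwidth
margin and are written as Esri ASCII grids.

## Synthetic data generator

The generator emulates the study conditions: a 20 × 22 square-cell lattice
(440 regions ≈ the 438 health regions) with 140 km cells (continental
scale), log-normal 40–79 populations (median 150,000, log-sd 0.7), baseline
rates per 100,000 of 24 (diagnosis), 20 (treatment), 38 (death) — inside the
observed national ranges — macro-regional multiplicative blocks producing
the high-South/low-North gradient, annual trends of ×1.035 (diagnosis) and
×1.03 (treatment) with a 2019 peak (×1.07) and 2020 dip (×0.90/0.88), flat
mortality, and a latent log-scale Gaussian field (kernel-smoothed white
noise, 400 km range, sd 0.25, mean-centred before rescaling) shared across
years.  Counts are Poisson with mean P·rate/10⁵.  Year shocks are
per-indicator because the pandemic-era dip affected service indicators, not
mortality rates.

Choices and what they imply: kernel-smoothed noise rather than a CAR/SAR
model (simpler, induces controllable Moran's I); Poisson rather than
negative binomial counts (the pipeline consumes rates, not count
likelihoods); constant within-region population; planar km coordinates
throughout (the KDE bandwidth scale presumes projected distance).  Planted
rectangular blocks (rate and/or trend factors) are recorded as ground truth
for recovery scoring.  The generator does **not** emulate irregular region
geometry, migration, cause-of-death misclassification, reporting delays or
overdispersion — passing recovery tests show the pipeline detects the
patterns it models, not that real registry artefacts are handled.

## Numerical conventions and degenerate inputs

Seeds: every stochastic routine takes an explicit seed; the generator
derives independent streams for geometry, field and counts from one seed.
Constant inputs: Moran/Gi* raise degenerate-variance errors; constant
Mann–Kendall series return p = 1 flagged.  s² and shrink weights are clipped
to [0, ∞) and [0, 1].  Pseudo p-values are bounded below by 1/(n_perm + 1).
Ripley tie-breaks go to the smaller distance; a boundary maximum warns.

## Problem sizes in the test suite

The statistical acceptance checks run at: full enumeration of the
Mann–Kendall null for n ≤ 7; 10,000 null series for the exact test's level;
200 simulated panels for block-trend power; 100 seeds × 999 permutations for
LISA recovery on the 440-region lattice; 100 seeds for emerging-hotspot
recovery and null calibration on a 100-region lattice; 500 panels for the
smoothing variance-reduction check; 30 torus point patterns of 1,000 points
for Ripley calibration.  The whole suite completes in a few minutes on one
core.
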
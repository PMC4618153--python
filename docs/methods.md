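# Methods

This note documents the models and procedures implemented in
`trackcloud`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that
make the results reproducible.

## Coordinate frame and gridding

All analyses run on a projected plane in km. For geographic input a
spherical Lambert azimuthal equal-area projection centered at 57° N,
190° E is provided (`trackcloud.projection`); longitudes are normalized
to [0, 360) before projection so the antimeridian never splits a track.
Equal-area cells are a requirement, not a convenience: occupancy counts,
densities, and the similarity index all compare areas.

Grids are square with a fixed origin at (0, 0) and half-open cells
`[left, right) × [bottom, top)`; a point exactly on a boundary belongs
to the cell on the right/top. The origin is pinned rather than
data-dependent so that results are reproducible and permutation tests
are origin-consistent by construction. A cell counts as occupied if
*any* replicate point falls in it (a `min_visits` threshold exists but
defaults to 1): the replicate cloud already encodes location
uncertainty, which is why no kernel density estimation is offered.
The 45-km cell is the default analysis scale (≈ one mean daily
displacement); the 5-km grid supported by `density_surface` is intended
for visualization only.

## Group similarity and its permutation null

The similarity index of two groups is the Jaccard ratio of their
group-level occupied-cell unions. Significance comes from randomly
reassigning *birds* (the exchangeable unit — never points) to groups of
the original sizes, default 10,000 times, and counting permuted indices
smaller than the observed one, i.e. a lower-tail test for "less sharing
than random".

Tie handling: the literal rule `#{perm < obs}/n` ("strict") returns
p = 0 whenever the observed index ties the entire null distribution —
anti-conservative in degenerate cases — so the default is the plus-one
rule `(1 + #{perm ≤ obs})/(n + 1)`, which is uniform under the null and
cannot return 0. Both are available. No multiple-testing correction is
applied across the three pairwise year comparisons; callers who need one
should apply it downstream.

Saturation curves average the cumulative union size over random bird
orderings; when n! is smaller than the requested iteration count the
orderings are enumerated exhaustively, making the mean exact. The curve
endpoint equals the full union in every iteration by construction.

## Site fidelity

Repeat birds (exactly two consecutive winters) are compared with
themselves via the same index, computed over all replicate locations,
monthly (Oct–Feb) and pooled, at grid scales {10, 25, 45, 50, 100, 200,
400} km — the series is configurable; results at 100 km and 400 km are
the conventional summary points. The null is random pairs of *different*
birds of the same sex and colony from consecutive years, sampled
uniformly without replacement from the constrained pair universe
(default 59 pairs). Self-pairings are excluded because they would
contaminate the null with the signal. Scale behavior is reported, not
assumed monotone: coarser grids usually raise the index but are not
guaranteed to.

## Ecoregion occupancy

Provinces are polygons in projected km (GeoJSON with a `region`
property; a synthetic eight-province rectangular partition ships for
testing — real province boundaries are user-supplied, not bundled).
Cells are assigned by their center point; centers exactly on a shared
boundary go to the lexicographically first region name, and enumerated
cells outside every polygon are labeled `outside` explicitly, which
makes the conservation checks exact: province cell counts tile the
domain, and the % of bird distribution sums to 100 across provinces
plus `outside`. Mean bird density is averaged over *occupied* cells
only (an empty province reports density 0 with zero occupied cells).
Monthly province shares are location-weighted over all replicate points
and sum to 100 per month × year.

## Residency time

Residency at location *i* of a daily best track is the windowed count

    residency(i) = #{ j : |t_j − t_i| ≤ W/2  and  d(p_j, p_i) ≤ r } days,

with radius r = 45 km (≈ one mean daily displacement) and time
constraint W = 30 days, which prevents return-trip re-crossings months
later from inflating the statistic. "One month" is taken as 30 days.
The centered window is symmetric, always includes the location itself
(residency ≥ 1 day), and is bounded by W + 1 days; at track endpoints
the window is necessarily truncated to the available days. This
windowed-count formulation is deliberately simple and exactly matches a
quadratic-time brute-force oracle; crossing-based first-passage variants
of residency time are a different statistic and are out of scope.
High-residency locations are those at or above each bird's
`high_quantile` (default 0.75) residency quantile, computed with linear
interpolation between order statistics and flagged inclusively (≥), so
ties are flagged rather than split.

## Habitat annotation and mixed models

Covariates (SST, depth, slope, SSH, EKE, distance to eddy, distance to
seamount, chl a, wind) are extracted at each best-track location by
nearest raster cell, matched by calendar month — except chl a, where
locations in the first week of a month borrow the previous month's
composite (satellite chlorophyll composites lag). Locations outside the
raster extent keep their rows with missing covariates; missing rows are
dropped listwise before fitting, deterministically.

The model is `log(residency) ~ covariates + (1 | bird)` per province,
with log-transformed chl a and square-root-transformed distance-to-eddy
and slope (the standard normalizing transforms for these right-skewed
quantities). Collinearity is screened with VIFs (flagged at ≥ 3, never
auto-dropped). Model selection is reductive: starting from the full
term set, the single term whose removal most lowers AIC is dropped,
repeating until no removal lowers AIC. Fitting uses REML by default;
because statsmodels does not define an AIC under REML, AIC is computed
from the fitted log-likelihood with k = #fixed effects + 2 variance
parameters. REML likelihoods are not strictly comparable across
fixed-effect sets, so an ML selection mode (`reml=False`) is provided;
the REML default mirrors conventional practice in this literature.
Variance explained is reported as marginal and conditional R²:

    R²m = var(Xβ) / (var(Xβ) + σ²_bird + σ²_res)
    R²c = (var(Xβ) + σ²_bird) / (var(Xβ) + σ²_bird + σ²_res).

Temporal autocorrelation: a continuous-time AR(1) residual on daily
data is equivalent to a discrete AR(1), which the optional `ar1=True`
mode approximates by a two-stage procedure — estimate the within-bird
lag-1 residual autocorrelation from an initial fit, pre-whiten response
and design within bird (only across consecutive days), and refit. This
is an approximation, off by default, and both the plain and whitened
AICs are reported when enabled.

Numerical notes: the profiled mixed-model likelihood can become
singular or spuriously infinite when the random-intercept variance hits
zero under L-BFGS; fits fall back to derivative-free optimizers
(Powell, Nelder–Mead) and a fit is declared singular only if all fail.
Standard errors and CIs are reported as missing when the Hessian is
singular at a boundary solution.

## Synthetic populations

The generator emulates the *structure* of a multi-year GLS study of a
colonial, dispersively migrating seabird, with defaults set to the
study-like conditions:

* **Season**: 151 daily positions from Oct 1 (the Oct–Feb core winter).
  GLS yields ~2 fixes/day; daily is the coarsest grain that supports
  the monthly and residency analyses, and is the assumed resolution
  throughout.
* **Movement**: a correlated random walk leaving the colony through a
  per-bird sequence of attraction centers at increasing colony
  distances (dispersive migration, capped at 2,500 km from the colony).
  Daily step lengths are truncated-normal with mean
  `mean_daily_distance` (default 34 km/day, mid-range of observed
  32–35 km/day) and CV 0.15.
* **Location uncertainty**: replicate tracks are the truth plus
  stationary AR(1) Gaussian noise (per-axis SD `error_sd` = 186 km,
  lag-1 correlation 0.7). Geolocation errors are serially correlated;
  i.i.d. jitter would understate cloud occupancy. The closed form
  E|error| = σ√(π/2) anchors the tests. Clouds default to 50
  replicates — statistics are defined per cloud, not per replicate
  count, so this is a cost knob, not a model change.
* **Structure**: two colonies 70 km apart, alternating sexes, multiple
  years; `n_returners` birds per consecutive-year pair are re-tracked
  and reuse the previous winter's attraction centers with probability
  `fidelity` (default 0.8); with fidelity 0 the two winters are
  independent draws.
* **Habitat**: smooth Gaussian random fields on a 100-km monthly grid
  (September included so the chl-a lag rule has data). SST and chl a
  share spatial structure with a standardized link field that
  multiplicatively slows movement (`habitat_link_coef`, default 0.15,
  mean-one normalized), so residency inherits a positive,
  known-sign association with SST/chl a for recovery tests. The link
  is kept weak because dwell-time weighting biases mean daily
  displacement low; at 0.15 the bias is a few percent, inside the
  generator's 10 % displacement contract.

Not emulated: light-level estimation itself, wind drift, wet/dry
activity, behavioral states, land masks, or real province shapes.
Passing tests therefore demonstrate the *statistical machinery* —
estimator correctness, null calibration, power, and parameter
recovery — under a realistic data structure, not ecological conclusions
about any real population.

## Problem sizes used in the checks

The verification suite uses desk-scale sizes chosen once: exhaustive
enumeration oracles at 3–6 birds; null calibration with 20 + 20 birds,
500 permutations, 200 replicates; power at 12 + 12 birds with colony
displacement 1,500 km, 100 replicates; fidelity recovery with 17
returners and 59 random pairs over 50 replicates (90-day seasons,
3-replicate clouds); mixed-model recovery with 40 birds × 50
observations over 50 replicates; and a full study-scale pipeline run
(3 winters × 38 birds × 50-replicate clouds, 151 days) with 1,000
permutations per comparison.
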
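# trackcloud

Uncertainty-aware spatial analysis of wintering-seabird geolocator tracks.

Light-level geolocation (GLS) tags recover the non-breeding movements of
small pelagic seabirds, but each position carries errors on the order of
100–200 km. Bayesian track models express that uncertainty as a *cloud*
of replicate plausible tracks per bird-winter. `trackcloud` is a library
(plus a thin CLI) for movement ecologists who want to take that
uncertainty seriously in population-level winter-distribution analyses:
rather than smoothing point estimates with a kernel, every statistic is
computed from the full replicate cloud on an equal-area grid.

## What it computes

With `A` and `B` the unions of 45-km grid cells occupied by any replicate
point of the birds in two groups (colonies, sexes, or years), the
**similarity index** is the Jaccard ratio

    S(A, B) = |A ∩ B| / |A ∪ B|,   S = 1 for identical groups,

tested against a null in which birds are randomly reassigned to groups of
the original sizes; the p-value is the share of permuted indices smaller
than the observed one (a "plus-one" tie rule is the default). Around this
core the package provides:

* **Gridding** — per-bird occupied-cell sets and density surfaces at any
  cell size, with month filters (Oct–Feb core winter by default).
* **Saturation curves** — expected cumulative occupied area as birds are
  added in random order (exact enumeration when feasible); shallower
  curves mean more shared space use.
* **Site fidelity** — similarity of each bird's two consecutive winters
  at grid scales from 10 to 400 km, against random same-sex, same-colony,
  consecutive-year pairs.
* **Ecoregion occupancy** — per biogeographic province: % of province
  occupied, mean bird density over occupied cells, % of the total bird
  distribution, per-bird province counts, monthly location shares.
* **Residency time** — windowed day counts within a 45-km radius under a
  30-day time constraint, with upper-quartile high-residency flags, and
  **habitat-selection mixed models**: log residency ~ habitat covariates
  with a random intercept per bird, reductive AIC selection, VIF
  screening, and marginal/conditional R².
* **Synthetic populations** — a correlated-random-walk generator with
  dispersive migration, serially correlated replicate noise, colony/sex/
  year structure, repeat-winter fidelity, province partitions, and
  habitat fields with a known residency link, so every stage is testable
  without tracking data. All analyses run on a Lambert azimuthal
  equal-area plane (km); a projection adapter handles lon/lat input
  across the antimeridian.

## Worked example

```python
import numpy as np
from trackcloud import (SimConfig, simulate_population, GridSpec,
                        occupied_cells, range_size, permutation_test)
from trackcloud.fidelity import repeat_fidelity, random_pair_null

cfg = SimConfig(n_birds_per_group=15, n_years=2, days=151, n_replicates=20,
                n_returners=10, seed=42)
pop = simulate_population(cfg)
grid = GridSpec(cell_size=45.0)
cellsets = [occupied_cells(c, grid, months=(10, 11, 12, 1, 2))
            for c in pop.clouds]
sizes = [range_size(cs) for cs in cellsets]
print(f"individual range size (45-km cells): "
      f"{np.mean(sizes):.0f} +/- {np.std(sizes):.0f}")

cmp = permutation_test(cellsets, [c.colony for c in pop.clouds],
                       n_iterations=2000, seed=1)
print(f"colony overlap: {100*cmp.observed_index:.0f} % (p = {cmp.p_value:.3f})")

rep = repeat_fidelity(pop.clouds, scales=(100.0,), months=("pooled",))
ran = random_pair_null(pop.clouds, n_pairs=30, scales=(100.0,),
                       months=("pooled",), seed=2)
print(f"repeat-trip overlap at 100 km: {100*rep['index'].mean():.0f} % "
      f"(random pairs: {100*ran['index'].mean():.0f} %)")
```

prints

```
individual range size (45-km cells): 1106 +/- 69
colony overlap: 71 % (p = 0.046)
repeat-trip overlap at 100 km: 66 % (random pairs: 13 %)
```

Each bird-winter occupies ~1,100 cells of 45 × 45 km. The two simulated
colonies (70 km apart) share 71 % of their occupied cells; the
permutation p of 0.046 says the observed sharing is slightly *below*
what random group assignment produces. Returner birds re-use last year's
areas far above the random-pair null (66 % vs 13 % at the 100-km scale) —
the simulated site-fidelity signal, recovered.

The same steps are available from a shell:

```sh
trackcloud simulate --seed 42 --out data/
trackcloud compare-groups --tracks data/tracks.csv --by colony \
    --iterations 10000 --seed 1 --out colony.json
trackcloud fidelity --tracks data/tracks.csv --seed 2 --out fidelity.csv
trackcloud pipeline --seed 1 --out report.json
```

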
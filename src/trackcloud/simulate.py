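"""Synthetic winter-migration track generator.

Emulates the data structure produced by light-level geolocation of a
colonial pelagic seabird over the October–February core wintering period:

* per bird-winter, a daily *best track* plus ``n_replicates`` replicate
  tracks that sample the location-uncertainty cloud (geolocation errors
  are on the order of 186 km and serially correlated, so replicate noise
  is an AR(1) random walk, not i.i.d. jitter);
* dispersive migration — a correlated random walk that leaves the colony
  and drifts through a per-bird sequence of attraction centers, with
  daily displacement averaging ``mean_daily_distance`` (~32–35 km/day)
  and maximum colony distance capped near 2,500 km;
* group structure: two colonies ~70 km apart, two sexes, multiple years;
* repeat-year site fidelity: a configurable number of birds are tracked
  in two consecutive winters and reuse the previous winter's attraction
  centers with probability ``fidelity``;
* a synthetic ecoregion partition and smooth random habitat fields, one
  of which modulates movement speed so that residency time carries a
  known habitat association for recovery tests.

Everything is deterministic for a fixed ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

__all__ = [
    "SimConfig",
    "TrackCloud",
    "Population",
    "simulate_population",
    "synthetic_habitat",
    "prior_mean_speed",
    "HABITAT_VARS",
]

SEASON_START = (10, 1)  # Oct 1; 151 days reaches Feb 28

#: habitat covariates carried by the synthetic raster set
HABITAT_VARS = ("sst", "depth", "slope", "ssh", "eke", "d2eddy", "d2hill", "chla", "wind")


def prior_mean_speed(flight_speed_kmh: float = 33.0, flight_fraction: float = 0.33) -> float:
    """Mean speed of the movement prior used by Bayesian geolocation models.

    A sustained flight speed is discounted by the fraction of each day the
    bird actually spends in flight, giving the effective mean speed entered
    into the track model's log-normal speed prior.  With the defaults
    (33 km/h sustained, 33 % of time flying) this is 10.89 km/h.
    """
    if flight_speed_kmh <= 0:
        raise ValueError("flight_speed_kmh must be > 0")
    if not 0 < flight_fraction <= 1:
        raise ValueError("flight_fraction must be in (0, 1]")
    return flight_speed_kmh * flight_fraction


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic tracked population.

    Defaults are the study-like conditions: 151-day season (Oct 1–Feb 28),
    ~34 km/day displacement, 186-km replicate noise, two colonies 70 km
    apart, and a handful of two-winter returners per consecutive-year pair.
    """

    n_birds_per_group: int = 10          # birds per colony per year (returners included)
    n_years: int = 1
    days: int = 151
    mean_daily_distance: float = 34.0    # km/day
    colony_xy: tuple[float, float] = (0.0, 0.0)
    colony_offset_km: float = 70.0       # separation of the second colony
    n_attraction_centers: int = 3
    fidelity: float = 0.8                # P(returner reuses last year's centers)
    error_sd: float = 186.0              # km, per-axis replicate-noise scale
    error_rho: float = 0.7               # lag-1 autocorrelation of replicate noise
    n_replicates: int = 50
    n_returners: int = 8                 # birds re-tracked in the following winter
    habitat_link_coef: float = 0.15      # speed reduction per SD of the link field
    step_cv: float = 0.15                # CV of daily step length
    max_colony_distance: float = 2500.0  # km
    start_year: int = 2008
    seed: int = 0

    def __post_init__(self):
        for name in ("n_birds_per_group", "n_years", "days", "n_attraction_centers",
                     "n_replicates"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"invalid SimConfig: {name} must be >= 1")
        if not 0.0 <= self.fidelity <= 1.0:
            raise ValueError("invalid SimConfig: fidelity must be in [0, 1]")
        if self.error_sd < 0:
            raise ValueError("invalid SimConfig: error_sd must be >= 0")
        if self.mean_daily_distance <= 0:
            raise ValueError("invalid SimConfig: mean_daily_distance must be > 0")
        if not -1.0 < self.error_rho < 1.0:
            raise ValueError("invalid SimConfig: error_rho must be in (-1, 1)")
        if self.n_returners < 0:
            raise ValueError("invalid SimConfig: n_returners must be >= 0")
        if self.n_returners > 2 * self.n_birds_per_group:
            raise ValueError("invalid SimConfig: n_returners exceeds birds per year")


@dataclass
class TrackCloud:
    """One bird-winter: a best track plus replicate uncertainty tracks.

    ``x`` and ``y`` have shape ``(n_replicates + 1, days)``; row 0 is the
    best track, rows 1..R the uncertainty-cloud members.  All replicates
    share the (gapless, daily) ``dates`` axis.
    """

    bird_id: str
    year: int
    colony: str
    sex: str
    dates: pd.DatetimeIndex
    x: np.ndarray
    y: np.ndarray
    centers: np.ndarray | None = None  # (n_centers, 2) attraction centers, generator metadata

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 2:
            raise ValueError("x and y must be 2-D arrays of identical shape")
        if self.x.shape[1] != len(self.dates):
            raise ValueError("second axis of x/y must match dates")
        if self.x.shape[0] < 1:
            raise ValueError("replicate 0 (the best track) is required")
        if len(self.dates) > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 1):
                raise ValueError(f"dates of bird {self.bird_id} are not a gapless daily sequence")

    @property
    def n_replicates(self) -> int:
        return self.x.shape[0] - 1

    @property
    def n_days(self) -> int:
        return self.x.shape[1]

    @property
    def best_x(self) -> np.ndarray:
        return self.x[0]

    @property
    def best_y(self) -> np.ndarray:
        return self.y[0]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view: one row per (date, replicate)."""
        n_rep, n_days = self.x.shape
        return pd.DataFrame({
            "bird_id": self.bird_id,
            "colony": self.colony,
            "sex": self.sex,
            "year": self.year,
            "date": np.tile(self.dates.values, n_rep),
            "replicate_id": np.repeat(np.arange(n_rep), n_days),
            "x_km": self.x.ravel(),
            "y_km": self.y.ravel(),
        })


@dataclass
class Population:
    """Bundle returned by :func:`simulate_population`."""

    clouds: list[TrackCloud]
    ecoregions: "object"        # trackcloud.ecoregions.EcoregionMap
    habitat: xr.Dataset
    config: SimConfig


def season_dates(start_year: int, year_offset: int, days: int) -> pd.DatetimeIndex:
    start = pd.Timestamp(start_year + year_offset, *SEASON_START)
    return pd.date_range(start, periods=days, freq="D")


# ---------------------------------------------------------------------------
# movement model

def _draw_centers(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Per-bird attraction centers, dispersive: increasing colony distance."""
    n = cfg.n_attraction_centers
    d_max = min(0.5 * cfg.days * cfg.mean_daily_distance, cfg.max_colony_distance)
    base = rng.uniform(0.0, 2.0 * np.pi)
    angles = base + rng.normal(0.0, 0.5, size=n)
    dists = d_max * (np.arange(1, n + 1) / n) * rng.uniform(0.75, 1.05, size=n)
    dists = np.maximum.accumulate(dists)
    return np.column_stack([dists * np.cos(angles), dists * np.sin(angles)])


class _LinkField:
    """Nearest-cell lookup into the standardized habitat link field."""

    def __init__(self, xs: np.ndarray, ys: np.ndarray, values: np.ndarray):
        self.xs, self.ys, self.values = xs, ys, values

    def __call__(self, x: float, y: float) -> float:
        i = int(np.clip(np.searchsorted(self.ys, y), 0, len(self.ys) - 1))
        j = int(np.clip(np.searchsorted(self.xs, x), 0, len(self.xs) - 1))
        return float(self.values[i, j])


def _simulate_best_track(rng: np.random.Generator, cfg: SimConfig,
                         colony: np.ndarray, centers: np.ndarray,
                         link: _LinkField | None) -> tuple[np.ndarray, np.ndarray]:
    """Correlated random walk from the colony through the attraction centers."""
    days = cfg.days
    xs = np.empty(days)
    ys = np.empty(days)
    pos = np.array(colony, dtype=float)
    xs[0], ys[0] = pos
    seg = max(1, days // len(centers))
    heading = None
    c = cfg.habitat_link_coef
    steps = rng.normal(cfg.mean_daily_distance, cfg.step_cv * cfg.mean_daily_distance,
                       size=days)
    steps = np.clip(steps, 1.0, None)
    turn_noise = rng.normal(0.0, 0.3, size=days)
    dwell_draws = rng.standard_normal(size=days)  # reserved stream, keeps layout stable
    _ = dwell_draws
    for t in range(1, days):
        target = centers[min((t - 1) // seg, len(centers) - 1)]
        rel = pos - colony
        if np.hypot(*rel) > cfg.max_colony_distance:
            target = colony  # soft reflection back toward the colony
        d = target - pos
        desired = np.arctan2(d[1], d[0])
        if heading is None:
            heading = desired
        else:
            # persistent heading: blend of previous heading and target direction
            vx = 0.6 * np.cos(heading) + 0.4 * np.cos(desired)
            vy = 0.6 * np.sin(heading) + 0.4 * np.sin(desired)
            heading = np.arctan2(vy, vx)
        heading = heading + turn_noise[t]
        step = steps[t]
        if link is not None and c > 0:
            # slow down in high-link-field habitat; normalized so the
            # population mean daily displacement stays ~mean_daily_distance
            z = link(pos[0], pos[1])
            step = step * np.exp(-c * z - 0.5 * c * c)
        pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
        xs[t], ys[t] = pos
    return xs, ys


def _replicate_noise(rng: np.random.Generator, n_rep: int, days: int,
                     sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise, shape (n_rep, days, 2), per-axis SD = sd."""
    z = rng.standard_normal((n_rep, days, 2))
    if sd == 0 or n_rep == 0:
        return np.zeros((n_rep, days, 2))
    e = np.empty_like(z)
    e[:, 0] = sd * z[:, 0]
    a = sd * np.sqrt(1.0 - rho * rho)
    for t in range(1, days):
        e[:, t] = rho * e[:, t - 1] + a * z[:, t]
    return e


# ---------------------------------------------------------------------------
# habitat rasters

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float = 3.0) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    return (f - f.mean()) / f.std()


def synthetic_habitat(rng: np.random.Generator, months: list[str],
                      extent: float = 2800.0, cell_km: float = 100.0,
                      link_field: np.ndarray | None = None) -> xr.Dataset:
    """Smooth random habitat fields on a (month, y, x) grid.

    ``months`` are "YYYY-MM" labels.  Static bathymetry-derived variables
    (depth, slope, d2hill) repeat across months; the others get monthly
    anomalies.  SST and chl a share spatial structure with ``link_field``
    (the field that slows simulated movement), so residency inherits a
    positive association with SST and chl a of known sign.
    """
    xs = np.arange(-extent + cell_km / 2, extent, cell_km)
    ys = np.arange(-extent + cell_km / 2, extent, cell_km)
    shape = (len(ys), len(xs))
    if link_field is None:
        link_field = _smooth_field(rng, shape)
    lat_grad = np.linspace(1.0, -1.0, len(ys))[:, None] * np.ones((1, len(xs)))  # +south

    statics = {
        "depth": np.clip(4000 + 1200 * _smooth_field(rng, shape), 50, None),
        "slope": np.abs(_smooth_field(rng, shape)) * 0.05,
        "d2hill": np.abs(_smooth_field(rng, shape)) * 400 + 20,
    }
    data = {v: np.empty((len(months),) + shape) for v in HABITAT_VARS}
    for m, _month in enumerate(months):
        season = np.cos(2 * np.pi * m / 12.0)  # mild seasonal cycle
        anom = {v: _smooth_field(rng, shape) for v in ("sst", "ssh", "eke", "d2eddy",
                                                       "chla", "wind")}
        data["sst"][m] = 6.0 + 3.0 * lat_grad - 1.5 * season + 2.0 * link_field + 1.0 * anom["sst"]
        data["ssh"][m] = -9.0 + 6.0 * anom["ssh"] + 2.0 * lat_grad
        data["eke"][m] = 60.0 * np.exp(0.5 * anom["eke"])
        data["d2eddy"][m] = np.abs(150.0 * (0.8 * anom["d2eddy"] + 0.6)) + 5.0
        data["chla"][m] = np.exp(np.log(0.8) + 0.6 * link_field + 0.5 * anom["chla"])
        data["wind"][m] = 9.0 + 1.2 * anom["wind"]
        for v, arr in statics.items():
            data[v][m] = arr
    ds = xr.Dataset(
        {v: (("month", "y", "x"), data[v]) for v in HABITAT_VARS},
        coords={"month": months, "y": ys, "x": xs},
        attrs={"cell_km": cell_km, "link_variable": "sst"},
    )
    return ds


def _season_months(start_year: int, n_years: int) -> list[str]:
    """Month labels covering Sep..Mar of every simulated winter.

    September is included because first-week locations borrow the previous
    month's chl-a composite.
    """
    labels = []
    for y in range(n_years):
        for mm in (9, 10, 11, 12):
            labels.append(f"{start_year + y:04d}-{mm:02d}")
        for mm in (1, 2, 3):
            labels.append(f"{start_year + y + 1:04d}-{mm:02d}")
    return sorted(set(labels))


# ---------------------------------------------------------------------------
# population assembly

def simulate_population(config: SimConfig) -> Population:
    """Simulate a multi-year tracked population plus ecoregions and habitat.

    Deterministic for a fixed ``config.seed``.  Returns a
    :class:`Population` whose ``clouds`` list holds one
    :class:`TrackCloud` per bird-winter.
    """
    from .ecoregions import synthetic_ecoregions  # local import to avoid cycle

    rng = np.random.default_rng(config.seed)
    months = _season_months(config.start_year, config.n_years)

    extent = 2800.0
    link_values = _smooth_field(rng, (56, 56))
    habitat = synthetic_habitat(rng, months, extent=extent, cell_km=100.0,
                                link_field=link_values)
    link = _LinkField(habitat.x.values, habitat.y.values,
                      link_values) if config.habitat_link_coef > 0 else None

    colonies = {
        "colony_A": np.asarray(config.colony_xy, dtype=float),
        "colony_B": np.asarray(config.colony_xy, dtype=float)
        + np.array([config.colony_offset_km, 0.0]),
    }

    clouds: list[TrackCloud] = []
    prev_roster: list[dict] = []
    counter = 0
    for yo in range(config.n_years):
        roster: list[dict] = []
        # returners carry over from last year's roster
        if yo > 0 and config.n_returners > 0 and prev_roster:
            k = min(config.n_returners, len(prev_roster))
            idx = rng.choice(len(prev_roster), size=k, replace=False)
            for i in sorted(idx):
                b = dict(prev_roster[i])
                if rng.random() < config.fidelity:
                    b["centers"] = prev_roster[i]["centers"]
                else:
                    b["centers"] = _draw_centers(rng, config) + colonies[b["colony"]]
                roster.append(b)
        # fill each colony to n_birds_per_group with new birds
        for colony in colonies:
            n_have = sum(1 for b in roster if b["colony"] == colony)
            for i in range(config.n_birds_per_group - n_have):
                counter += 1
                sex = "F" if counter % 2 else "M"
                b = {
                    "bird_id": f"{colony[-1]}{counter:03d}",
                    "colony": colony,
                    "sex": sex,
                    "centers": _draw_centers(rng, config) + colonies[colony],
                }
                roster.append(b)
        for b in roster:
            bx, by = _simulate_best_track(rng, config, colonies[b["colony"]],
                                          b["centers"], link)
            noise = _replicate_noise(rng, config.n_replicates, config.days,
                                     config.error_sd, config.error_rho)
            x = np.vstack([bx[None, :], bx[None, :] + noise[:, :, 0]])
            y = np.vstack([by[None, :], by[None, :] + noise[:, :, 1]])
            clouds.append(TrackCloud(
                bird_id=b["bird_id"],
                year=config.start_year + yo,
                colony=b["colony"],
                sex=b["sex"],
                dates=season_dates(config.start_year, yo, config.days),
                x=x, y=y,
                centers=np.array(b["centers"], dtype=float),
            ))
        prev_roster = roster

    ecoregions = synthetic_ecoregions(extent=extent)
    return Population(clouds=clouds, ecoregions=ecoregions, habitat=habitat,
                      config=config)


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain dict (e.g. parsed JSON), ignoring nulls."""
    names = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
    clean = {k: (tuple(v) if k == "colony_xy" else v) for k, v in d.items() if v is not None}
    return SimConfig(**clean)
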
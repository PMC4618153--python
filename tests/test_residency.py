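import numpy as np
import pandas as pd
import pytest

from trackcloud import (ResidencyConfig, annotate_habitat, residency_time,
                        transform_covariates)
from trackcloud.simulate import SimConfig, simulate_population, synthetic_habitat


def _track(xy, start="2008-11-01"):
    n = len(xy)
    return pd.DataFrame({
        "bird_id": "b1",
        "date": pd.date_range(start, periods=n, freq="D"),
        "x": [p[0] for p in xy],
        "y": [p[1] for p in xy],
    })


def brute_force_residency(track, cfg):
    """Independent O(n^2) oracle with explicit loops."""
    t = pd.DatetimeIndex(track["date"])
    days = [(ti - t[0]).days for ti in t]
    out = []
    for i in range(len(track)):
        count = 0
        for j in range(len(track)):
            dt = abs(days[j] - days[i])
            d = np.hypot(track.x.iloc[j] - track.x.iloc[i],
                         track.y.iloc[j] - track.y.iloc[i])
            if dt <= cfg.time_constraint_days / 2 and d <= cfg.radius_km:
                count += 1
        out.append(float(count))
    return np.array(out)


def test_stationary_track_windowed_residency():
    # 31-day stationary track: interior points see the full 31-day window,
    # endpoints only their own half (16 days) under the centered window
    prof = residency_time(_track([(0.0, 0.0)] * 31))
    r = prof["residency_days"].to_numpy()
    assert r[15] == 31.0
    assert r[0] == 16.0 and r[-1] == 16.0
    assert r.max() <= 30.0 + 1.0  # time constraint + sampling interval


def test_daily_100km_jumps_give_residency_one():
    xy = [(100.0 * k, 0.0) for k in range(40)]
    prof = residency_time(_track(xy))
    assert (prof["residency_days"] == 1.0).all()


def test_residency_matches_brute_force_oracle(rng):
    cfg = ResidencyConfig()
    for _ in range(5):
        steps = rng.normal(0, 30, size=(80, 2))
        xy = np.cumsum(steps, axis=0)
        track = _track([tuple(p) for p in xy])
        prof = residency_time(track, cfg)
        np.testing.assert_array_equal(prof["residency_days"].to_numpy(),
                                      brute_force_residency(track, cfg))


def test_time_reversal_symmetry(rng):
    xy = np.cumsum(rng.normal(0, 25, size=(60, 2)), axis=0)
    fwd = residency_time(_track([tuple(p) for p in xy]))
    rev = residency_time(_track([tuple(p) for p in xy[::-1]]))
    np.testing.assert_array_equal(fwd["residency_days"].to_numpy(),
                                  rev["residency_days"].to_numpy()[::-1])


def test_residency_bounds_and_quantile_flags(rng):
    xy = np.cumsum(rng.normal(0, 20, size=(100, 2)), axis=0)
    cfg = ResidencyConfig()
    prof = residency_time(_track([tuple(p) for p in xy]), cfg)
    r = prof["residency_days"]
    assert (r >= 1.0).all() and (r <= cfg.time_constraint_days + 1).all()
    thresh = np.quantile(r, cfg.high_quantile)
    assert prof["is_high_residency"].equals(r >= thresh)
    assert prof["is_high_residency"].sum() >= np.ceil(0.25 * len(r)) - (r == thresh).sum()


def test_short_track_rejected():
    with pytest.raises(ValueError, match="at least 2"):
        residency_time(_track([(0.0, 0.0)]))


def test_residency_config_validation():
    for kwargs in ({"radius_km": 0}, {"time_constraint_days": 0},
                   {"high_quantile": 1.0}):
        with pytest.raises(ValueError):
            ResidencyConfig(**kwargs)


# --- habitat annotation -----------------------------------------------------

@pytest.fixture(scope="module")
def habitat():
    rng = np.random.default_rng(77)
    months = ["2008-09", "2008-10", "2008-11", "2008-12"]
    return synthetic_habitat(rng, months, extent=600.0, cell_km=100.0)


def test_constant_raster_annotates_constant(habitat):
    h = habitat.copy()
    h["sst"] = h["sst"] * 0 + 4.25
    prof = residency_time(_track([(10.0 * k, 5.0 * k) for k in range(20)]))
    ann = annotate_habitat(prof, h)
    assert (ann["sst"] == 4.25).all()


def test_chla_first_week_uses_previous_month(habitat):
    # (10, 10) avoids equidistant cell-center ties in the nearest lookup
    track = _track([(10.0, 10.0)] * 25, start="2008-11-01")
    ann = annotate_habitat(residency_time(track), habitat)
    nov3 = ann[pd.DatetimeIndex(ann.date).day == 3].iloc[0]
    nov20 = ann[pd.DatetimeIndex(ann.date).day == 20].iloc[0]
    oct_val = float(habitat["chla"].sel(month="2008-10").sel(x=10, y=10, method="nearest"))
    nov_val = float(habitat["chla"].sel(month="2008-11").sel(x=10, y=10, method="nearest"))
    assert nov3["chla"] == pytest.approx(oct_val)
    assert nov20["chla"] == pytest.approx(nov_val)
    # non-chla variables use the calendar month even in the first week
    nov_sst = float(habitat["sst"].sel(month="2008-11").sel(x=10, y=10, method="nearest"))
    assert nov3["sst"] == pytest.approx(nov_sst)


def test_outside_extent_yields_missing_but_keeps_rows(habitat):
    xy = [(0.0, 0.0)] * 10 + [(5000.0, 5000.0)] * 10
    ann = annotate_habitat(residency_time(_track(xy)), habitat)
    assert len(ann) == 20
    assert ann["sst"].iloc[:10].notna().all()
    assert ann["sst"].iloc[10:].isna().all()


# --- covariate transforms ---------------------------------------------------

def _samples():
    return pd.DataFrame({
        "bird_id": ["b1"] * 3,
        "residency_days": [1.0, 2.0, 4.0],
        "sst": [5.0, 6.0, 7.0], "depth": [4000.0, 3500.0, 3000.0],
        "slope": [144.0, 0.0, 4.0], "ssh": [-9.0, -8.0, -7.0],
        "eke": [60.0, 50.0, 40.0], "d2eddy": [144.0, 100.0, 25.0],
        "d2hill": [400.0, 300.0, 200.0], "chla": [1.0, 2.0, 0.5],
        "wind": [9.0, 8.0, 7.0],
    })


def test_transforms_follow_field_conventions():
    design = transform_covariates(_samples())
    assert design["log_residency"].iloc[0] == 0.0      # log(1 day)
    assert design["log_chla"].iloc[0] == 0.0           # log(1)
    assert design["sqrt_d2eddy"].iloc[0] == 12.0       # sqrt(144)
    assert design["sqrt_slope"].iloc[0] == 12.0
    assert design["sst"].equals(_samples()["sst"])     # untransformed


def test_nonpositive_chla_error_names_row():
    bad = _samples()
    bad.loc[1, "chla"] = 0.0
    with pytest.raises(ValueError, match="row 1"):
        transform_covariates(bad)


def test_residency_link_raises_residency_in_high_sst_habitat():
    # the generator slows birds in high-link-field (warm, green) habitat,
    # so residency should correlate positively with SST along tracks
    cfg = SimConfig(n_birds_per_group=10, n_years=1, days=120, n_replicates=1,
                    n_returners=0, habitat_link_coef=0.4, seed=55)
    pop = simulate_population(cfg)
    prof = pd.concat([residency_time(c) for c in pop.clouds], ignore_index=True)
    ann = annotate_habitat(prof, pop.habitat)
    sub = ann.dropna(subset=["sst"])
    r = np.corrcoef(sub["residency_days"], sub["sst"])[0, 1]
    assert r > 0.05
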
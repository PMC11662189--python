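import math

import numpy as np
import pandas as pd
import pytest

from mobimood import features as ft
from mobimood.features import FeatureConfig, cluster_locations, daily_features, infer_home
from mobimood.preprocess import (CELLS_PER_DAY, CELL_SECONDS, MISSING, MOVING, PAUSE,
                                 DayTrajectory, mercator_distance)
from mobimood.synthetic import ScenarioConfig, generate_cohort
from mobimood.pipeline import process_gps
from mobimood.preprocess import PreprocessConfig

from conftest import deg_offset


def _pause_df(lats, lons, durations, t0=0.0):
    t = t0
    rows = []
    for la, lo, d in zip(lats, lons, durations):
        rows.append({"t_begin_s": t, "t_end_s": t + d, "duration_s": d,
                     "lat": la, "lon": lo})
        t += d + 600
    return pd.DataFrame(rows)


class TestClusterLocations:
    def test_one_tight_group_one_cluster(self):
        rng = np.random.default_rng(0)
        lats = 25.0 + rng.normal(0, deg_offset(30, 25.0), 20)
        lons = 121.5 + rng.normal(0, deg_offset(30, 25.0), 20)
        clusters = cluster_locations(_pause_df(lats, lons, np.full(20, 600.0)))
        assert len(clusters) == 1

    def test_two_groups_far_apart_two_clusters(self):
        lats = [25.0] * 5 + [25.0] * 5
        lons = [121.5] * 5 + [121.5 + deg_offset(5000, 25.0)] * 5
        clusters = cluster_locations(_pause_df(lats, lons, np.full(10, 600.0)))
        assert len(clusters) == 2

    def test_three_planted_sites_recovered(self):
        rng = np.random.default_rng(1)
        centers = [(25.00, 121.50), (25.00, 121.52), (25.02, 121.50)]  # ~2 km apart
        lats, lons = [], []
        for la, lo in centers:
            lats += list(la + rng.normal(0, deg_offset(30, 25.0), 15))
            lons += list(lo + rng.normal(0, deg_offset(30, 25.0), 15))
        clusters = cluster_locations(_pause_df(lats, lons, np.full(45, 900.0)),
                                     d_max_m=500.0)
        assert len(clusters) == 3
        for la, lo in centers:
            d = mercator_distance(clusters["lat"], clusters["lon"], la, lo)
            assert np.min(d) < 150.0

    def test_no_pauses_empty_with_warning(self):
        out = cluster_locations(pd.DataFrame())
        assert len(out) == 0


class TestInferHome:
    def test_cluster_with_night_pauses_wins(self):
        pauses = pd.concat([
            _pause_df([25.0], [121.5], [6 * 3600.0], t0=0.0),           # night
            _pause_df([25.0], [121.5 + deg_offset(5000, 25.0)],
                      [10 * 3600.0], t0=9 * 3600.0),                    # day, longer
        ], ignore_index=True)
        clusters = cluster_locations(pauses)
        home = infer_home(clusters, pauses)
        d = mercator_distance(clusters.loc[clusters.index[home], "lat"],
                              clusters.loc[clusters.index[home], "lon"], 25.0, 121.5)
        assert d < 100.0
        assert clusters["is_home"].sum() == 1

    def test_night_time_majority_wins(self):
        far = 121.5 + deg_offset(5000, 25.0)
        pauses = pd.concat([
            _pause_df([25.0], [121.5], [0.8 * 6 * 3600.0], t0=0.0),
            _pause_df([25.0], [far], [0.2 * 6 * 3600.0], t0=5 * 3600.0),
        ], ignore_index=True)
        clusters = cluster_locations(pauses)
        home = infer_home(clusters, pauses)
        d = mercator_distance(clusters.loc[clusters.index[home], "lat"],
                              clusters.loc[clusters.index[home], "lon"], 25.0, 121.5)
        assert d < 100.0

    def test_synthetic_routine_home_found_for_every_participant(self):
        cfg = ScenarioConfig(n_participants=20, n_days=6, master_seed=77)
        cohort = generate_cohort(cfg)
        from mobimood.preprocess import preprocess_participant
        hits = 0
        for i, (pid, fixes) in enumerate(sorted(cohort.gps.items())):
            days, _, _ = preprocess_participant(
                fixes, PreprocessConfig(n_sim=1), rng=np.random.default_rng(i))
            pauses = pd.concat([d.pauses for d in days], ignore_index=True)
            clusters = cluster_locations(pauses)
            home = infer_home(clusters, pauses)
            true_home = cohort.gps[pid][["latitude", "longitude"]].iloc[:5].median()
            d = mercator_distance(clusters.loc[clusters.index[home], "lat"],
                                  clusters.loc[clusters.index[home], "lon"],
                                  true_home["latitude"], true_home["longitude"])
            hits += d < 300.0
        assert hits == 20


def _uniform_day(lat=25.0, lon=121.5):
    glat = np.full(CELLS_PER_DAY, lat)
    glon = np.full(CELLS_PER_DAY, lon)
    states = np.full(CELLS_PER_DAY, PAUSE, dtype=np.uint8)
    return glat, glon, states


def _clusters_at(coords):
    return pd.DataFrame({"lat": [c[0] for c in coords], "lon": [c[1] for c in coords],
                         "total_pause_seconds": 1.0, "is_home": False})


class TestDailyFeatures:
    def test_whole_day_at_home_degenerate(self):
        glat, glon, states = _uniform_day()
        day = DayTrajectory(pd.Timestamp("2020-03-01"), glat, glon, states,
                            np.ones(CELLS_PER_DAY, bool))
        out = daily_features(day, _clusters_at([(25.0, 121.5)]), home=0)
        assert out["homestay"] == 1.0
        assert out["transition_time"] == 0.0
        assert out["total_distance"] == pytest.approx(0.0, abs=1e-9)
        assert out["normalized_entropy"] == 0.0
        assert out["n_clusters"] == 1.0

    def test_equal_split_two_clusters_unit_entropy(self):
        glat, glon, states = _uniform_day()
        far = 121.5 + deg_offset(2000, 25.0)
        glon[CELLS_PER_DAY // 2:] = far
        day = DayTrajectory(pd.Timestamp("2020-03-01"), glat, glon, states,
                            np.ones(CELLS_PER_DAY, bool))
        out = daily_features(day, _clusters_at([(25.0, 121.5), (25.0, far)]), home=0)
        assert out["normalized_entropy"] == pytest.approx(1.0)
        assert out["homestay"] == pytest.approx(0.5)

    def test_75_25_split_entropy_closed_form(self):
        glat, glon, states = _uniform_day()
        far = 121.5 + deg_offset(2000, 25.0)
        q = int(CELLS_PER_DAY * 0.75)
        glon[q:] = far
        day = DayTrajectory(pd.Timestamp("2020-03-01"), glat, glon, states,
                            np.ones(CELLS_PER_DAY, bool))
        out = daily_features(day, _clusters_at([(25.0, 121.5), (25.0, far)]), home=0)
        # closed form: -(0.75 ln 0.75 + 0.25 ln 0.25) and its / ln 2
        assert out["normalized_entropy"] == pytest.approx(0.8112781244591328, abs=1e-9)
        ent = out["normalized_entropy"] * math.log(2)
        assert ent == pytest.approx(0.5623351446188083, abs=1e-9)

    def test_entropy_bounds_random_allocations(self):
        rng = np.random.default_rng(3)
        coords = [(25.0, 121.5 + deg_offset(1500 * k, 25.0)) for k in range(4)]
        for _ in range(20):
            glat, glon, states = _uniform_day()
            labels = rng.integers(0, 4, CELLS_PER_DAY)
            glon[:] = [coords[k][1] for k in labels]
            day = DayTrajectory(pd.Timestamp("2020-03-01"), glat, glon, states,
                                np.ones(CELLS_PER_DAY, bool))
            out = daily_features(day, _clusters_at(coords), home=0)
            assert 0.0 <= out["normalized_entropy"] <= 1.0 + 1e-12

    def test_longitude_translation_invariance(self):
        glat, glon, states = _uniform_day()
        glon[1000:2000] += deg_offset(800, 25.0)
        states[999:2001] = MOVING
        day = DayTrajectory(pd.Timestamp("2020-03-01"), glat, glon, states,
                            np.ones(CELLS_PER_DAY, bool))
        coords = [(25.0, 121.5)]
        base = daily_features(day, _clusters_at(coords), home=0)
        shift = 0.7
        day2 = DayTrajectory(day.date, glat, glon + shift, states,
                             np.ones(CELLS_PER_DAY, bool))
        moved = daily_features(day2, _clusters_at([(25.0, 121.5 + shift)]), home=0)
        for k in ft.FEATURE_NAMES:
            assert moved[k] == pytest.approx(base[k], rel=1e-9, abs=1e-12), k

    def test_total_distance_shrinks_under_subsampling(self):
        rng = np.random.default_rng(8)
        glat = 25.0 + np.cumsum(rng.normal(0, 1e-5, CELLS_PER_DAY))
        glon = 121.5 + np.cumsum(rng.normal(0, 1e-5, CELLS_PER_DAY))
        states = np.full(CELLS_PER_DAY, MOVING, dtype=np.uint8)
        obs = np.ones(CELLS_PER_DAY, bool)
        day = DayTrajectory(pd.Timestamp("2020-03-01"), glat, glon, states, obs)
        full = daily_features(day, _clusters_at([(25.0, 121.5)]), home=0)
        sub_obs = obs.copy()
        sub_obs[rng.random(CELLS_PER_DAY) < 0.5] = False
        states_sub = np.where(sub_obs, MOVING, MISSING).astype(np.uint8)
        day_sub = DayTrajectory(day.date, glat, glon, states_sub, sub_obs)
        sub = daily_features(day_sub, _clusters_at([(25.0, 121.5)]), home=0)
        assert sub["total_distance"] <= full["total_distance"] * (1 + 1e-9)


def _features_cell_oracle(lat, lon, states, clat, clon, home):
    """Brute-force cell-by-cell re-derivation of the eight features."""
    mask = states != MISSING
    idx = np.flatnonzero(mask)
    la, lo = lat[idx], lon[idx]
    out = {}
    out["location_variance"] = math.log(max(la.var() + lo.var(), 1e-12))
    x = np.radians(lo)
    y = np.log(np.tan(np.pi / 4 + np.radians(la) / 2))
    scale = 6_378_137.0 * math.cos(math.radians(la.mean()))
    seg = scale * np.hypot(np.diff(x), np.diff(y))
    adj = np.diff(idx) == 1
    out["total_distance"] = float(seg[adj].sum())
    sp = seg[adj & (states[idx[:-1]] == MOVING)] / CELL_SECONDS
    out["speed_mean"] = float(sp.mean()) if len(sp) else 0.0
    out["speed_variance"] = float(sp.var()) if len(sp) else 0.0
    out["transition_time"] = float((states == MOVING).sum() / mask.sum())
    pm = states == PAUSE
    ref = math.radians(clat.mean())
    d2 = ((lat[pm][None, :] - clat[:, None]) ** 2
          + ((lon[pm][None, :] - clon[:, None]) * math.cos(ref)) ** 2)
    labels = np.argmin(d2, axis=0)
    ptime = CELL_SECONDS * np.bincount(labels, minlength=len(clat)).astype(float)
    p = ptime[ptime > 0] / ptime.sum()
    k = int((ptime > 0).sum())
    ent = float(-(p * np.log(p)).sum())
    out["n_clusters"] = float(k)
    out["normalized_entropy"] = ent / math.log(k) if k > 1 else 0.0
    out["homestay"] = float(ptime[home] / (mask.sum() * CELL_SECONDS))
    return out


def test_run_compressed_features_match_cell_oracle(tiny_cohort):
    """The weighted run-length path equals a naive cell-level recomputation."""
    from mobimood.preprocess import preprocess_participant
    from mobimood.features import _features_single
    fixes = next(iter(tiny_cohort.gps.values()))
    days, imputed, _ = preprocess_participant(
        fixes, PreprocessConfig(n_sim=1), rng=np.random.default_rng(0))
    pauses = pd.concat([d.pauses for d in days], ignore_index=True)
    clusters = cluster_locations(pauses)
    home = infer_home(clusters, pauses)
    clat = clusters["lat"].to_numpy()
    clon = clusters["lon"].to_numpy()
    cfg = FeatureConfig()
    n_checked = 0
    for imp in imputed[:4]:
        got = _features_single(imp.lat[0], imp.lon[0], imp.states[0], clat, clon,
                               home, cfg)
        want = _features_cell_oracle(imp.lat[0], imp.lon[0], imp.states[0],
                                     clat, clon, home)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k
        n_checked += 1
    assert n_checked == 4
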
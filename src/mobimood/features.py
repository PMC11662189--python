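"""Daily mobility features from imputed 10-second trajectories.

Eight features per participant-day, following the convention of the
smartphone-sensing literature: location variance (log of summed coordinate
variances), speed mean and variance over moving cells, total distance,
transition time (fraction of the day moving), number of clusters visited,
normalized entropy of pause time across clusters, and homestay (fraction of
time paused at the inferred home).

Location clusters are discovered once per participant over the whole study
so that homestay and entropy are comparable across days; home is the cluster
holding the most night-time (00:00-06:00) pause time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .preprocess import (CELL_SECONDS, MISSING, MOVING, PAUSE,
                         EARTH_RADIUS_M, DayTrajectory, ImputedDay,
                         mercator_distance)

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "location_variance", "speed_mean", "speed_variance", "total_distance",
    "transition_time", "n_clusters", "normalized_entropy", "homestay",
)


@dataclass(frozen=True)
class FeatureConfig:
    d_max_m: float = 500.0            # max pause-to-centroid distance within a cluster
    night_start_s: float = 0.0        # home-inference window, seconds from local midnight
    night_end_s: float = 6 * 3600.0
    loc_var_floor: float = 1e-12      # degrees^2; keeps log finite for a motionless day
    loc_var_all_points: bool = True   # False: variance over pause cells only


def _to_plane(lat: np.ndarray, lon: np.ndarray, ref_lat: float) -> np.ndarray:
    """Equirectangular projection to local meters for clustering geometry."""
    x = EARTH_RADIUS_M * np.cos(np.radians(ref_lat)) * np.radians(lon)
    y = EARTH_RADIUS_M * np.radians(lat)
    return np.column_stack([x, y])


def cluster_locations(pauses: pd.DataFrame, d_max_m: float = 500.0) -> pd.DataFrame:
    """Centroid clustering of pause events, growing k until radii fit.

    k-means (weighted by pause duration) is rerun with increasing k until
    every pause event lies within ``d_max_m`` of its centroid.  Returns a
    frame with ``lat``, ``lon``, ``total_pause_seconds``, ``is_home``
    (all False until :func:`infer_home` runs).
    """
    cols = ["lat", "lon", "total_pause_seconds", "is_home"]
    if pauses is None or not len(pauses):
        logger.warning("no pause events: returning empty cluster set")
        return pd.DataFrame(columns=cols)
    ref_lat = float(pauses["lat"].mean())
    pts = _to_plane(pauses["lat"].to_numpy(), pauses["lon"].to_numpy(), ref_lat)
    w = pauses["duration_s"].to_numpy(dtype=float)
    n = len(pts)
    for k in range(1, n + 1):
        km = KMeans(n_clusters=k, n_init=4, random_state=0)
        labels = km.fit_predict(pts, sample_weight=w)
        dist = np.linalg.norm(pts - km.cluster_centers_[labels], axis=1)
        if dist.max() <= d_max_m or k == n:
            break
    centers = km.cluster_centers_
    lat_c = np.degrees(centers[:, 1] / EARTH_RADIUS_M)
    lon_c = np.degrees(centers[:, 0] / (EARTH_RADIUS_M * np.cos(np.radians(ref_lat))))
    total = np.bincount(labels, weights=w, minlength=k)
    out = pd.DataFrame({"lat": lat_c, "lon": lon_c, "total_pause_seconds": total,
                        "is_home": False})
    return out


def _assign(lat: np.ndarray, lon: np.ndarray,
            clat: np.ndarray, clon: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels via a local equirectangular metric."""
    ref = math.radians(float(clat.mean()))
    cosr = math.cos(ref)
    dy = lat[None, :] - clat[:, None]
    dx = (lon[None, :] - clon[:, None]) * cosr
    return np.argmin(dx * dx + dy * dy, axis=0)


def assign_clusters(lat: np.ndarray, lon: np.ndarray, clusters: pd.DataFrame) -> np.ndarray:
    """Index of the nearest cluster centroid for each point."""
    if not len(clusters):
        return np.full(np.shape(lat), -1, dtype=int)
    return _assign(np.atleast_1d(np.asarray(lat, dtype=float)),
                   np.atleast_1d(np.asarray(lon, dtype=float)),
                   clusters["lat"].to_numpy(), clusters["lon"].to_numpy())


def infer_home(clusters: pd.DataFrame, pauses: pd.DataFrame,
               cfg: FeatureConfig | None = None) -> int:
    """Flag the home cluster: most pause time in the night window over the study.

    Ties, and the no-nocturnal-pause fallback, resolve to the cluster with the
    largest all-day pause time.  Returns the home cluster's index and sets
    ``is_home`` in place.
    """
    cfg = cfg or FeatureConfig()
    if not len(clusters):
        raise ValueError("cannot infer home from an empty cluster set")
    labels = assign_clusters(pauses["lat"].to_numpy(), pauses["lon"].to_numpy(), clusters)
    night = (np.minimum(pauses["t_end_s"].to_numpy(), cfg.night_end_s)
             - np.maximum(pauses["t_begin_s"].to_numpy(), cfg.night_start_s)).clip(min=0)
    night_time = np.bincount(labels, weights=night, minlength=len(clusters))
    if night_time.max() <= 0:
        logger.info("no nocturnal pauses; falling back to largest all-day cluster")
        scores = clusters["total_pause_seconds"].to_numpy()
    else:
        # tie-break on all-day pause time via a tiny lexicographic bonus
        allday = clusters["total_pause_seconds"].to_numpy()
        scores = night_time + 1e-9 * allday / max(allday.max(), 1.0)
    home = int(np.argmax(scores))
    clusters["is_home"] = False
    clusters.loc[clusters.index[home], "is_home"] = True
    return home


def _features_single(lat: np.ndarray, lon: np.ndarray, states: np.ndarray,
                     clat: np.ndarray, clon: np.ndarray, home: int,
                     cfg: FeatureConfig) -> dict:
    """The eight features for one realization (or one observed-only day).

    Internally the trajectory is run-length compressed (pauses are long
    constant stretches), with run lengths as weights; every statistic equals
    its cell-by-cell counterpart exactly, since within-run displacements are
    zero by construction.
    """
    mask = states != MISSING
    n_def = int(mask.sum())
    out = dict.fromkeys(FEATURE_NAMES, np.nan)
    if n_def == 0:
        return out
    idx = np.flatnonzero(mask)
    la, lo, st = lat[idx], lon[idx], states[idx]
    # runs break on any change of position/state and across grid gaps, so
    # run adjacency mirrors cell adjacency
    new = np.empty(len(idx), dtype=bool)
    new[0] = True
    new[1:] = ((la[1:] != la[:-1]) | (lo[1:] != lo[:-1])
               | (st[1:] != st[:-1]) | (np.diff(idx) != 1))
    r = np.flatnonzero(new)
    w = np.diff(np.append(r, len(idx))).astype(float)
    rla, rlo, rst = la[r], lo[r], st[r]
    start, end = idx[r], idx[r] + w.astype(np.int64) - 1
    wsum = w.sum()
    mla = (rla * w).sum() / wsum
    mlo = (rlo * w).sum() / wsum
    if cfg.loc_var_all_points:
        v = ((w * (rla - mla) ** 2).sum() + (w * (rlo - mlo) ** 2).sum()) / wsum
    else:
        pm0 = rst == PAUSE
        if pm0.any():
            pw = w[pm0]
            ps = pw.sum()
            pla = (rla[pm0] * pw).sum() / ps
            plo = (rlo[pm0] * pw).sum() / ps
            v = ((pw * (rla[pm0] - pla) ** 2).sum()
                 + (pw * (rlo[pm0] - plo) ** 2).sum()) / ps
        else:
            v = 0.0
    out["location_variance"] = float(np.log(max(v, cfg.loc_var_floor)))
    mov = rst == MOVING
    if len(r) > 1:
        # Mercator plane projected once; cos of the day's mean latitude
        # undoes the projection stretch (all points lie within a few km)
        x = np.radians(rlo)
        y = np.log(np.tan(np.pi / 4 + np.radians(rla) / 2))
        scale = EARTH_RADIUS_M * math.cos(math.radians(float(mla)))
        seg = scale * np.hypot(np.diff(x), np.diff(y))
        adj = start[1:] == end[:-1] + 1
        # only 10-s adjacent displacements count: a day with unfilled gaps
        # does not bridge them (that is the imputation's job)
        out["total_distance"] = float(seg[adj].sum())
        sp = seg[adj & mov[:-1]] / CELL_SECONDS
        # within-run steps of a moving run have zero displacement, hence
        # contribute zero speeds
        n_zero = float((w[mov] - 1).sum()) if mov.any() else 0.0
        n_sp = len(sp) + n_zero
        if n_sp:
            m_sp = sp.sum() / n_sp
            out["speed_mean"] = float(m_sp)
            out["speed_variance"] = float((sp * sp).sum() / n_sp - m_sp * m_sp)
        else:
            out["speed_mean"] = 0.0
            out["speed_variance"] = 0.0
    else:
        out["total_distance"] = 0.0
        out["speed_mean"] = 0.0
        out["speed_variance"] = 0.0
    out["transition_time"] = float(w[mov].sum() / n_def)
    pm = rst == PAUSE
    if pm.any() and len(clat):
        labels = _assign(rla[pm], rlo[pm], clat, clon)
        ptime = CELL_SECONDS * np.bincount(labels, weights=w[pm], minlength=len(clat))
        visited = ptime > 0
        out["n_clusters"] = float(visited.sum())
        p = ptime[visited] / ptime.sum()
        ent = float(-(p * np.log(p)).sum())
        k = int(visited.sum())
        out["normalized_entropy"] = float(ent / np.log(k)) if k > 1 else 0.0
        out["homestay"] = float(ptime[home] / (n_def * CELL_SECONDS)) if home >= 0 else np.nan
    else:
        out["n_clusters"] = 0.0
        out["normalized_entropy"] = 0.0
        out["homestay"] = 0.0
    return out


def daily_features(day: ImputedDay | DayTrajectory, clusters: pd.DataFrame,
                   home: int, cfg: FeatureConfig | None = None) -> dict:
    """Feature dict for one day, averaged over imputation realizations.

    Accepts an :class:`ImputedDay` (average over its realizations) or a bare
    :class:`DayTrajectory` (observed cells only — used for comparison and for
    days that could not be imputed but clear the coverage floor).
    """
    cfg = cfg or FeatureConfig()
    clat = clusters["lat"].to_numpy() if len(clusters) else np.empty(0)
    clon = clusters["lon"].to_numpy() if len(clusters) else np.empty(0)
    if isinstance(day, ImputedDay):
        rows = [
            _features_single(day.lat[r], day.lon[r], day.states[r], clat, clon, home, cfg)
            for r in range(day.lat.shape[0])
        ]
        out = {k: float(np.nanmean([r[k] for r in rows])) for k in FEATURE_NAMES}
        out["coverage"] = day.coverage
    else:
        out = _features_single(day.lat, day.lon, day.states, clat, clon, home, cfg)
        out["coverage"] = day.coverage
    out["date"] = day.date
    return out
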
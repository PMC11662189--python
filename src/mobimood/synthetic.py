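"""Synthetic smartphone digital-phenotyping cohort.

Generates a study the pipeline can consume unchanged: duty-cycled GPS
traces over a home + multi-site daily routine, twice-daily ordinal mood
series with planted bidirectional mood-mobility coupling, participant
metadata, and a ground-truth file (true daily features, latent moods) for
recovery tests.

The generative model, per participant:

* a home and ``k_locations - 1`` other sites near a reference point
  (default Taipei, 25.04 N 121.56 E — a latitude where an uncorrected
  Mercator distance would be ~10% wrong, so distance bugs surface);
* each day, a semi-Markov pause/flight schedule: night at home, daytime
  excursions to sites (walking 1.4 m/s, vehicle 8 m/s), pause durations
  log-normal; the day's homestay target and far-site bias are modulated by
  the previous day's change in latent mood (mood -> mobility coupling);
* latent moods follow an AR(1) driven by the day's change in TRUE location
  variance and homestay (mobility -> mood coupling), then threshold to the
  ordinal 1-5 scale; couplings apply to the patient groups only, mirroring
  a cohort where controls' mobility is mood-independent;
* the observation layer samples the continuous path on a
  1-minute-on / 10-minutes-off duty cycle at a configurable burst rate,
  adds Gaussian position noise, and draws accuracy values from a log-normal
  whose upper tail exceeds the 51 m cleaning threshold.

Everything is reproducible from ``master_seed`` (per-participant substreams).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gps_io import EMA_ITEMS, write_gps
from .preprocess import CELL_SECONDS, CELLS_PER_DAY, MOVING, PAUSE, EARTH_RADIUS_M
from .features import FeatureConfig, _features_single

DEG = math.pi / 180.0


@dataclass(frozen=True)
class Coupling:
    """Planted coupling coefficients (signs follow the studied pathways).

    Feature -> mood terms act on the latent mood scale per unit change of the
    true feature; mood -> feature terms shift the next day's homestay target
    (per latent mood unit) or far-site bias (per latent mood unit per km).
    """

    b_lv_dep: float = -0.25    # change in location variance -> depressed
    b_hs_dep: float = 2.0      # change in homestay -> depressed
    b_hs_fat: float = 2.0      # change in homestay -> fatigue
    b_hs_irr: float = 1.5      # change in homestay -> irritability
    b_dep_lv: float = -0.40    # change in depressed -> next-day far-site bias
    b_fat_lv: float = -0.25    # change in fatigue -> next-day far-site bias
    b_dep_hs: float = 0.04     # change in depressed -> next-day homestay
    b_fat_hs: float = 0.04     # change in fatigue -> next-day homestay
    b_irr_hs: float = 0.03     # change in irritability -> next-day homestay

    @classmethod
    def null(cls) -> "Coupling":
        return cls(**{f.name: 0.0 for f in dataclasses.fields(cls)})


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-scale defaults: 38 participants followed 180 days near Taipei."""

    n_participants: int = 38
    n_days: int = 180
    start_date: str = "2020-03-01"
    group_sizes: tuple[int, int, int] = (10, 11, 17)   # HC, BP, MDD
    ref_lat: float = 25.04
    ref_lon: float = 121.56
    k_locations: int = 4
    on_seconds: int = 60
    off_seconds: int = 600
    fixes_per_burst: int = 8          # ~1,050 fixes/day at the default cycle
    gps_bias_sd_m: float = 8.0        # slowly varying positional bias, per burst
    gps_jitter_sd_m: float = 1.5      # fix-to-fix jitter on top of the bias
    accuracy_log_mu: float = 2.7318   # ~95% of accuracies < 47.6 m, ~4% >= 51 m
    accuracy_log_sigma: float = 0.6875
    coupling: Coupling = field(default_factory=Coupling)
    couple_controls: bool = False     # HC mobility stays mood-independent
    mood_ar: float = 0.5
    mood_noise_sd: float = 0.8
    prompt_noise_sd: float = 0.3      # latent noise between the two daily prompts
    mood_thresholds: tuple[float, ...] = (-0.4, 0.6, 1.6, 2.6)
    ema_missing_rate: float = 0.065
    second_prompt_rate: float = 0.95
    utc_offset_hours: int = 8
    master_seed: int = 0

    def __post_init__(self):
        if not all(a < b for a, b in zip(self.mood_thresholds, self.mood_thresholds[1:])):
            raise ValueError("mood thresholds must be strictly increasing")
        if not 0 < self.on_seconds + self.off_seconds <= 86_400:
            raise ValueError("duty cycle period must be positive and fit in a day")
        if not 0 <= self.ema_missing_rate <= 1:
            raise ValueError("ema_missing_rate must lie in [0, 1]")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=list)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        """Load a scenario from a YAML or JSON file of ScenarioConfig fields."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "coupling" in raw and isinstance(raw["coupling"], dict):
            raw["coupling"] = Coupling(**raw["coupling"])
        for key in ("group_sizes", "mood_thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticCohort:
    """In-memory synthetic study; :func:`generate_cohort` can also write it."""

    config: ScenarioConfig
    participants: pd.DataFrame          # participant, age, sex, group
    gps: dict                           # participant -> fixes frame (t_utc, lat, lon, alt, acc)
    ema: pd.DataFrame                   # long EMA table, both prompts
    truth: pd.DataFrame                 # per participant-day true features + latent moods
    followup: pd.DataFrame              # participant, date calendar


# ---------------------------------------------------------------------------
# geometry helpers

def _offset_deg(ref_lat: float, d_m: float, bearing: float) -> tuple[float, float]:
    """Displace by ``d_m`` meters along ``bearing`` (radians) in degrees."""
    dlat = d_m * math.cos(bearing) / EARTH_RADIUS_M / DEG
    dlon = d_m * math.sin(bearing) / (EARTH_RADIUS_M * math.cos(ref_lat * DEG)) / DEG
    return dlat, dlon


def _site_distance_km(sites: np.ndarray, ref_lat: float) -> np.ndarray:
    """Distance of each site from the first (home), in km."""
    dy = (sites[:, 0] - sites[0, 0]) * DEG * EARTH_RADIUS_M
    dx = (sites[:, 1] - sites[0, 1]) * DEG * EARTH_RADIUS_M * math.cos(ref_lat * DEG)
    return np.hypot(dx, dy) / 1000.0


# ---------------------------------------------------------------------------
# day-level simulation

def simulate_day_schedule(sites: np.ndarray, site_km: np.ndarray, h_target: float,
                          far_bias: float, rng: np.random.Generator) -> np.ndarray:
    """One day's continuous path as pause/flight segments.

    Returns an array of rows ``(t0, t1, lat0, lon0, lat1, lon1, state)`` that
    tile ``[0, 86400)``.  The schedule alternates home bouts and excursions;
    away time targets ``(1 - h_target)`` of the day; site choice is biased
    toward distant sites by ``exp(far_bias * km)``.
    """
    h_target = float(np.clip(h_target, 0.02, 1.0))
    wake = float(np.clip(rng.normal(8 * 3600, 1800), 6 * 3600, 10 * 3600))
    day_end = float(np.clip(rng.normal(22 * 3600, 1800), 20 * 3600, 23.5 * 3600))
    away_budget = (1 - h_target) * 86_400.0
    home = sites[0]
    segs: list[tuple] = [(0.0, wake, *home, *home, PAUSE)]
    t = wake
    away_used = 0.0
    n_away = len(sites) - 1
    while t < day_end - 900 and away_used < away_budget and n_away > 0:
        w = np.exp(far_bias * site_km[1:])
        s = 1 + rng.choice(n_away, p=w / w.sum())
        d_m = site_km[s] * 1000.0
        speed = 1.4 if d_m < 1200 else 8.0
        t_fly = max(d_m / speed, 10.0)
        stay = float(np.clip(rng.lognormal(math.log(5400), 0.6), 600, 6 * 3600))
        stay = min(stay, max(away_budget - away_used, 600.0))
        if t + 2 * t_fly + stay > 86_400 - 600:
            break
        segs.append((t, t + t_fly, *home, *sites[s], MOVING))
        t += t_fly
        segs.append((t, t + stay, *sites[s], *sites[s], PAUSE))
        t += stay
        segs.append((t, t + t_fly, *sites[s], *home, MOVING))
        t += t_fly
        away_used += 2 * t_fly + stay
        if away_used < away_budget and t < day_end - 900:
            home_bout = float(np.clip(rng.lognormal(math.log(3600), 0.6), 300, 4 * 3600))
            home_bout = min(home_bout, day_end - t)
            if home_bout > 0:
                segs.append((t, t + home_bout, *home, *home, PAUSE))
                t += home_bout
    segs.append((t, 86_400.0, *home, *home, PAUSE))
    return np.asarray(segs, dtype=float)


def _eval_path(segs: np.ndarray, times: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Position and state of the continuous path at arbitrary day-seconds."""
    t0, t1 = segs[:, 0], segs[:, 1]
    idx = np.clip(np.searchsorted(t0, times, side="right") - 1, 0, len(segs) - 1)
    dur = np.maximum(t1[idx] - t0[idx], 1e-9)
    f = np.clip((times - t0[idx]) / dur, 0.0, 1.0)
    lat = segs[idx, 2] + f * (segs[idx, 4] - segs[idx, 2])
    lon = segs[idx, 3] + f * (segs[idx, 5] - segs[idx, 3])
    return lat, lon, segs[idx, 6].astype(np.uint8)


def true_daily_features(segs: np.ndarray, site_lat: np.ndarray, site_lon: np.ndarray,
                        fcfg: FeatureConfig) -> dict:
    """The eight features computed on the noise-free path at 10-s resolution.

    The true sites serve as the location clusters, with home at index 0.
    """
    times = (np.arange(CELLS_PER_DAY) + 0.5) * CELL_SECONDS
    lat, lon, states = _eval_path(segs, times)
    return _features_single(lat, lon, states, site_lat, site_lon, 0, fcfg)


def _observe(segs: np.ndarray, cfg: ScenarioConfig, rng: np.random.Generator
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Duty-cycled noisy sampling: (day-seconds, lat, lon, accuracy) arrays."""
    period = cfg.on_seconds + cfg.off_seconds
    starts = np.arange(0, 86_400, period, dtype=float)
    offsets = np.arange(cfg.fixes_per_burst) * (cfg.on_seconds / cfg.fixes_per_burst)
    times = (starts[:, None] + offsets[None, :]).ravel()
    lat, lon, _ = _eval_path(segs, times)
    # GPS error = per-burst bias (atmospheric/multipath drift, constant over
    # a 1-min window) + small fix-to-fix jitter; i.i.d. noise per fix would
    # wildly overstate apparent motion between adjacent 10-s cells
    m_to_lat = 1.0 / EARTH_RADIUS_M / DEG
    m_to_lon = m_to_lat / math.cos(cfg.ref_lat * DEG)
    n_b = len(starts)
    bias_lat = np.repeat(rng.normal(0, cfg.gps_bias_sd_m, n_b), cfg.fixes_per_burst)
    bias_lon = np.repeat(rng.normal(0, cfg.gps_bias_sd_m, n_b), cfg.fixes_per_burst)
    lat = lat + (bias_lat + rng.normal(0, cfg.gps_jitter_sd_m, len(times))) * m_to_lat
    lon = lon + (bias_lon + rng.normal(0, cfg.gps_jitter_sd_m, len(times))) * m_to_lon
    acc = rng.lognormal(cfg.accuracy_log_mu, cfg.accuracy_log_sigma, len(times))
    return times, lat, lon, acc


def apply_observation_model(segs: np.ndarray, cfg: ScenarioConfig,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Duty-cycled noisy sampling of one day's continuous path.

    Returns day-second fixes (columns ``sec``, ``latitude``, ``longitude``,
    ``altitude``, ``accuracy``); the caller attaches the calendar date.
    """
    times, lat, lon, acc = _observe(segs, cfg, rng)
    return pd.DataFrame({
        "sec": times, "latitude": lat, "longitude": lon,
        "altitude": np.zeros(len(times)), "accuracy": acc,
    })


# ---------------------------------------------------------------------------
# mood coupling

def couple_mood(dlv: float, dhs: float, prev: np.ndarray, coupling: Coupling,
                cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Advance the four latent moods one day.

    ``prev`` holds yesterday's latents (fatigue, depressed, manic,
    irritability); ``dlv``/``dhs`` are today's changes in true location
    variance and homestay.  AR(1) carryover plus the planted feature->mood
    terms plus Gaussian innovation.
    """
    drive = np.array([
        coupling.b_hs_fat * dhs,
        coupling.b_lv_dep * dlv + coupling.b_hs_dep * dhs,
        0.0,
        coupling.b_hs_irr * dhs,
    ])
    return cfg.mood_ar * prev + drive + rng.normal(0, cfg.mood_noise_sd, 4)


def _to_ordinal(latent: np.ndarray, thresholds: tuple[float, ...]) -> np.ndarray:
    return 1 + np.searchsorted(np.asarray(thresholds), latent, side="left")


# ---------------------------------------------------------------------------
# cohort assembly

def _participant_sites(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Home plus k-1 sites; rows are (lat, lon)."""
    b = rng.uniform(0, 2 * math.pi)
    d = rng.uniform(0, 3000.0)
    dlat, dlon = _offset_deg(cfg.ref_lat, d, b)
    home = (cfg.ref_lat + dlat, cfg.ref_lon + dlon)
    sites = [home]
    dists = [rng.uniform(1000, 6000)] + [rng.uniform(500, 4000)
                                         for _ in range(cfg.k_locations - 2)]
    for d_m in dists:
        b = rng.uniform(0, 2 * math.pi)
        dlat, dlon = _offset_deg(cfg.ref_lat, d_m, b)
        sites.append((home[0] + dlat, home[1] + dlon))
    return np.asarray(sites)


def generate_cohort(cfg: ScenarioConfig | None = None,
                    outdir: str | Path | None = None,
                    groups: tuple[str, ...] | None = None) -> SyntheticCohort:
    """Simulate the full study; optionally write it to ``outdir``.

    On disk: ``gps/<participant>.csv`` (Beiwe dialect), ``ema.csv``,
    ``participants.csv``, ``truth.csv`` (true daily features and latent
    moods), ``scenario.json``.

    ``groups`` restricts generation to those study arms.  Every participant
    draws from an independent substream keyed by (master_seed, index), so
    the generated participants are bit-identical whether or not the others
    are materialized — the restriction is purely computational.
    """
    cfg = cfg or ScenarioConfig()
    start = pd.Timestamp(cfg.start_date)
    # scale the study's HC/BP/MDD mix to the requested cohort size
    props = np.asarray(cfg.group_sizes, dtype=float)
    props = props / props.sum()
    counts = np.floor(props * cfg.n_participants).astype(int)
    while counts.sum() < cfg.n_participants:
        counts[int(np.argmax(props * cfg.n_participants - counts))] += 1
    group_labels = []
    for g, n in zip(("HC", "BP", "MDD"), counts):
        group_labels += [g] * int(n)
    fcfg = FeatureConfig()
    meta_rows, ema_rows, truth_rows, gps = [], [], [], {}
    followup_rows = []
    for i in range(cfg.n_participants):
        pid = f"P{i + 1:03d}"
        group = group_labels[i]
        if groups is not None and group not in groups:
            continue
        rng = np.random.default_rng(np.random.SeedSequence([cfg.master_seed, i]))
        age = float(np.round(rng.normal(41.3, 12.1), 1))
        sex = int(rng.random() < 0.37)          # 1 = male
        meta_rows.append({"participant": pid, "age": age, "sex": sex, "group": group})
        sites = _participant_sites(cfg, rng)
        site_km = _site_distance_km(sites, cfg.ref_lat)
        coupling = (cfg.coupling if (group != "HC" or cfg.couple_controls)
                    else Coupling.null())
        h_base = rng.uniform(0.55, 0.85)
        bias_base = rng.uniform(0.1, 0.4)
        latent = rng.normal(0, cfg.mood_noise_sd, 4)
        prev_latent = latent.copy()
        prev_lv = prev_hs = None
        fx_sec, fx_lat, fx_lon, fx_acc = [], [], [], []
        for d in range(cfg.n_days):
            date = start + pd.Timedelta(days=d)
            followup_rows.append({"participant": pid, "date": date})
            dmood = latent - prev_latent    # yesterday's latent change
            h_t = (h_base + coupling.b_dep_hs * dmood[1]
                   + coupling.b_fat_hs * dmood[0] + coupling.b_irr_hs * dmood[3]
                   + rng.normal(0, 0.05))
            bias_t = (bias_base + coupling.b_dep_lv * dmood[1]
                      + coupling.b_fat_lv * dmood[0])
            segs = simulate_day_schedule(sites, site_km, h_t, bias_t, rng)
            feats = true_daily_features(segs, sites[:, 0], sites[:, 1], fcfg)
            dlv = 0.0 if prev_lv is None else feats["location_variance"] - prev_lv
            dhs = 0.0 if prev_hs is None else feats["homestay"] - prev_hs
            prev_lv, prev_hs = feats["location_variance"], feats["homestay"]
            prev_latent = latent
            latent = couple_mood(dlv, dhs, latent, coupling, cfg, rng)
            ords = _to_ordinal(latent, cfg.mood_thresholds)
            truth_rows.append({"participant": pid, "date": date,
                               **{f"true_{k}": v for k, v in feats.items()},
                               **{f"latent_{m}": latent[j]
                                  for j, m in enumerate(EMA_ITEMS)},
                               **{f"ord_{m}": int(ords[j])
                                  for j, m in enumerate(EMA_ITEMS)}})
            if rng.random() >= cfg.ema_missing_rate:
                ema_rows.append({"participant": pid, "date": date, "prompt": "12:45",
                                 **{m: int(ords[j]) for j, m in enumerate(EMA_ITEMS)}})
            if rng.random() < cfg.second_prompt_rate:
                lat2 = latent + rng.normal(0, cfg.prompt_noise_sd, 4)
                o2 = _to_ordinal(lat2, cfg.mood_thresholds)
                ema_rows.append({"participant": pid, "date": date, "prompt": "17:00",
                                 **{m: int(o2[j]) for j, m in enumerate(EMA_ITEMS)}})
            sec, la, lo, ac = _observe(segs, cfg, rng)
            fx_sec.append(sec + d * 86_400.0)
            fx_lat.append(la)
            fx_lon.append(lo)
            fx_acc.append(ac)
        sec = np.concatenate(fx_sec)
        t_utc = (start - pd.Timedelta(hours=cfg.utc_offset_hours)).tz_localize("UTC") \
            + pd.to_timedelta(sec, unit="s")
        gps[pid] = pd.DataFrame({
            "t_utc": t_utc,
            "latitude": np.concatenate(fx_lat),
            "longitude": np.concatenate(fx_lon),
            "altitude": np.zeros(len(sec)),
            "accuracy": np.concatenate(fx_acc),
        })
    cohort = SyntheticCohort(
        config=cfg,
        participants=pd.DataFrame(meta_rows),
        gps=gps,
        ema=pd.DataFrame(ema_rows),
        truth=pd.DataFrame(truth_rows),
        followup=pd.DataFrame(followup_rows),
    )
    if outdir is not None:
        _write_cohort(cohort, Path(outdir))
    return cohort


def _write_cohort(cohort: SyntheticCohort, outdir: Path) -> None:
    gps_dir = outdir / "gps"
    gps_dir.mkdir(parents=True, exist_ok=True)
    for pid, fixes in cohort.gps.items():
        write_gps(fixes, gps_dir / f"{pid}.csv")
    ema = cohort.ema.copy()
    ema["date"] = pd.to_datetime(ema["date"]).dt.strftime("%Y-%m-%d")
    ema.to_csv(outdir / "ema.csv", index=False)
    cohort.participants.to_csv(outdir / "participants.csv", index=False)
    truth = cohort.truth.copy()
    truth["date"] = pd.to_datetime(truth["date"]).dt.strftime("%Y-%m-%d")
    truth.to_csv(outdir / "truth.csv", index=False)
    (outdir / "scenario.json").write_text(cohort.config.to_json())
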
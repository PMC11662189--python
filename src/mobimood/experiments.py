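"""Validation experiments on synthetic cohorts.

These are the package's standard self-checks: end-to-end recovery of the
planted mood-mobility coupling signs, type-I calibration of the lag models
under a null cohort, and the accuracy gain from simulation-averaged
trajectory imputation.  Both the test suite and ``scripts/acceptance.py``
drive them, so the problem sizes are chosen to run on one CPU in minutes;
``docs/methods.md`` discusses the choices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ema as ema_mod
from . import stats
from .features import FEATURE_NAMES, cluster_locations, daily_features, infer_home
from .pipeline import process_gps
from .preprocess import PreprocessConfig
from .synthetic import Coupling, ScenarioConfig, generate_cohort

#: the four planted pathways checked for sign recovery:
#: (direction, predictor, outcome, expected sign)
PLANTED_PATHWAYS = (
    ("feature_to_mood", "homestay", "depressed", +1),
    ("feature_to_mood", "location_variance", "depressed", -1),
    ("mood_to_feature", "depressed", "location_variance", -1),
    ("mood_to_feature", "fatigue", "homestay", +1),
)


def _fit_pathways(pairs: pd.DataFrame, meta: pd.DataFrame) -> list[dict]:
    out = []
    for direction, pred, outc, sign in PLANTED_PATHWAYS:
        res = stats.fit_lag_model(pairs, meta, direction, outc, pred)
        b, se, p = res.delta
        out.append({"direction": direction, "predictor": pred, "outcome": outc,
                    "expected_sign": sign, "beta": b, "se": se, "p_value": p,
                    "n_pairs": res.n_pairs})
    return out


def sign_recovery_replicate(seed: int, n_participants: int = 38, n_days: int = 180,
                            n_sim: int = 1) -> list[dict]:
    """One full generate -> preprocess -> features -> lag-model replicate.

    The cohort is defined at study scale; only the patient group (whose data
    enter the lag models) is materialized and pushed through the GPS
    estimation pipeline — per-participant seed substreams make the patient
    data identical either way — and the four planted pathways are fit.
    Returns one dict per pathway.
    """
    cfg = ScenarioConfig(n_participants=n_participants, n_days=n_days,
                         master_seed=seed)
    cohort = generate_cohort(cfg, groups=("BP", "MDD"))
    patients = cohort.participants
    gps = cohort.gps
    feats, _ = process_gps(gps, PreprocessConfig(n_sim=n_sim), master_seed=seed)
    analysis = ema_mod.select_analysis_prompt(cohort.ema)
    analysis = analysis[analysis["participant"].isin(patients["participant"])]
    pairs = stats.build_day_pairs(feats, analysis)
    return _fit_pathways(pairs, patients)


def null_calibration_replicate(seed: int, n_participants: int = 15,
                               n_days: int = 60) -> list[dict]:
    """One zero-coupling replicate fit on the generator's true daily features.

    With every coupling coefficient at zero, mood and mobility are
    independent by construction; the measurement layer cannot induce a
    dependence, so the lag models are fit on the true features directly and
    their delta-term p-values probe type-I behavior of the inference.
    """
    cfg = ScenarioConfig(n_participants=n_participants, n_days=n_days,
                         coupling=Coupling.null(), couple_controls=True,
                         master_seed=seed)
    cohort = generate_cohort(cfg)
    feats = cohort.truth[["participant", "date"]
                         + [f"true_{f}" for f in FEATURE_NAMES]].rename(
        columns={f"true_{f}": f for f in FEATURE_NAMES})
    analysis = ema_mod.select_analysis_prompt(cohort.ema)
    pairs = stats.build_day_pairs(feats, analysis)
    return _fit_pathways(pairs, cohort.participants)


def imputation_benefit(seed: int, n_days: int = 20, n_sim: int = 10) -> dict:
    """Total-distance error with and without simulation-averaged imputation.

    Simulates ``n_days`` duty-cycled days for one participant, computes the
    daily total distance three ways (ground truth on the continuous path;
    10-realization hot-deck average; observed cells only) and returns the
    mean absolute errors of the two estimates.
    """
    from .preprocess import preprocess_participant

    cfg = ScenarioConfig(n_participants=1, n_days=n_days, master_seed=seed,
                         group_sizes=(0, 0, 1))
    cohort = generate_cohort(cfg)
    pid = cohort.participants["participant"].iloc[0]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    days, imputed, _ = preprocess_participant(
        cohort.gps[pid], PreprocessConfig(n_sim=n_sim), rng=rng)
    pauses = pd.concat([d.pauses for d in days], ignore_index=True)
    clusters = cluster_locations(pauses)
    home = infer_home(clusters, pauses)
    rows = []
    truth = cohort.truth.set_index("date")["true_total_distance"]
    for day, imp in zip(days, imputed):
        true_d = truth.loc[day.date]
        obs = daily_features(day, clusters, home)["total_distance"]
        est = daily_features(imp, clusters, home)["total_distance"]
        rows.append({"true": true_d, "observed_only": obs, "imputed": est})
    df = pd.DataFrame(rows)
    return {
        "mae_imputed": float((df["imputed"] - df["true"]).abs().mean()),
        "mae_observed_only": float((df["observed_only"] - df["true"]).abs().mean()),
        "n_days": len(df),
    }


def adherence_fixture(n_participants: int = 38, answered: int = 4803,
                      total: int = 5137) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A follow-up calendar and EMA analysis series encoding given counts.

    Person-days are spread as evenly as possible over the participants and
    the unanswered days placed deterministically, so the QC counting path
    reproduces ``answered / total`` exactly.
    """
    per = np.full(n_participants, total // n_participants)
    per[: total % n_participants] += 1
    miss = total - answered
    miss_per = np.zeros(n_participants, dtype=int)
    i = 0
    while miss > 0:
        take = min(per[i] // 2, miss)
        miss_per[i] = take
        miss -= take
        i += 1
    follow_rows, ema_rows = [], []
    start = pd.Timestamp("2020-03-01")
    for p in range(n_participants):
        pid = f"P{p + 1:03d}"
        dates = pd.date_range(start, periods=per[p], freq="D")
        for j, d in enumerate(dates):
            follow_rows.append({"participant": pid, "date": d})
            if j >= miss_per[p]:
                ema_rows.append({"participant": pid, "date": d,
                                 "fatigue": 2, "depressed": 2, "manic": 1,
                                 "irritability": 1})
    return pd.DataFrame(ema_rows), pd.DataFrame(follow_rows)
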
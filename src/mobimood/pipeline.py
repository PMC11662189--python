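"""End-to-end orchestration: raw study directory to results bundle.

A study directory holds ``gps/<participant>.csv`` files in the six-column
dialect, ``ema.csv`` and ``participants.csv``.  :func:`run_all` cleans and
imputes each participant's GPS stream, computes daily features, reduces the
EMA series, runs the weekly polyserial screen and the bidirectional lag
models on the patient group, and writes CSV tables plus a QC report and the
resolved configuration next to them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ema as ema_mod
from . import gps_io, stats
from .features import FEATURE_NAMES, FeatureConfig, cluster_locations, daily_features, infer_home
from .preprocess import PreprocessConfig, preprocess_participant

logger = logging.getLogger(__name__)

PATIENT_GROUPS = ("BP", "MDD")


@dataclass
class RunConfig:
    input_dir: str = "."
    output_dir: str = "results"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    utc_offset_hours: int = 8
    week_window: str = "first"
    patient_groups: tuple[str, ...] = PATIENT_GROUPS
    master_seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)


def process_gps(gps: dict[str, pd.DataFrame],
                pre_cfg: PreprocessConfig | None = None,
                feat_cfg: FeatureConfig | None = None,
                offset_hours: int = 8,
                master_seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Clean, impute and featurize every participant's GPS stream.

    ``gps`` maps participant id to a fixes frame (as loaded by
    :func:`mobimood.gps_io.read_gps_files`).  Returns the daily-features
    table (NaN feature rows carry a ``reason``) and a QC dict.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    feat_cfg = feat_cfg or FeatureConfig()
    rows: list[dict] = []
    qc: dict = {"participants": {}}
    for idx, pid in enumerate(sorted(gps)):
        fixes = gps[pid]
        rng = np.random.default_rng(np.random.SeedSequence([master_seed, 7_919, idx]))
        n_raw = len(fixes)
        days, imputed, _ = preprocess_participant(fixes, pre_cfg, offset_hours, rng)
        n_kept = int((fixes["accuracy"] < pre_cfg.accuracy_threshold).sum())
        pauses = pd.concat([d.pauses for d in days if d.pauses is not None and len(d.pauses)],
                           ignore_index=True) if days else pd.DataFrame()
        if not len(pauses):
            logger.warning("%s: no pause events at all, participant skipped", pid)
            qc["participants"][pid] = {"n_fixes": n_raw, "retention": np.nan, "n_days": 0}
            continue
        clusters = cluster_locations(pauses, feat_cfg.d_max_m)
        home = infer_home(clusters, pauses, feat_cfg)
        n_null = 0
        for day, imp in zip(days, imputed):
            if imp is not None:
                feats = daily_features(imp, clusters, home, feat_cfg)
                reason = ""
            elif day.coverage >= pre_cfg.coverage_floor:
                feats = daily_features(day, clusters, home, feat_cfg)
                reason = "observed-only"
            else:
                feats = {k: np.nan for k in FEATURE_NAMES}
                feats["coverage"] = day.coverage
                feats["date"] = day.date
                reason = "unimputable"
                n_null += 1
            rows.append({"participant": pid, **feats, "reason": reason})
        qc["participants"][pid] = {
            "n_fixes": n_raw,
            "retention": n_kept / n_raw if n_raw else np.nan,
            "n_days": len(days),
            "n_unusable_days": n_null,
            "n_clusters": len(clusters),
            "mean_coverage": float(np.mean([d.coverage for d in days])),
        }
    cols = ["participant", "date", *FEATURE_NAMES, "coverage", "reason"]
    feats_df = pd.DataFrame(rows)
    if len(feats_df):
        feats_df = feats_df[cols]
    return feats_df, qc


def infer_followup(features_df: pd.DataFrame, ema_df: pd.DataFrame) -> pd.DataFrame:
    """Follow-up calendar per participant: every day from first to last datum."""
    spans: dict[str, tuple] = {}
    for df in (features_df, ema_df):
        if df is None or not len(df):
            continue
        for pid, grp in df.groupby("participant"):
            lo, hi = grp["date"].min(), grp["date"].max()
            if pid in spans:
                lo = min(lo, spans[pid][0])
                hi = max(hi, spans[pid][1])
            spans[pid] = (lo, hi)
    rows = []
    for pid, (lo, hi) in sorted(spans.items()):
        for d in pd.date_range(lo, hi, freq="D"):
            rows.append({"participant": pid, "date": d})
    return pd.DataFrame(rows)


def analyze(features_df: pd.DataFrame, ema_raw: pd.DataFrame,
            participants: pd.DataFrame, followup: pd.DataFrame | None = None,
            week_window: str = "first",
            patient_groups: tuple[str, ...] = PATIENT_GROUPS) -> dict:
    """EMA reduction plus the full statistics layer.

    Returns a dict with the analysis EMA series, weekly summaries, the
    polyserial correlation table (all participants), the day-pair table and
    lag-model battery (patient group only), ICCs, and QC counts.
    """
    analysis = ema_mod.select_analysis_prompt(ema_raw)
    if followup is None:
        followup = infer_followup(features_df, analysis)
    iccs = {item: ema_mod.icc_between_prompts(ema_raw, item) for item in gps_io.EMA_ITEMS}
    missing = ema_mod.ema_missing_rate(analysis, followup)
    answered, total, pct = ema_mod.adherence(analysis, followup)
    weekly = stats.weekly_aggregate(features_df, analysis, window=week_window)
    corr = stats.correlation_table(weekly)
    patients = participants[participants["group"].isin(patient_groups)]
    pat_feats = features_df[features_df["participant"].isin(patients["participant"])]
    pat_ema = analysis[analysis["participant"].isin(patients["participant"])]
    pairs = stats.build_day_pairs(pat_feats, pat_ema)
    lag = stats.lag_model_battery(pairs, patients)
    qc = {
        "adherence_answered": int(answered),
        "adherence_total": int(total),
        "adherence_pct": float(pct),
        "ema_missing_rate_mean": float(missing.mean()),
        "icc": {k: (float(v) if np.isfinite(v) else None) for k, v in iccs.items()},
        "n_weekly_participants": int(len(weekly)),
        "n_day_pairs": int(len(pairs)),
    }
    return {"analysis_ema": analysis, "weekly": weekly, "correlations": corr,
            "pairs": pairs, "lag_models": lag, "qc": qc, "followup": followup}


def run_all(config: RunConfig) -> dict:
    """Execute the whole pipeline on a study directory and write the bundle."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    gps_paths = sorted((indir / "gps").glob("*.csv"))
    if not gps_paths:
        raise FileNotFoundError(f"no GPS files under {indir / 'gps'}")
    gps = {}
    for p in gps_paths:
        fixes, rejects = gps_io.read_gps_files([p])
        if rejects.n_rejected:
            logger.info("%s: rejected %d rows (%s)", p.name, rejects.n_rejected, rejects.reasons)
        gps[p.stem] = fixes
    ema_raw = gps_io.read_ema(indir / "ema.csv")
    participants = gps_io.read_participants(indir / "participants.csv")
    features_df, gps_qc = process_gps(gps, config.preprocess, config.features,
                                      config.utc_offset_hours, config.master_seed)
    res = analyze(features_df, ema_raw, participants,
                  week_window=config.week_window,
                  patient_groups=config.patient_groups)
    features_df.to_csv(outdir / "daily_features.csv", index=False)
    res["correlations"].to_csv(outdir / "correlation_table.csv", index=False)
    res["lag_models"].to_csv(outdir / "lag_models.csv", index=False)
    res["weekly"].to_csv(outdir / "weekly_summary.csv", index=False)
    qc = {"gps": gps_qc, "ema": res["qc"]}
    (outdir / "qc_report.json").write_text(json.dumps(qc, indent=2, default=float))
    (outdir / "resolved_config.json").write_text(config.to_json())
    res["daily_features"] = features_df
    res["qc_full"] = qc
    return res
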
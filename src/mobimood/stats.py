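"""Statistics layer: weekly polyserial screening, day-lagged GEE models,
and Fisher-z power / sample-size calculations.

The lag models are marginal linear (identity link) GEEs with the participant
as the cluster and a first-order autoregressive working correlation across
day pairs, reported with robust sandwich standard errors.  Each model
regresses a day-2 outcome on the day-1-to-day-2 change in the predictor,
age, sex, and the predictor's day-1 level — one model per
(feature, mood item) pair and direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats as sps

from .gps_io import EMA_ITEMS
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

#: the three features carried into the lag models
LAG_FEATURES = ("location_variance", "normalized_entropy", "homestay")


# ---------------------------------------------------------------------------
# Fisher-z power and sample size

def fisher_required_n(rho: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Sample size for detecting a correlation ``rho`` via the Fisher z test.

    n = ((z_{1-alpha/2} + z_power) / atanh(rho))^2 + 3, rounded to the
    nearest integer (the rounding convention of the standard tables: 29 at
    rho=0.5, power .80; 38 at power .90).
    """
    if not 0 < abs(rho) < 1:
        raise ValueError("rho must lie strictly between 0 and 1 in magnitude")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    z = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)
    return int(round((z / np.arctanh(abs(rho))) ** 2 + 3))


def fisher_power(rho: float, n: int, alpha: float = 0.05) -> float:
    """Achieved power of the two-sided Fisher z test at correlation ``rho``.

    power = Phi(|atanh(rho)| * sqrt(n-3) - z_{1-alpha/2}); the far tail of
    the two-sided rejection region is ignored, as is conventional.
    """
    if n < 4:
        raise ValueError("n must be at least 4")
    return float(sps.norm.cdf(abs(np.arctanh(rho)) * np.sqrt(n - 3)
                              - sps.norm.ppf(1 - alpha / 2)))


# ---------------------------------------------------------------------------
# Polyserial correlation

@dataclass(frozen=True)
class PolyserialResult:
    rho: float
    se: float
    p_value: float
    n: int


def polyserial(x: np.ndarray, y: np.ndarray) -> PolyserialResult:
    """Two-step polyserial correlation between continuous ``x`` and ordinal ``y``.

    Thresholds of the latent normal behind ``y`` come from the inverse-normal
    cumulative category proportions; the latent correlation ``rho`` is then
    fit by maximum likelihood with the thresholds held fixed.  The two-sided
    p-value uses the large-sample SE from the observed information.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    ok = np.isfinite(x) & pd.notna(y)
    x, y = x[ok], np.asarray(y[ok], dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("polyserial needs at least 5 complete observations")
    levels, counts = np.unique(y, return_counts=True)
    if len(levels) < 2:
        return PolyserialResult(np.nan, np.nan, np.nan, n)
    cum = np.cumsum(counts)[:-1] / n
    tau = sps.norm.ppf(cum)                       # interior thresholds
    lo = np.concatenate(([-np.inf], tau))         # per-category lower bound
    hi = np.concatenate((tau, [np.inf]))
    cat = np.searchsorted(levels, y)
    z = (x - x.mean()) / x.std()

    def negll(rho: float) -> float:
        s = np.sqrt(1 - rho * rho)
        upper = sps.norm.cdf((hi[cat] - rho * z) / s)
        lower = sps.norm.cdf((lo[cat] - rho * z) / s)
        p = np.clip(upper - lower, 1e-300, None)
        return -np.log(p).sum()

    res = optimize.minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded")
    rho = float(res.x)
    h = 1e-4
    d2 = (negll(rho + h) - 2 * negll(rho) + negll(rho - h)) / h**2
    se = float(1 / np.sqrt(d2)) if d2 > 0 else np.nan
    if np.isfinite(se) and se > 0:
        p = float(2 * sps.norm.sf(abs(rho) / se))
    else:
        p = np.nan
    return PolyserialResult(rho, se, max(p, np.finfo(float).tiny), n)


# ---------------------------------------------------------------------------
# Weekly aggregation and screening correlations

def weekly_aggregate(features: pd.DataFrame, ema: pd.DataFrame,
                     window: str = "first", min_days: int = 4) -> pd.DataFrame:
    """Per-participant weekly summaries pairing GPS features with mood.

    Weeks are consecutive 7-day blocks from each participant's first
    feature day.  ``window='first'`` keeps the first block with at least
    ``min_days`` valid days in both series; ``window='all'`` averages over
    every qualifying block.  Features are summarized by the weekly mean,
    moods by the rounded mean category (ordinal 1-5).
    """
    if window not in ("first", "all"):
        raise ValueError("window must be 'first' or 'all'")
    daily = features.merge(ema, on=["participant", "date"], how="outer")
    rows = []
    for pid, grp in daily.groupby("participant"):
        grp = grp.sort_values("date")
        start = grp["date"].min()
        week_idx = ((grp["date"] - start).dt.days // 7).to_numpy()
        summaries = []
        for _, wk in grp.groupby(week_idx):
            feat_ok = wk[list(FEATURE_NAMES)].notna().all(axis=1).sum()
            mood_ok = wk[list(EMA_ITEMS)].notna().all(axis=1).sum()
            if feat_ok < min_days or mood_ok < min_days:
                continue
            row = {f: wk[f].mean() for f in FEATURE_NAMES}
            row |= {m: wk[m].astype(float).mean() for m in EMA_ITEMS}
            summaries.append(row)
            if window == "first":
                break
        if not summaries:
            logger.info("participant %s: no qualifying week, excluded", pid)
            continue
        agg = pd.DataFrame(summaries).mean()
        rec = {"participant": pid}
        rec |= {f: float(agg[f]) for f in FEATURE_NAMES}
        rec |= {m: int(np.clip(np.rint(agg[m]), 1, 5)) for m in EMA_ITEMS}
        rows.append(rec)
    return pd.DataFrame(rows)


def correlation_table(weekly: pd.DataFrame) -> pd.DataFrame:
    """Polyserial rho and p for every (feature, mood item) pair."""
    rows = []
    for f in FEATURE_NAMES:
        for m in EMA_ITEMS:
            sub = weekly[[f, m]].dropna()
            try:
                res = polyserial(sub[f].to_numpy(), sub[m].to_numpy())
                rows.append({"feature": f, "mood": m, "rho": res.rho,
                             "p_value": res.p_value, "n": res.n})
            except ValueError as err:
                logger.info("correlation %s-%s skipped: %s", f, m, err)
                rows.append({"feature": f, "mood": m, "rho": np.nan,
                             "p_value": np.nan, "n": len(sub)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Day pairs and lagged GEE models

def build_day_pairs(features: pd.DataFrame, ema: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-day pair table for the lag models.

    One row per (participant, day1, day2 = day1 + 1) where both calendar days
    appear in the merged daily table.  Carries day-1 levels, day-2 levels and
    day-2 minus day-1 changes for every feature and mood item; missing
    elements stay NaN and are dropped per model at fit time.
    """
    daily = features.merge(ema, on=["participant", "date"], how="outer")
    daily = daily.sort_values(["participant", "date"]).reset_index(drop=True)
    cols = list(FEATURE_NAMES) + list(EMA_ITEMS)
    nxt = daily.groupby("participant", group_keys=False).shift(-1)
    consecutive = (nxt["date"] - daily["date"]).dt.days == 1
    keep = consecutive.fillna(False).to_numpy()
    out = pd.DataFrame({
        "participant": daily.loc[keep, "participant"].to_numpy(),
        "date1": daily.loc[keep, "date"].to_numpy(),
    })
    for c in cols:
        a = pd.to_numeric(daily.loc[keep, c], errors="coerce").to_numpy(dtype=float)
        b = pd.to_numeric(nxt.loc[keep, c], errors="coerce").to_numpy(dtype=float)
        out[f"{c}_d1"] = a
        out[f"{c}_d2"] = b
        out[f"d_{c}"] = b - a
    return out


@dataclass
class LagFitResult:
    """One fitted bidirectional lag model."""

    direction: str                    # 'feature_to_mood' or 'mood_to_feature'
    outcome: str
    predictor: str
    params: dict = field(default_factory=dict)   # term -> (beta, robust SE, p)
    ar1: float = np.nan               # AR(1) working-correlation parameter
    n_pairs: int = 0
    n_participants: int = 0
    converged: bool = True

    def term(self, name: str) -> tuple[float, float, float]:
        return self.params[name]

    @property
    def delta(self) -> tuple[float, float, float]:
        """(beta, SE, p) of the day-1-to-day-2 change term."""
        return self.params["delta"]


def fit_lag_model(pairs: pd.DataFrame, meta: pd.DataFrame, direction: str,
                  outcome: str, predictor: str,
                  cov: str = "ar1") -> LagFitResult:
    """Fit one lag model on the day-pair table.

    ``direction='feature_to_mood'``: outcome is a mood item's day-2 value,
    predictor a GPS feature (its change and day-1 level enter).
    ``direction='mood_to_feature'`` swaps the roles.  ``meta`` supplies age
    and sex per participant.  ``cov`` selects the working correlation:
    'ar1' (default) or 'independence' (useful as an OLS-equivalence oracle).
    """
    if direction not in ("feature_to_mood", "mood_to_feature"):
        raise ValueError(f"unknown direction: {direction!r}")
    ycol = f"{outcome}_d2"
    dcol = f"d_{predictor}"
    lcol = f"{predictor}_d1"
    df = pairs.merge(meta[["participant", "age", "sex"]], on="participant", how="left")
    df = df[["participant", "date1", ycol, dcol, "age", "sex", lcol]].dropna()
    n_part = df["participant"].nunique()
    if len(df) < 10 or n_part < 2:
        raise ValueError(
            f"too little data for {direction} {predictor}->{outcome}: "
            f"{len(df)} pairs from {n_part} participants")
    df = df.sort_values(["participant", "date1"])
    endog = df[ycol].to_numpy(dtype=float)
    exog = sm.add_constant(df[[dcol, "age", "sex", lcol]].to_numpy(dtype=float))
    groups = df["participant"].to_numpy()
    if cov == "ar1":
        # grid form: successive rows within a cluster are one day-lag apart
        # (gaps from missing days only perturb the nuisance AR estimate;
        # robust SEs do not rely on it)
        cov_struct = sm.cov_struct.Autoregressive(grid=True)
    elif cov == "independence":
        cov_struct = sm.cov_struct.Independence()
    else:
        raise ValueError(f"unknown working correlation: {cov!r}")
    model = sm.GEE(endog, exog, groups=groups,
                   family=sm.families.Gaussian(), cov_struct=cov_struct)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(maxiter=100)
    converged = bool(getattr(fit, "converged", True))
    if not converged:
        logger.warning("GEE did not converge: %s %s->%s", direction, predictor, outcome)
    names = ["const", "delta", "age", "sex", "level_day1"]
    params = {nm: (float(b), float(se), float(p))
              for nm, b, se, p in zip(names, fit.params, fit.bse, fit.pvalues)}
    ar1 = float(np.atleast_1d(cov_struct.dep_params)[0]) if cov == "ar1" else 0.0
    return LagFitResult(direction=direction, outcome=outcome, predictor=predictor,
                        params=params, ar1=ar1, n_pairs=len(df),
                        n_participants=n_part, converged=converged)


def lag_model_battery(pairs: pd.DataFrame, meta: pd.DataFrame,
                      features: tuple[str, ...] = LAG_FEATURES,
                      moods: tuple[str, ...] = EMA_ITEMS) -> pd.DataFrame:
    """Fit the full bidirectional battery and return one tidy table.

    Feature-to-mood: every mood item's day-2 value on each feature's change.
    Mood-to-feature: every feature's day-2 value on each mood item's change.
    """
    rows = []
    for direction, preds, outs in (
        ("feature_to_mood", features, moods),
        ("mood_to_feature", moods, features),
    ):
        for pred in preds:
            for out in outs:
                try:
                    res = fit_lag_model(pairs, meta, direction, out, pred)
                except ValueError as err:
                    logger.info("lag model skipped: %s", err)
                    continue
                for term, (b, se, p) in res.params.items():
                    rows.append({
                        "direction": direction, "outcome": out, "predictor": pred,
                        "term": term, "beta": b, "se": se, "p_value": p,
                        "ar1": res.ar1, "n_pairs": res.n_pairs,
                        "converged": res.converged,
                    })
    return pd.DataFrame(rows)
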
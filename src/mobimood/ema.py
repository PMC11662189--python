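"""EMA mood series handling: prompt selection, agreement, missingness.

Participants answer four ordinal items (fatigue, depressed, manic,
irritability; 1 = not at all ... 5 = serious and lasted all day) at two daily
prompts.  The 12:45 response is the analysis series; the 17:00 response is
used only to quantify within-day consistency via an intraclass correlation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .gps_io import EMA_ITEMS

logger = logging.getLogger(__name__)

ANALYSIS_PROMPT = "12:45"
SECOND_PROMPT = "17:00"


def select_analysis_prompt(ema: pd.DataFrame, prompt: str = ANALYSIS_PROMPT) -> pd.DataFrame:
    """Reduce to one record per participant-date: the analysis prompt only.

    A date whose analysis prompt is unanswered is simply absent (there is no
    fallback to the other prompt); duplicates keep the first by load order.
    """
    out = ema[ema["prompt"] == prompt]
    dups = out.duplicated(["participant", "date"])
    if dups.any():
        logger.info("dropping %d duplicate prompt record(s), keeping first", int(dups.sum()))
        out = out[~dups]
    return out.drop(columns="prompt").reset_index(drop=True)


def _icc_a1(y: np.ndarray) -> float:
    """ICC(A,1): two-way, absolute agreement, single measure.

    ``y`` is an (n_rows, k_raters) complete matrix; here rows are dates and
    the two raters are the two daily prompts.
    """
    n, k = y.shape
    if n < 2:
        return np.nan
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((y - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0:
        return 1.0 if msr == mse else np.nan
    return float((msr - mse) / denom)


def icc_between_prompts(ema: pd.DataFrame, item: str) -> float:
    """Between-prompt ICC for one mood item.

    Dates with both prompts answered are paired within each participant;
    the per-participant ICC(A,1) values are then averaged (participants with
    fewer than 2 complete pairs contribute nothing).  NaN when no participant
    has enough complete pairs.
    """
    if item not in EMA_ITEMS:
        raise ValueError(f"unknown EMA item: {item!r}")
    wide = (
        ema.pivot_table(index=["participant", "date"], columns="prompt",
                        values=item, aggfunc="first", observed=True)
        .dropna()
    )
    if ANALYSIS_PROMPT not in wide.columns or SECOND_PROMPT not in wide.columns:
        return np.nan
    vals = []
    for _, grp in wide.groupby(level="participant"):
        y = grp[[ANALYSIS_PROMPT, SECOND_PROMPT]].to_numpy(dtype=float)
        icc = _icc_a1(y)
        if np.isfinite(icc):
            vals.append(icc)
    if not vals:
        logger.warning("ICC undefined for %s: no participant with >=2 complete pairs", item)
        return np.nan
    return float(np.mean(vals))


def ema_missing_rate(analysis: pd.DataFrame, followup: pd.DataFrame) -> pd.Series:
    """Per-participant fraction of follow-up days with no analysis response.

    ``followup`` lists the person-day calendar (columns ``participant``,
    ``date``); a day counts as answered when an analysis-prompt record exists
    with at least one item filled in.
    """
    answered = analysis.dropna(subset=list(EMA_ITEMS), how="all")
    have = set(zip(answered["participant"], answered["date"]))
    flag = [
        (p, d) in have for p, d in zip(followup["participant"], followup["date"])
    ]
    df = followup.assign(_answered=flag)
    return 1.0 - df.groupby("participant")["_answered"].mean()


def adherence(analysis: pd.DataFrame, followup: pd.DataFrame) -> tuple[int, int, float]:
    """Pooled adherence: (answered days, total person-days, percentage)."""
    answered = analysis.dropna(subset=list(EMA_ITEMS), how="all")
    have = set(zip(answered["participant"], answered["date"]))
    total = len(followup)
    n_answered = sum(
        (p, d) in have for p, d in zip(followup["participant"], followup["date"])
    )
    pct = 100.0 * n_answered / total if total else np.nan
    return n_answered, total, pct
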
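"""Reading and writing the Beiwe-style GPS dialect and EMA tables.

The smartphone app uploads hourly CSV chunks with six columns
(``timestamp``, ``UTC time``, ``latitude``, ``longitude``, ``altitude``,
``accuracy``).  Timestamps are UTC; all daily aggregation downstream uses
local study time (UTC+8 for the Taiwan deployment the defaults target).
Malformed rows are rejected and counted, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of the GPS dialect
GPS_COLUMNS = ("timestamp", "UTC time", "latitude", "longitude", "altitude", "accuracy")

#: canonical EMA mood items, in file order
EMA_ITEMS = ("fatigue", "depressed", "manic", "irritability")

#: the two daily prompt labels
PROMPTS = ("12:45", "17:00")

#: hours local study time runs ahead of UTC
DEFAULT_UTC_OFFSET_HOURS = 8


@dataclass
class RejectLog:
    """Per-load accounting of rows that failed validation."""

    n_read: int = 0
    n_rejected: int = 0
    reasons: dict = field(default_factory=dict)

    def add(self, reason: str, n: int = 1) -> None:
        if n:
            self.n_rejected += n
            self.reasons[reason] = self.reasons.get(reason, 0) + n


def _parse_timestamps(raw: pd.Series) -> pd.Series:
    """Parse a timestamp column that is either epoch-milliseconds or ISO-8601.

    Detection is per file: if the column coerces to numeric it is treated as
    epoch-ms, otherwise as ISO-8601 strings.  Unparseable entries become NaT
    (rejected by the caller, row by row).
    """
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().any():
        return pd.to_datetime(numeric, unit="ms", errors="coerce", utc=True)
    return pd.to_datetime(raw, errors="coerce", utc=True, format="mixed")


def read_gps_files(
    paths: Iterable[str | Path],
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, RejectLog]:
    """Load and concatenate hourly GPS CSV chunks into one time-sorted frame.

    Parameters
    ----------
    paths
        CSV files in the six-column dialect; rows may be unsorted across files.
    column_map
        Optional mapping from canonical names (:data:`GPS_COLUMNS`) to the
        header names actually present in the files.

    Returns
    -------
    frame, rejects
        ``frame`` has columns ``t_utc`` (tz-aware), ``latitude``,
        ``longitude``, ``altitude``, ``accuracy`` sorted by ``t_utc``
        (stable, so load order breaks ties).  ``rejects`` counts rows that
        failed validation, by reason.

    Raises
    ------
    ValueError
        If a file lacks a required column (named in the message).
    """
    column_map = dict(column_map or {})
    rejects = RejectLog()
    frames: list[pd.DataFrame] = []
    for path in paths:
        # round_trip parser: re-reading our own output is bit-exact
        df = pd.read_csv(path, float_precision="round_trip")
        rename = {column_map.get(c, c): c for c in GPS_COLUMNS}
        missing = [src for src in rename if src not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
        df = df.rename(columns=rename)[list(GPS_COLUMNS)]
        t = _parse_timestamps(df["timestamp"])
        for col in ("latitude", "longitude", "altitude", "accuracy"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        bad_time = t.isna()
        bad_lat = ~df["latitude"].between(-90, 90)
        bad_lon = ~df["longitude"].between(-180, 180)
        bad_acc = ~(df["accuracy"] >= 0)
        for reason, mask in (
            ("unparseable timestamp", bad_time),
            ("latitude out of range", bad_lat & ~bad_time),
            ("longitude out of range", bad_lon & ~bad_time & ~bad_lat),
            ("negative or missing accuracy", bad_acc & ~bad_time & ~bad_lat & ~bad_lon),
        ):
            n = int(mask.sum())
            if n:
                logger.debug("%s: rejecting %d row(s): %s", path, n, reason)
                rejects.add(reason, n)
        keep = ~(bad_time | bad_lat | bad_lon | bad_acc)
        rejects.n_read += len(df)
        out = df.loc[keep, ["latitude", "longitude", "altitude", "accuracy"]].copy()
        out.insert(0, "t_utc", t[keep])
        frames.append(out)
    if not frames:
        empty = pd.DataFrame(
            {
                "t_utc": pd.Series(dtype="datetime64[ns, UTC]"),
                "latitude": pd.Series(dtype=float),
                "longitude": pd.Series(dtype=float),
                "altitude": pd.Series(dtype=float),
                "accuracy": pd.Series(dtype=float),
            }
        )
        return empty, rejects
    fixes = pd.concat(frames, ignore_index=True)
    fixes = fixes.sort_values("t_utc", kind="stable", ignore_index=True)
    return fixes, rejects


def write_gps(fixes: pd.DataFrame, path: str | Path) -> None:
    """Write fixes back out in the six-column dialect (epoch-ms + ISO time)."""
    t = pd.to_datetime(fixes["t_utc"], utc=True)
    out = pd.DataFrame(
        {
            "timestamp": (t.astype("int64") // 1_000_000),
            "UTC time": t.dt.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "latitude": fixes["latitude"].to_numpy(),
            "longitude": fixes["longitude"].to_numpy(),
            "altitude": fixes["altitude"].to_numpy(),
            "accuracy": fixes["accuracy"].to_numpy(),
        }
    )
    out.to_csv(path, index=False)


def utc_to_local(
    t_utc: pd.Series | pd.Timestamp | pd.DatetimeIndex,
    offset_hours: int = DEFAULT_UTC_OFFSET_HOURS,
) -> pd.Series | pd.Timestamp | pd.DatetimeIndex:
    """Shift UTC instants to local study time (naive local clock).

    Day boundaries for every daily aggregate are drawn on this local clock:
    e.g. 2020-03-16 16:00 UTC is 2020-03-17 00:00 local at offset 8.
    """
    shifted = t_utc + pd.Timedelta(hours=offset_hours)
    if isinstance(shifted, pd.Timestamp):
        return shifted.tz_localize(None) if shifted.tzinfo is not None else shifted
    try:
        return shifted.dt.tz_localize(None)
    except (AttributeError, TypeError):
        if getattr(shifted, "tz", None) is not None:
            return shifted.tz_localize(None)
        return shifted


def read_ema(path: str | Path) -> pd.DataFrame:
    """Load the EMA response table.

    Expected columns: ``participant``, ``date`` (local calendar date),
    ``prompt`` (one of :data:`PROMPTS`) and the four mood items, each an
    integer 1–5 or blank.  Values outside 1–5 are set missing and logged.
    """
    df = pd.read_csv(path, dtype={"participant": str})
    required = ["participant", "date", "prompt", *EMA_ITEMS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    df["prompt"] = df["prompt"].astype(str)
    for item in EMA_ITEMS:
        vals = pd.to_numeric(df[item], errors="coerce")
        bad = vals.notna() & ~vals.isin([1, 2, 3, 4, 5])
        if bad.any():
            logger.debug("%s: %d out-of-range %s value(s) set missing", path, int(bad.sum()), item)
            vals[bad] = np.nan
        df[item] = vals.astype("Int64")
    return df[required]


def read_participants(path: str | Path) -> pd.DataFrame:
    """Load participant metadata: id, age (years), sex (1=male, 0=female),
    group (HC / BP / MDD)."""
    df = pd.read_csv(path, dtype={"participant": str})
    required = ["participant", "age", "sex", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    bad = ~df["group"].isin(["HC", "BP", "MDD"])
    if bad.any():
        raise ValueError(f"{path}: unknown group label(s): {sorted(df.loc[bad, 'group'].unique())}")
    return df[required]
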
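"""Reading and writing detection streams, receiver metadata and tag deployments.

All interchange is plain CSV (comma separated, header row, ISO-8601 timestamps).
Timestamps are stored internally as timezone-naive UTC ``pandas.Timestamp``;
input without an explicit zone is assumed to be UTC, zone-aware input is
converted to UTC and the zone dropped.

Canonical columns
-----------------
detections.csv   tag_id, receiver_id, timestamp
receivers.csv    receiver_id, array_id, x, y, rank, habitat
deployments.csv  tag_id, river, year, release_time, fork_length_mm, mass_g,
                 delay_min_s, delay_max_s
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

HABITATS = ("freshwater", "marine_inlet", "coastal")

DETECTION_COLUMNS = ["tag_id", "receiver_id", "timestamp"]
RECEIVER_COLUMNS = ["receiver_id", "array_id", "x", "y", "rank", "habitat"]
DEPLOYMENT_COLUMNS = [
    "tag_id", "river", "year", "release_time",
    "fork_length_mm", "mass_g", "delay_min_s", "delay_max_s",
]


@dataclass
class ReadReport:
    """Bookkeeping for one file read: rows seen, kept and rejected."""

    n_rows: int = 0
    n_rejected: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_rows - self.n_rejected


def _to_utc(series: pd.Series) -> pd.Series:
    """Parse timestamps, assuming UTC when no zone is given."""
    ts = pd.to_datetime(series, errors="coerce", utc=True, format="mixed")
    return ts.dt.tz_localize(None)


def read_detections(
    path,
    schema: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read a detection stream from CSV.

    Parameters
    ----------
    path
        CSV file with one row per detection.
    schema
        Optional mapping from canonical name (``tag_id``, ``receiver_id``,
        ``timestamp``) to the column name in the file.

    Returns
    -------
    (DataFrame, ReadReport)
        Detections sorted by (tag_id, timestamp, receiver_id) with ties broken
        by input order; rows with unparseable timestamps are dropped and
        counted in the report.
    """
    raw = pd.read_csv(path, dtype=str)
    schema = schema or {}
    rename = {schema.get(c, c): c for c in DETECTION_COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise ValueError(f"missing detection columns in {path}: {missing}")
    df = raw.rename(columns=rename)[DETECTION_COLUMNS].copy()

    report = ReadReport(n_rows=len(df))
    df["timestamp"] = _to_utc(df["timestamp"])
    bad = df["timestamp"].isna()
    report.n_rejected = int(bad.sum())
    if report.n_rejected:
        logger.warning("%s: rejected %d rows with unparseable timestamps",
                       path, report.n_rejected)
    df = df[~bad].copy()
    df["_order"] = range(len(df))
    df = df.sort_values(
        ["tag_id", "timestamp", "receiver_id", "_order"], kind="mergesort"
    ).drop(columns="_order").reset_index(drop=True)
    return df, report


def read_receivers(path) -> pd.DataFrame:
    """Read receiver metadata; validates rank uniqueness within each array.

    Rank is taken from the file, not recomputed from coordinates (arrays may
    bend, in which case numbering simply follows the curtain); a warning is
    logged where rank order disagrees with the y-ordinate order.
    """
    df = pd.read_csv(path)
    missing = [c for c in RECEIVER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing receiver columns in {path}: {missing}")
    df = df[RECEIVER_COLUMNS].copy()
    df["rank"] = df["rank"].astype(int)
    bad_hab = set(df["habitat"]) - set(HABITATS)
    if bad_hab:
        raise ValueError(f"unknown habitat labels: {sorted(bad_hab)}")
    for array_id, grp in df.groupby("array_id"):
        if grp["rank"].duplicated().any():
            raise ValueError(f"duplicate receiver ranks in array {array_id}")
        g = grp.sort_values("rank")
        if len(g) > 2 and not (g["y"].is_monotonic_increasing
                               or g["y"].is_monotonic_decreasing):
            logger.warning(
                "array %s: receiver rank order is not monotone in y "
                "(accepted as a stated override)", array_id)
    return df.reset_index(drop=True)


def read_deployments(path) -> pd.DataFrame:
    """Read tag-deployment metadata and validate basic invariants."""
    df = pd.read_csv(path)
    missing = [c for c in DEPLOYMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing deployment columns in {path}: {missing}")
    df = df[DEPLOYMENT_COLUMNS].copy()
    df["release_time"] = _to_utc(df["release_time"])
    if (df["fork_length_mm"] <= 0).any():
        raise ValueError("fork_length_mm must be positive")
    if (df["mass_g"] <= 0).any():
        raise ValueError("mass_g must be positive")
    if (df["delay_min_s"] >= df["delay_max_s"]).any():
        raise ValueError("delay_min_s must be below delay_max_s")
    if df["tag_id"].duplicated().any():
        raise ValueError("duplicate tag_id in deployments")
    df["tag_id"] = df["tag_id"].astype(str)
    return df.reset_index(drop=True)


def tag_burden(mass_g: float, tag_mass_g: float = 1.5) -> float:
    """Tag burden: tag weight as a percentage of fish body weight in air."""
    if mass_g <= 0:
        raise ValueError("fish mass must be positive")
    return 100.0 * tag_mass_g / mass_g


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as UTF-8 CSV; reading it back recovers canonical records."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, encoding="utf-8")
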
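"""False-detection filtering for coded acoustic tag data.

Three sequential rules reduce spurious detections before any analysis:

1. drop detections whose tag ID matches no deployed transmitter;
2. within each (tag, receiver) stream, drop a detection arriving less than
   ``min_gap`` seconds (default 15 s, below the minimum transmitter delay)
   after the last *retained* detection — greedy keep-first;
3. drop detections with no other same-tag same-receiver detection within
   ``singleton_window`` seconds either side (default 30 × the 35 s upper
   nominal delay = 1050 s = 17.5 min).

A :class:`CleaningAudit` reconciles every removed row. The subsequent
plausibility check against known smolt swimming speeds is advisory only
(:func:`speed_plausibility_report`); it never deletes data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

DEFAULT_MIN_GAP_S = 15.0
DEFAULT_DELAY_MAX_S = 35.0
SINGLETON_DELAY_MULTIPLE = 30


@dataclass
class CleaningConfig:
    min_gap: float = DEFAULT_MIN_GAP_S
    delay_max: float = DEFAULT_DELAY_MAX_S
    singleton_window: float | None = None  # derived as 30 x delay_max if None

    def __post_init__(self):
        if self.singleton_window is None:
            self.singleton_window = SINGLETON_DELAY_MULTIPLE * self.delay_max
        if self.min_gap <= 0:
            raise ValueError("min_gap must be positive")
        if self.singleton_window < self.min_gap:
            raise ValueError("singleton_window must be >= min_gap")


@dataclass
class CleaningAudit:
    n_input: int = 0
    n_unknown_tag: int = 0
    n_min_gap_removed: int = 0
    n_singleton_removed: int = 0

    @property
    def n_output(self) -> int:
        return (self.n_input - self.n_unknown_tag
                - self.n_min_gap_removed - self.n_singleton_removed)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["n_output"] = self.n_output
        return d


def filter_unknown_tags(
    detections: pd.DataFrame, deployments: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Keep only detections whose tag_id matches a deployed transmitter."""
    if len(deployments) == 0:
        raise ValueError("deployment table is empty")
    known = set(deployments["tag_id"].astype(str))
    mask = detections["tag_id"].astype(str).isin(known)
    return detections[mask].reset_index(drop=True), int((~mask).sum())


def _check_sorted(detections: pd.DataFrame) -> None:
    key = detections[["tag_id", "receiver_id"]].astype(str).agg("\x00".join, axis=1)
    if len(detections) > 1:
        same = key.values[1:] == key.values[:-1]
        dt = np.diff(detections["timestamp"].values)
        if (same & (dt < np.timedelta64(0, "ns"))).any():
            raise ValueError("detections must be sorted by (tag, receiver, time)")


def filter_min_gap(
    detections: pd.DataFrame, min_gap: float = DEFAULT_MIN_GAP_S
) -> tuple[pd.DataFrame, int]:
    """Greedy left-to-right minimum-gap filter within each (tag, receiver) stream.

    The first of a too-close pair is kept; a record is dropped when it falls
    strictly less than ``min_gap`` seconds after the last retained record of
    the same tag at the same receiver.
    """
    if len(detections) == 0:
        return detections.reset_index(drop=True), 0
    df = detections.sort_values(
        ["tag_id", "receiver_id", "timestamp"], kind="mergesort"
    )
    _check_sorted(df)
    keep = np.ones(len(df), dtype=bool)
    t = df["timestamp"].values.astype("datetime64[ns]").astype("int64") / 1e9
    stream = df["tag_id"].astype(str).values.astype(object) + "\x00" \
        + df["receiver_id"].astype(str).values.astype(object)
    last_kept = None
    last_stream = None
    for i in range(len(df)):
        if stream[i] != last_stream:
            last_stream = stream[i]
            last_kept = t[i]
            continue
        if t[i] - last_kept < min_gap:
            keep[i] = False
        else:
            last_kept = t[i]
    out = df[keep]
    # restore the caller's canonical (tag, time) ordering
    out = out.sort_values(["tag_id", "timestamp", "receiver_id"],
                          kind="mergesort").reset_index(drop=True)
    return out, int((~keep).sum())


def filter_singletons(
    detections: pd.DataFrame,
    singleton_window: float = SINGLETON_DELAY_MULTIPLE * DEFAULT_DELAY_MAX_S,
) -> tuple[pd.DataFrame, int]:
    """Drop detections with no same-tag same-receiver neighbour within the window.

    The neighbour test is two-sided and runs over the candidate stream this
    filter receives (i.e. after the minimum-gap rule), so two isolated pings
    within the window of each other keep each other.
    """
    if len(detections) == 0:
        return detections.reset_index(drop=True), 0
    df = detections.sort_values(
        ["tag_id", "receiver_id", "timestamp"], kind="mergesort"
    )
    t = df["timestamp"].values.astype("datetime64[ns]").astype("int64") / 1e9
    stream = df["tag_id"].astype(str).values.astype(object) + "\x00" \
        + df["receiver_id"].astype(str).values.astype(object)
    n = len(df)
    keep = np.zeros(n, dtype=bool)
    for i in range(n):
        if i > 0 and stream[i - 1] == stream[i] and t[i] - t[i - 1] <= singleton_window:
            keep[i] = True
        elif i < n - 1 and stream[i + 1] == stream[i] and t[i + 1] - t[i] <= singleton_window:
            keep[i] = True
    out = df[keep].sort_values(["tag_id", "timestamp", "receiver_id"],
                               kind="mergesort").reset_index(drop=True)
    return out, int((~keep).sum())


def clean(
    detections: pd.DataFrame,
    deployments: pd.DataFrame,
    config: CleaningConfig | None = None,
) -> tuple[pd.DataFrame, CleaningAudit]:
    """Apply the three filters in order: unknown-tag, minimum-gap, singleton."""
    config = config or CleaningConfig()
    audit = CleaningAudit(n_input=len(detections))
    out, audit.n_unknown_tag = filter_unknown_tags(detections, deployments)
    out, audit.n_min_gap_removed = filter_min_gap(out, config.min_gap)
    out, audit.n_singleton_removed = filter_singletons(out, config.singleton_window)
    return out, audit


def speed_plausibility_report(
    cleaned: pd.DataFrame,
    receivers: pd.DataFrame,
    distance_km,
    max_speed_kmh: float = 10.0,
) -> pd.DataFrame:
    """Advisory report of implied between-array speeds exceeding a ceiling.

    ``distance_km(array_a, array_b)`` supplies by-water distance between two
    arrays. Rows flag tag transitions whose implied speed exceeds
    ``max_speed_kmh``; nothing is deleted on the basis of this report.
    """
    df = cleaned.merge(receivers[["receiver_id", "array_id"]], on="receiver_id")
    firsts = (df.sort_values("timestamp")
                .groupby(["tag_id", "array_id"], as_index=False)
                .first())
    rows = []
    for tag, grp in firsts.groupby("tag_id"):
        g = grp.sort_values("timestamp")
        for (_, a), (_, b) in zip(g.iterrows(), g.iloc[1:].iterrows()):
            hours = (b["timestamp"] - a["timestamp"]).total_seconds() / 3600.0
            if hours <= 0:
                continue
            d = distance_km(a["array_id"], b["array_id"])
            speed = d / hours
            if speed > max_speed_kmh:
                rows.append({"tag_id": tag, "from_array": a["array_id"],
                             "to_array": b["array_id"], "distance_km": d,
                             "elapsed_h": hours, "speed_kmh": speed})
    return pd.DataFrame(
        rows, columns=["tag_id", "from_array", "to_array",
                       "distance_km", "elapsed_h", "speed_kmh"])
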
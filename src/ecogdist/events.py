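"""Biomarker event handling: rates per bipolar channel, montages, D_max.

Events (spikes, ripples, fast ripples) arrive as per-channel timestamp logs
from short intraoperative epochs (60 s by default).  This module normalizes
them to events/min, applies artifact-channel exclusion, builds the bipolar
montage from an electrode layout, summarizes rates per pathology with the
convention that means/SDs are computed over channels that recorded at least
one event, and finds each patient's maximal-rate channel (D_max).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ElectrodeArray, bipolar_midpoint

EVENT_TYPES = ("spike", "ripple", "fast_ripple")
RATE_COLUMNS = {t: f"{t}_rate" for t in EVENT_TYPES}
PATHOLOGIES = (
    "FCD",
    "ganglioglioma",
    "DNET",
    "low_grade_glioma",
    "PXA",
    "cavernoma",
)

CHANNEL_KEY = ["patient_id", "recording_id", "channel_id"]


@dataclass
class DmaxRecord:
    """Per patient and event type: the maximal rate and where it occurred."""

    patient_id: str
    event_type: str
    channel_id: str
    max_rate: float
    distance_mm: float


def build_montage(
    array: ElectrodeArray, direction: str = "row"
) -> list[tuple[str, int, int]]:
    """Ordered adjacent electrode pairs of a fully localized array.

    ``direction='row'`` pairs (r, c)-(r, c+1); ``'column'`` pairs
    (r, c)-(r+1, c).  Channel ids are deterministic,
    ``{array_id}:e{i}-e{j}`` with 1-based row-major electrode numbers.
    """
    if direction not in ("row", "column"):
        raise ValueError(f"invalid montage direction {direction!r}")
    if not array.known_mask().all():
        raise ValueError(
            f"array {array.array_id} is not fully localized; run grid "
            "extrapolation first"
        )
    pairs = []
    for r in range(array.n_rows):
        for c in range(array.n_cols):
            if direction == "row" and c + 1 < array.n_cols:
                a, b = array.index(r, c), array.index(r, c + 1)
            elif direction == "column" and r + 1 < array.n_rows:
                a, b = array.index(r, c), array.index(r + 1, c)
            else:
                continue
            cid = f"{array.array_id}:e{a + 1}-e{b + 1}"
            pairs.append((cid, a, b))
    return pairs


def montage_midpoints(
    array: ElectrodeArray, direction: str = "row"
) -> pd.DataFrame:
    """Bipolar channel table (channel_id, electrode indices, midpoint)."""
    rows = []
    for cid, a, b in build_montage(array, direction):
        mid = bipolar_midpoint(array.coordinates[a], array.coordinates[b])
        rows.append(
            {
                "channel_id": cid,
                "electrode_a": a,
                "electrode_b": b,
                "mid_x": mid[0],
                "mid_y": mid[1],
                "mid_z": mid[2],
            }
        )
    return pd.DataFrame(rows)


def compute_rates(
    events: pd.DataFrame,
    montage: pd.DataFrame,
    artifacts: pd.DataFrame | None = None,
    default_epoch_length_s: float = 60.0,
) -> pd.DataFrame:
    """Per-channel biomarker rates (events/min) from timestamp logs.

    Parameters
    ----------
    events : DataFrame
        Columns patient_id, recording_id, channel_id, event_type, time_s,
        epoch_length_s.  May be empty.
    montage : DataFrame
        One row per valid channel: patient_id, recording_id, channel_id.
        Channels without events get rate 0 for every type.
    artifacts : DataFrame, optional
        Channels to exclude (same key columns); they are dropped from the
        output entirely, so no rates propagate downstream.

    Notes
    -----
    rate = count / (epoch_length_s / 60) per channel and event type.  An
    event on a channel absent from the montage, a negative timestamp, a
    timestamp at/past the epoch end, or an unknown event type raises.
    """
    mont = montage[CHANNEL_KEY].drop_duplicates().copy()
    out = mont.copy()
    if len(events):
        bad_type = set(events["event_type"]) - set(EVENT_TYPES)
        if bad_type:
            raise ValueError(f"unknown event types {sorted(bad_type)}")
        if (events["time_s"] < 0).any():
            raise ValueError("negative event time")
        if (events["time_s"] >= events["epoch_length_s"]).any():
            raise ValueError("event time at or beyond the epoch end")
        if (events["epoch_length_s"] <= 0).any():
            raise ValueError("epoch length must be positive")
        merged = events.merge(mont, on=CHANNEL_KEY, how="left", indicator=True)
        unknown = merged[merged["_merge"] == "left_only"]
        if len(unknown):
            key = unknown.iloc[0][CHANNEL_KEY].tolist()
            raise ValueError(f"event on unknown channel {key}")

        counts = (
            events.groupby(CHANNEL_KEY + ["event_type"])
            .agg(n=("time_s", "size"), epoch_s=("epoch_length_s", "first"))
            .reset_index()
        )
        counts["rate"] = counts["n"] / (counts["epoch_s"] / 60.0)
        wide = counts.pivot_table(
            index=CHANNEL_KEY, columns="event_type", values="rate", fill_value=0.0
        ).reset_index()
        out = out.merge(wide, on=CHANNEL_KEY, how="left")
    for t in EVENT_TYPES:
        col = RATE_COLUMNS[t]
        if t in out.columns:
            out[col] = out[t].fillna(0.0)
            out = out.drop(columns=[t])
        else:
            out[col] = 0.0
    if artifacts is not None and len(artifacts):
        art = artifacts[CHANNEL_KEY].drop_duplicates()
        out = out.merge(art, on=CHANNEL_KEY, how="left", indicator=True)
        out = out[out["_merge"] == "left_only"].drop(columns=["_merge"])
    return out.reset_index(drop=True)


def summarize_rates(records: pd.DataFrame, by: str = "pathology") -> pd.DataFrame:
    """Per-group biomarker summary mirroring the descriptive-table layout.

    For each group (plus an ``all`` row): number of channels, total events,
    and mean/SD of rates restricted to channels with rate > 0 for that
    biomarker.  Groups where a biomarker never occurred get total 0 and
    NaN mean/SD (the table's em-dash convention).
    """
    if not len(records):
        raise ValueError("no channel records to summarize")

    def one(group: pd.DataFrame, label: str) -> dict:
        row: dict = {by: label, "n_channels": len(group)}
        for t in EVENT_TYPES:
            rates = group[RATE_COLUMNS[t]].to_numpy(float)
            epochs_min = group["epoch_minutes"].to_numpy(float) if "epoch_minutes" in group else np.ones(len(group))
            row[f"total_{t}s"] = float(np.round(np.sum(rates * epochs_min)))
            nz = rates[rates > 0]
            row[f"mean_{t}_rate"] = float(nz.mean()) if len(nz) else np.nan
            row[f"sd_{t}_rate"] = (
                float(nz.std(ddof=1)) if len(nz) > 1 else (0.0 if len(nz) else np.nan)
            )
        return row

    rows = [one(records, "all")]
    for label, g in records.groupby(by, sort=True):
        rows.append(one(g, label))
    return pd.DataFrame(rows)


def dmax(records: pd.DataFrame, distance_col: str = "d_edge_mm") -> pd.DataFrame:
    """Per patient and event type: the channel with the highest rate.

    Only event types with at least one event for that patient produce a
    record.  Ties are broken by the lexicographically lowest channel_id.
    Raises if a patient has no included channels at all.
    """
    if not len(records):
        raise ValueError("no included channels")
    rows = []
    for pid, g in records.groupby("patient_id", sort=True):
        if not len(g):
            raise ValueError(f"patient {pid} has no included channels")
        for t in EVENT_TYPES:
            col = RATE_COLUMNS[t]
            rates = g[col].to_numpy(float)
            if rates.max() <= 0:
                continue
            best = g[rates == rates.max()].sort_values("channel_id").iloc[0]
            rows.append(
                {
                    "patient_id": pid,
                    "event_type": t,
                    "channel_id": best["channel_id"],
                    "max_rate": float(best[col]),
                    "distance_mm": float(best[distance_col]),
                }
            )
    return pd.DataFrame(
        rows, columns=["patient_id", "event_type", "channel_id", "max_rate", "distance_mm"]
    )
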
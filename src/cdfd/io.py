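"""CSV/JSON/YAML readers and writers for pipeline inputs and outputs."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import EVENT_COLUMNS, SpikeTrain
from .errors import DataFormatError

__all__ = [
    "read_spikes",
    "write_spikes",
    "read_events",
    "write_events",
    "read_freezing",
    "read_startle",
    "write_truth",
    "read_truth",
]

SPIKE_COLUMNS = ("unit_id", "timestamp_s")


def read_spikes(path: str | Path) -> dict[str, SpikeTrain]:
    """Read a `unit_id,timestamp_s` CSV into per-unit sorted trains.

    Duplicate timestamps within a unit are dropped with a warning;
    unsorted input is sorted with a warning. Malformed rows raise with
    the offending line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"unit_id": str})
    except Exception as exc:  # header/parse failures
        raise DataFormatError(f"{path}: cannot parse spikes CSV: {exc}") from exc
    missing = set(SPIKE_COLUMNS) - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    ts = pd.to_numeric(df["timestamp_s"], errors="coerce")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        raise DataFormatError(f"{path}: non-numeric timestamp at line {bad[0] + 2}")
    df = df.assign(timestamp_s=ts)
    trains: dict[str, SpikeTrain] = {}
    for uid, grp in df.groupby("unit_id", sort=True):
        t = grp["timestamp_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            warnings.warn(f"{path}: unit {uid} timestamps unsorted; sorting")
            t = np.sort(t)
        tu = np.unique(t)
        if tu.size != t.size:
            warnings.warn(f"{path}: unit {uid} has {t.size - tu.size} duplicate timestamps; deduplicated")
        trains[str(uid)] = SpikeTrain(str(uid), tu)
    return trains


def write_spikes(trains: dict[str, SpikeTrain], path: str | Path) -> None:
    rows = [
        {"unit_id": uid, "timestamp_s": f"{t:.6f}"}
        for uid in sorted(trains)
        for t in trains[uid].times
    ]
    pd.DataFrame(rows, columns=list(SPIKE_COLUMNS)).to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"session_id": str, "context": str})
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("cs_onset_s", "cs_offset_s"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 2
            raise DataFormatError(f"{path}: non-numeric {col} at line {line}")
        df[col] = vals
    if "us_onset_s" not in df.columns:
        df["us_onset_s"] = np.nan
    if (df["cs_offset_s"] <= df["cs_onset_s"]).any():
        raise DataFormatError(f"{path}: cs_offset_s must exceed cs_onset_s")
    return df


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    cols = list(EVENT_COLUMNS) + ["us_onset_s"]
    events.to_csv(path, index=False, columns=[c for c in cols if c in events.columns])


def read_freezing(path: str | Path) -> pd.DataFrame:
    """`subject_id,start_s,end_s` immobility intervals."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = {"subject_id", "start_s", "end_s"} - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    if (df["end_s"] <= df["start_s"]).any():
        raise DataFormatError(f"{path}: freezing intervals need start_s < end_s")
    return df


def read_startle(path: str | Path) -> pd.DataFrame:
    """`trial_type,amplitude` startle-trial table."""
    df = pd.read_csv(path, dtype={"trial_type": str})
    missing = {"trial_type", "amplitude"} - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
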
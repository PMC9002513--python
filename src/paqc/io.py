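"""Record model, delimited-file IO, channel pairing and indoor/outdoor matching.

A monitor stream is held as a :class:`MonitorSeries`: a time-sorted pandas
DataFrame of per-record readings for both duplicate channels plus monitor
metadata.  The canonical on-disk form is a plain CSV with header

    timestamp, monitor_id, channel, location,
    n_gt_0p3_dl, n_gt_0p5_dl, n_gt_1p0_dl, n_gt_2p5_dl, pm25_cf1, pm25_atm

with ISO-8601 UTC timestamps; ``n_gt_*`` columns are the vendor's cumulative
particle counts per deciliter above each diameter threshold.  Two real-world
PurpleAir column vocabularies are also understood: the SD-card export
(">=0.3um/dl"-style, wide a/b columns) and the API export ("0.3_um_count"
style); a ``column_map`` argument rescues other variants.

Rows violating the physical invariants (negative or increasing cumulative
counts, unparseable timestamps) are dropped and tallied in a
:class:`ReadReport` rather than failing the whole file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "COUNT_COLUMNS",
    "SensorRecord",
    "MonitorSeries",
    "ReadReport",
    "PairingReport",
    "read_purpleair_csv",
    "write_records_csv",
    "build_paired",
    "pair_channels",
    "match_locations",
]

COUNT_COLUMNS = ["n_gt_0p3_dl", "n_gt_0p5_dl", "n_gt_1p0_dl", "n_gt_2p5_dl"]
CANONICAL_COLUMNS = ["timestamp", "monitor_id", "channel", "location", *COUNT_COLUMNS, "pm25_cf1", "pm25_atm"]

# column vocabularies of the two common PurpleAir export formats; values are
# canonical names, with "" / "_b" suffixes marking the a / b channel in the
# wide (one-row-per-timestamp) layouts.
_SDCARD_MAP = {
    "UTCDateTime": "timestamp",
    "mac_address": "monitor_id",
    ">=0.3um/dl": "n_gt_0p3_dl",
    ">=0.5um/dl": "n_gt_0p5_dl",
    ">=1.0um/dl": "n_gt_1p0_dl",
    ">=2.5um/dl": "n_gt_2p5_dl",
    "pm2.5_cf_1": "pm25_cf1",
    "pm2.5_atm": "pm25_atm",
}
_API_MAP = {
    "time_stamp": "timestamp",
    "sensor_index": "monitor_id",
    "0.3_um_count": "n_gt_0p3_dl",
    "0.5_um_count": "n_gt_0p5_dl",
    "1.0_um_count": "n_gt_1p0_dl",
    "2.5_um_count": "n_gt_2p5_dl",
    "pm2.5_cf_1": "pm25_cf1",
    "pm2.5_atm": "pm25_atm",
}


@dataclass(frozen=True)
class SensorRecord:
    """One timestamped reading of one channel of one monitor."""

    timestamp: pd.Timestamp
    monitor_id: str
    channel: str  # "a" | "b"
    location: str  # "indoor" | "outdoor"
    counts_gt: tuple[float, float, float, float]
    pm25_cf1: float | None = None
    pm25_atm: float | None = None

    def __post_init__(self) -> None:
        if self.channel not in ("a", "b"):
            raise ValueError("channel must be 'a' or 'b'")
        c = self.counts_gt
        if len(c) != 4 or any((not np.isfinite(v)) or v < 0 for v in c):
            raise ValueError("counts_gt must be four finite values >= 0")
        if any(x < y for x, y in zip(c, c[1:])):
            raise ValueError("cumulative counts must be non-increasing")
        for v in (self.pm25_cf1, self.pm25_atm):
            if v is not None and v < 0:
                raise ValueError("vendor PM fields must be >= 0 when present")


@dataclass
class ReadReport:
    """Row accounting for one file read."""

    path: str
    n_rows: int = 0
    n_kept: int = 0
    n_dropped_bad_timestamp: int = 0
    n_dropped_negative: int = 0
    n_dropped_monotonicity: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class MonitorSeries:
    """Both channels of one monitor, time-sorted.

    ``frame`` has the canonical columns; rows are sorted by timestamp (then
    channel, for reproducible ordering of simultaneous a/b readings).
    """

    monitor_id: str
    location: str
    frame: pd.DataFrame
    cadence_seconds: float = 120.0
    read_report: ReadReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in CANONICAL_COLUMNS if c not in f.columns]
        if missing:
            raise ValueError(f"frame missing canonical columns: {missing}")
        if len(f) and not f["timestamp"].is_monotonic_increasing:
            raise ValueError("records must be sorted by timestamp")
        if len(f) and (f["monitor_id"] != self.monitor_id).any():
            raise ValueError("all records must share the series monitor_id")

    def __len__(self) -> int:
        return len(self.frame)

    def channel(self, which: str) -> pd.DataFrame:
        return self.frame[self.frame["channel"] == which].reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, monitor_id: str, location: str,
                   cadence_seconds: float = 120.0, read_report: ReadReport | None = None) -> "MonitorSeries":
        frame = frame.sort_values(["timestamp", "channel"], kind="stable").reset_index(drop=True)
        return cls(monitor_id=monitor_id, location=location, frame=frame,
                   cadence_seconds=cadence_seconds, read_report=read_report)


def _finalize_long(df: pd.DataFrame, path: Path, monitor_id: str | None,
                   location: str | None, report: ReadReport) -> pd.DataFrame:
    """Validate a long-format canonical frame, dropping rows that violate invariants."""
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    bad_ts = ts.isna()
    report.n_dropped_bad_timestamp = int(bad_ts.sum())
    df = df.loc[~bad_ts].copy()
    df["timestamp"] = ts[~bad_ts]

    counts = df[COUNT_COLUMNS].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    negative = np.any(~np.isfinite(counts) | (counts < 0), axis=1)
    increasing = np.any(np.diff(counts, axis=1) > 0, axis=1) & ~negative
    report.n_dropped_negative = int(negative.sum())
    report.n_dropped_monotonicity = int(increasing.sum())
    df = df.loc[~(negative | increasing)].copy()

    for col in ("pm25_cf1", "pm25_atm"):
        df[col] = pd.to_numeric(df[col], errors="coerce") if col in df else np.nan
    if monitor_id is not None:
        df["monitor_id"] = monitor_id
    elif "monitor_id" not in df:
        df["monitor_id"] = path.stem
    df["monitor_id"] = df["monitor_id"].astype(str)
    if location is not None:
        df["location"] = location
    elif "location" not in df:
        df["location"] = "indoor"
    report.n_kept = len(df)
    return df[CANONICAL_COLUMNS]


def _wide_to_long(df: pd.DataFrame, name_map: dict[str, str]) -> pd.DataFrame:
    """Split a wide vendor export (a columns bare, b columns suffixed _b) into long form."""
    frames = []
    for suffix, channel in (("", "a"), ("_b", "b")):
        cols = {}
        for src, dst in name_map.items():
            candidate = src + suffix if dst not in ("timestamp", "monitor_id") else src
            if candidate in df.columns:
                cols[candidate] = dst
        present = set(cols.values())
        if not {"timestamp", *COUNT_COLUMNS} <= present:
            if suffix == "":
                missing = sorted({"timestamp", *COUNT_COLUMNS} - present)
                raise ValueError(f"no recognizable columns for channel a; missing {missing}")
            continue  # single-channel file: no b columns
        sub = df[list(cols)].rename(columns=cols).copy()
        sub["channel"] = channel
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def read_purpleair_csv(
    path,
    dialect: str = "simple",
    column_map: dict[str, str] | None = None,
    monitor_id: str | None = None,
    location: str | None = None,
    cadence_seconds: float = 120.0,
) -> MonitorSeries:
    """Read one monitor's delimited export into a :class:`MonitorSeries`.

    ``dialect`` is ``"simple"`` (the canonical long header written by
    :func:`write_records_csv`), ``"sdcard"`` or ``"api"`` (wide vendor
    vocabularies, a/b channels in suffixed columns).  ``column_map`` maps
    *file* column names to canonical names and is applied before dialect
    handling, rescuing nonstandard variants.  Invalid rows are dropped and
    tallied in ``series.read_report``.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path} has no header row") from None
    if column_map:
        raw = raw.rename(columns=column_map)
    report = ReadReport(path=str(path), n_rows=len(raw))

    if dialect == "simple":
        missing = [c for c in ("timestamp", "channel", *COUNT_COLUMNS) if c not in raw.columns]
        if missing:
            raise ValueError(f"{path}: missing canonical columns {missing}")
        long_df = raw
    elif dialect in ("sdcard", "api"):
        name_map = _SDCARD_MAP if dialect == "sdcard" else _API_MAP
        already = {c: c for c in CANONICAL_COLUMNS if c in raw.columns}
        long_df = _wide_to_long(raw, {**name_map, **already})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    df = _finalize_long(long_df, path, monitor_id, location, report)
    if monitor_id is None:
        ids = df["monitor_id"].unique()
        monitor_id = str(ids[0]) if len(ids) else path.stem
        df = df[df["monitor_id"] == monitor_id]
    loc = location if location is not None else (df["location"].iloc[0] if len(df) else "indoor")
    return MonitorSeries.from_frame(df, monitor_id=monitor_id, location=loc,
                                    cadence_seconds=cadence_seconds, read_report=report)


def write_records_csv(series: MonitorSeries, path) -> None:
    """Write the canonical CSV; ``read_purpleair_csv(dialect="simple")`` inverts it."""
    path = Path(path)
    df = series.frame.copy()
    ts = pd.to_datetime(df["timestamp"], utc=True)
    df["timestamp"] = ts.dt.strftime("%Y-%m-%dT%H:%M:%S%z").str.replace(r"\+0000$", "+00:00", regex=True)
    try:
        df[CANONICAL_COLUMNS].to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


@dataclass
class PairingReport:
    """Accounting for nearest-neighbour matching of two record streams."""

    n_left: int
    n_right: int
    n_pairs: int

    @property
    def n_unmatched_left(self) -> int:
        return self.n_left - self.n_pairs

    @property
    def n_unmatched_right(self) -> int:
        return self.n_right - self.n_pairs

    def to_json(self) -> str:
        d = asdict(self)
        d["n_unmatched_left"] = self.n_unmatched_left
        d["n_unmatched_right"] = self.n_unmatched_right
        return json.dumps(d, indent=2)


def _nearest_one_to_one(t_left: np.ndarray, t_right: np.ndarray, tolerance: float) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest matching of two sorted time axes.

    Candidate edges are each left point's nearest right neighbours (the one
    at or before, and the one after); edges are taken in order of increasing
    time difference, each endpoint used at most once.  Exact for the regular
    grids produced by monitors; documented greedy policy otherwise.
    """
    if t_left.size == 0 or t_right.size == 0:
        return []
    if t_left.size == t_right.size and np.array_equal(t_left, t_right):
        return list(zip(range(t_left.size), range(t_right.size)))  # identical grids
    pos = np.searchsorted(t_right, t_left)
    edges = []
    for i, p in enumerate(pos):
        for j in (p - 1, p):
            if 0 <= j < t_right.size:
                dt = abs(t_left[i] - t_right[j])
                if dt <= tolerance:
                    edges.append((dt, i, j))
    edges.sort()
    used_l: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for _, i, j in edges:
        if i not in used_l and j not in used_r:
            used_l.add(i)
            used_r.add(j)
            pairs.append((i, j))
    pairs.sort()
    return pairs


def build_paired(
    timestamps_a,
    values_a,
    timestamps_b,
    values_b,
    tolerance_seconds: float = 60.0,
    algorithm: str = "ALT_CF3",
) -> tuple[pd.DataFrame, PairingReport]:
    """Match two channel streams and compute pair statistics.

    Returns a paired-observation frame with columns ``timestamp, a_value,
    b_value, mu, sigma, precision, algorithm`` where µ = (a+b)/2,
    σ = |a−b|/√2 and precision = |a−b|/(a+b) (NaN when a+b = 0), plus a
    :class:`PairingReport`.  The pair timestamp is the a-channel's.
    """
    if tolerance_seconds < 0:
        raise ValueError("tolerance_seconds must be >= 0")
    ts_a = pd.to_datetime(pd.Series(timestamps_a), utc=True)
    ts_b = pd.to_datetime(pd.Series(timestamps_b), utc=True)
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    t_a = ts_a.astype("int64").to_numpy() / 1e9
    t_b = ts_b.astype("int64").to_numpy() / 1e9
    pairs = _nearest_one_to_one(t_a, t_b, tolerance_seconds)
    report = PairingReport(n_left=t_a.size, n_right=t_b.size, n_pairs=len(pairs))
    if pairs:
        ia, ib = map(np.asarray, zip(*pairs))
    else:
        ia = ib = np.array([], dtype=int)
    a = va[ia]
    b = vb[ib]
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(total > 0, np.abs(a - b) / total, np.nan)
    df = pd.DataFrame(
        {
            "timestamp": ts_a.iloc[ia].to_numpy() if len(pairs) else pd.DatetimeIndex([], tz="UTC"),
            "a_value": a,
            "b_value": b,
            "mu": (a + b) / 2.0,
            "sigma": np.abs(a - b) / np.sqrt(2.0),
            "precision": precision,
            "algorithm": algorithm,
        }
    )
    return df, report


def pair_channels(
    series: MonitorSeries,
    values,
    tolerance_seconds: float = 60.0,
    algorithm: str = "ALT_CF3",
) -> tuple[pd.DataFrame, PairingReport]:
    """Pair the a and b channels of one monitor on nearest timestamps.

    ``values`` is a per-record PM2.5 array aligned with ``series.frame``
    rows (e.g. the output of :class:`~paqc.algorithms.AltMassConverter` or a
    vendor PM column).  The default tolerance is half the nominal 2-min
    cadence.  Each record is used in at most one pair; unmatched records are
    tallied in the report.
    """
    frame = series.frame
    vals = np.asarray(values, dtype=float)
    if vals.size != len(frame):
        raise ValueError("values must align with series records")
    is_a = (frame["channel"] == "a").to_numpy()
    return build_paired(
        frame.loc[is_a, "timestamp"],
        vals[is_a],
        frame.loc[~is_a, "timestamp"],
        vals[~is_a],
        tolerance_seconds=tolerance_seconds,
        algorithm=algorithm,
    )


def match_locations(
    indoor: pd.DataFrame,
    outdoor: pd.DataFrame,
    tolerance_seconds: float = 60.0,
) -> pd.DataFrame:
    """Nearest-neighbour one-to-one match of indoor and outdoor paired series.

    Inputs are paired-observation frames (time-sorted); the matched values
    are the pair means µ of each monitor.  Returns columns
    ``timestamp, indoor_value, outdoor_value``.
    """
    ts_i = pd.to_datetime(indoor["timestamp"], utc=True)
    ts_o = pd.to_datetime(outdoor["timestamp"], utc=True)
    t_i = ts_i.astype("int64").to_numpy() / 1e9
    t_o = ts_o.astype("int64").to_numpy() / 1e9
    pairs = _nearest_one_to_one(t_i, t_o, tolerance_seconds)
    if pairs:
        ii, io = map(np.asarray, zip(*pairs))
    else:
        ii = io = np.array([], dtype=int)
    return pd.DataFrame(
        {
            "timestamp": ts_i.iloc[ii].to_numpy() if pairs else pd.DatetimeIndex([], tz="UTC"),
            "indoor_value": indoor["mu"].to_numpy(dtype=float)[ii],
            "outdoor_value": outdoor["mu"].to_numpy(dtype=float)[io],
        }
    )
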
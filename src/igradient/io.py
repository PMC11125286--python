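"""Plain-text readers and writers for epoch series, raw signals and wear logs.

Native dialect: comma-separated files with ``#``-prefixed metadata header
lines followed by a column header row and ISO-8601 timestamps.  An
ActiLife-style mode is also provided for epoch counts: a block of free-form
header lines (containing ``Start Time`` and ``Start Date``) terminated by a
dashed sentinel line, then one count per row.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EpochSeries, RawSignal, WearLog

__all__ = [
    "read_epoch_csv",
    "write_epoch_csv",
    "read_actilife_csv",
    "read_raw_csv",
    "write_raw_csv",
    "read_wear_log",
    "write_wear_log",
]

_SENTINEL = "----------"


def _parse_meta(path: Path) -> tuple[dict, int]:
    meta: dict[str, str] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta, n


def read_epoch_csv(path, epoch_length: float | None = None) -> EpochSeries:
    """Read an epoch series from the native two-column dialect.

    Columns: ``timestamp,value`` with an optional third ``wear`` column
    (0/1).  Metadata lines (``# key: value``) may set ``participant_id``,
    ``device_id``, ``epoch_length`` and ``units``; an explicit
    ``epoch_length`` argument overrides the file.
    """
    path = Path(path)
    meta, nskip = _parse_meta(path)
    df = pd.read_csv(path, skiprows=nskip)
    if "timestamp" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path}: expected 'timestamp' and 'value' columns")
    try:
        times = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed timestamp ({exc})") from exc
    vals = pd.to_numeric(df["value"], errors="coerce")
    if vals.isna().any():
        row = int(vals.index[vals.isna()][0])
        raise ValueError(f"{path}: missing or non-numeric value at row {row}")
    if (vals < 0).any():
        row = int(vals.index[vals < 0][0])
        raise ValueError(f"{path}: negative value at row {row}")

    length = float(epoch_length or meta.get("epoch_length", 15))
    if len(times) > 1:
        steps = np.diff(times.values).astype("timedelta64[ns]").astype(float) / 1e9
        if not np.allclose(steps, length):
            raise ValueError(
                f"{path}: timestamps are not contiguous {length:g} s epochs; "
                "missing epochs inside a recording are not imputed"
            )
    wear = df["wear"].astype(bool).to_numpy() if "wear" in df.columns else None
    return EpochSeries(
        participant_id=meta.get("participant_id", path.stem),
        device_id=meta.get("device_id", "unknown"),
        start_time=times.iloc[0],
        values=vals.to_numpy(),
        epoch_length=length,
        wear=wear,
        units=meta.get("units", "counts"),
    )


def write_epoch_csv(series: EpochSeries, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# participant_id: {series.participant_id}\n")
        fh.write(f"# device_id: {series.device_id}\n")
        fh.write(f"# epoch_length: {series.epoch_length:g}\n")
        fh.write(f"# units: {series.units}\n")
        fh.write("timestamp,value,wear\n")
        for t, v, w in zip(series.epoch_times, series.values, series.wear):
            fh.write(f"{t.isoformat()},{v:g},{int(w)}\n")


def read_actilife_csv(path, epoch_length: float = 15.0) -> EpochSeries:
    """Read a single-column epoch-count export with an ActiLife-like header.

    Header lines are skipped until a line of ten or more dashes; ``Start
    Time`` and ``Start Date`` lines inside the header set the series start.
    """
    path = Path(path)
    start_time = start_date = None
    lines = path.read_text().splitlines()
    body_at = None
    for i, line in enumerate(lines):
        if line.strip().startswith(_SENTINEL):
            body_at = i + 1
            break
        if "Start Time" in line:
            start_time = line.split("Start Time")[-1].strip(" ,:\t")
        if "Start Date" in line:
            start_date = line.split("Start Date")[-1].strip(" ,:\t")
    if body_at is None:
        raise ValueError(f"{path}: no dashed header sentinel found")
    if start_time is None or start_date is None:
        raise ValueError(f"{path}: header lacks Start Date / Start Time")
    start = pd.to_datetime(f"{start_date} {start_time}", dayfirst=False)
    vals = []
    for row, line in enumerate(lines[body_at:]):
        if not line.strip():
            continue
        v = float(line.split(",")[0])
        if v < 0:
            raise ValueError(f"{path}: negative count at row {row}")
        vals.append(v)
    return EpochSeries(
        participant_id=path.stem,
        device_id="actilife",
        start_time=start,
        values=np.asarray(vals),
        epoch_length=epoch_length,
    )


def read_raw_csv(path) -> RawSignal:
    """Read a triaxial raw signal: columns ``ax,ay,az`` in g, metadata
    ``sample_rate`` (Hz) and ``start_time`` in ``#`` header lines."""
    path = Path(path)
    meta, nskip = _parse_meta(path)
    df = pd.read_csv(path, skiprows=nskip)
    for col in ("ax", "ay", "az"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected column {col!r}")
    return RawSignal(
        participant_id=meta.get("participant_id", path.stem),
        device_id=meta.get("device_id", "unknown"),
        start_time=pd.Timestamp(meta.get("start_time", "2000-01-01T00:00:00")),
        ax=df["ax"].to_numpy(),
        ay=df["ay"].to_numpy(),
        az=df["az"].to_numpy(),
        sample_rate=float(meta.get("sample_rate", 30)),
    )


def write_raw_csv(signal: RawSignal, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# participant_id: {signal.participant_id}\n")
        fh.write(f"# device_id: {signal.device_id}\n")
        fh.write(f"# start_time: {signal.start_time.isoformat()}\n")
        fh.write(f"# sample_rate: {signal.sample_rate:g}\n")
        fh.write("ax,ay,az\n")
        np.savetxt(fh, np.column_stack([signal.ax, signal.ay, signal.az]),
                   delimiter=",", fmt="%.6f")


def read_wear_log(path, participant_id: str | None = None) -> WearLog | dict[str, WearLog]:
    """Read wear intervals from ``participant_id,on,off`` rows.

    Returns a single :class:`WearLog` when ``participant_id`` is given,
    otherwise a dict keyed by participant.
    """
    df = pd.read_csv(path, comment="#")
    for col in ("participant_id", "on", "off"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected column {col!r}")
    logs: dict[str, WearLog] = {}
    for pid, grp in df.groupby("participant_id"):
        ivs = [(pd.Timestamp(a), pd.Timestamp(b)) for a, b in zip(grp["on"], grp["off"])]
        logs[str(pid)] = WearLog(str(pid), ivs)
    if participant_id is not None:
        if participant_id not in logs:
            raise ValueError(f"{path}: no wear intervals for {participant_id!r}")
        return logs[participant_id]
    return logs


def write_wear_log(logs, path) -> None:
    """Write one or many wear logs as ``participant_id,on,off`` rows."""
    if isinstance(logs, WearLog):
        logs = [logs]
    elif isinstance(logs, dict):
        logs = list(logs.values())
    with open(Path(path), "w") as fh:
        fh.write("participant_id,on,off\n")
        for log in logs:
            for on, off in log.intervals:
                fh.write(f"{log.participant_id},{on.isoformat()},{off.isoformat()}\n")
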
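"""Reading and writing of FCS event data and assembly of measurement series.

Flow cytometers such as the BD Accuri C6 Plus store one FCS file per
measurement point: a matrix of per-event scatter/fluorescence intensities
plus a keyword TEXT segment carrying acquisition metadata.  This module
provides a compact FCS 3.0/3.1 reader and an FCS 3.1 writer (list-mode,
32-bit float), plus :class:`EventTable` — the in-memory container every
other stage of the pipeline operates on — and :func:`load_series` to turn
a set of files into a time-ordered :class:`MeasurementSeries`.

Acquisition volume and dilution factor are treated as per-sample *data*:
when a file does not carry them they fall back to the online-monitoring
defaults (61 µL analyzed volume, 1:100 dilution) with a logged warning.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: analyzed volume per online measurement (90 s on the Accuri ~ 61 µL)
DEFAULT_VOLUME_UL = 61.0
#: online samples are diluted 1:100 with filtered water before staining
DEFAULT_DILUTION = 100.0

CANONICAL_CHANNELS = ("FSC-A", "SSC-A", "FL1-A", "FL3-A")


class FCSParseError(ValueError):
    """Raised when an FCS file is structurally malformed."""


class ChannelError(KeyError):
    """Raised when a required channel is absent from an event table."""


@dataclass
class EventTable:
    """Per-sample matrix of events x channels with acquisition metadata.

    ``events`` holds linear-scale instrument intensities unless
    ``log_transformed`` is set (see :func:`cytomon.gating.transform_events`).
    """

    events: np.ndarray
    channel_names: list[str]
    acquired_volume_uL: float = DEFAULT_VOLUME_UL
    dilution_factor: float = DEFAULT_DILUTION
    timestamp: _dt.datetime | None = None
    sample_id: str = ""
    log_transformed: bool = False
    extra_keywords: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.float64)
        if self.events.ndim == 1 and self.events.size == 0:
            self.events = self.events.reshape(0, len(self.channel_names))
        if self.events.ndim != 2:
            raise ValueError("events must be a 2-D array (N_events x N_channels)")
        if self.events.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.events.shape[1]} event columns but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.events.size and not np.all(np.isfinite(self.events)):
            raise ValueError("event intensities must be finite")
        if not self.acquired_volume_uL > 0:
            raise ValueError("acquired_volume_uL must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ChannelError(
                f"channel {name!r} not present; available: {self.channel_names}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Column of intensities for one channel."""
        return self.events[:, self.channel_index(name)]

    def with_events(self, events: np.ndarray, **changes) -> "EventTable":
        """Copy of the table with a replaced event matrix (metadata kept)."""
        return replace(self, events=events, **changes)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.events, columns=self.channel_names)


@dataclass
class MeasurementSeries:
    """Time-ordered sequence of :class:`EventTable` from one experiment."""

    samples: list[EventTable]
    t0: _dt.datetime
    sampling_interval_min: float = 25.0

    def __post_init__(self) -> None:
        stamps = [s.timestamp for s in self.samples]
        if any(t is None for t in stamps):
            raise ValueError("all samples must carry a timestamp")
        diffs = np.diff([t.timestamp() for t in stamps])
        if len(diffs) and not np.all(diffs > 0):
            raise ValueError("sample timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def elapsed_hours(self) -> np.ndarray:
        """Hours since inoculation (t0) for each sample."""
        return np.array(
            [(s.timestamp - self.t0).total_seconds() / 3600.0 for s in self.samples]
        )


# ---------------------------------------------------------------------------
# FCS binary format
# ---------------------------------------------------------------------------

_HEADER_LEN = 58  # 6-byte version + 4 spaces + six 8-char offsets


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSParseError("TEXT segment is empty")
    text = raw.decode("latin-1")
    delim = text[0]
    body = text[1:]
    if body.endswith(delim):
        body = body[:-1]
    # doubled delimiters escape a literal delimiter inside a value; rare in
    # practice for the keywords we consume, so split then re-join empties
    parts = body.split(delim)
    merged: list[str] = []
    i = 0
    while i < len(parts):
        part = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            part += delim + parts[i + 2]
            i += 2
        merged.append(part)
        i += 1
    if len(merged) % 2:
        merged = merged[:-1]
    return {
        merged[j].strip().upper(): merged[j + 1]
        for j in range(0, len(merged), 2)
        if merged[j].strip()
    }


def _decode_events(data: bytes, keywords: dict[str, str]) -> np.ndarray:
    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    datatype = keywords.get("$DATATYPE", "F").strip().upper()
    byteord = keywords.get("$BYTEORD", "1,2,3,4").replace(" ", "")
    endian = "<" if byteord.startswith("1") else ">"
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        bits = {int(keywords.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
        if len(bits) != 1 or next(iter(bits)) not in (8, 16, 32):
            raise FCSParseError(
                "DATA segment: only uniform 8/16/32-bit integer data supported"
            )
        dtype = np.dtype(f"{endian}u{next(iter(bits)) // 8}")
    else:
        raise FCSParseError(f"DATA segment: unsupported $DATATYPE {datatype!r}")
    expected = n_par * n_tot * dtype.itemsize
    if len(data) < expected:
        raise FCSParseError(
            f"DATA segment: expected {expected} bytes for "
            f"{n_tot} events x {n_par} channels, found {len(data)}"
        )
    arr = np.frombuffer(data[:expected], dtype=dtype)
    return arr.reshape(n_tot, n_par).astype(np.float64)


def _parse_timestamp(keywords: dict[str, str]) -> _dt.datetime | None:
    iso = keywords.get("#TIMESTAMP")
    if iso:
        try:
            return _dt.datetime.fromisoformat(iso)
        except ValueError:
            pass
    date, btim = keywords.get("$DATE"), keywords.get("$BTIM")
    if date and btim:
        for datefmt in ("%d-%b-%Y", "%Y-%m-%d", "%d-%m-%Y"):
            try:
                day = _dt.datetime.strptime(date, datefmt)
                t = _dt.datetime.strptime(btim.split(".")[0], "%H:%M:%S")
                return day.replace(hour=t.hour, minute=t.minute, second=t.second)
            except ValueError:
                continue
    return None


def _sidecar_metadata(path: Path) -> dict:
    """YAML/JSON sidecar (<name>.yaml/.yml/.json) with per-sample metadata."""
    for suffix in (".yaml", ".yml", ".json"):
        side = path.with_suffix(suffix)
        if side.exists():
            text = side.read_text()
            return json.loads(text) if suffix == ".json" else yaml.safe_load(text)
    return {}


def read_fcs(path: str | Path, required_channels: Sequence[str] = ()) -> EventTable:
    """Read an FCS 3.0/3.1 list-mode file into an :class:`EventTable`.

    Volume and dilution come from keywords ($VOL in nL, #DILUTION), then a
    sidecar metadata file, then the online-monitoring defaults (with a
    warning).  ``required_channels`` lets callers fail early when a file
    lacks the channels the downstream gating needs.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_LEN:
        raise FCSParseError(f"{path}: HEADER segment truncated ({len(raw)} bytes)")
    version = raw[:6].decode("latin-1", "replace")
    if not version.startswith("FCS"):
        raise FCSParseError(f"{path}: HEADER segment: not an FCS file ({version!r})")

    def _offset(lo: int, hi: int) -> int:
        txt = raw[lo:hi].decode("latin-1").strip() or "0"
        try:
            return int(txt)
        except ValueError:
            raise FCSParseError(f"{path}: HEADER segment: bad offset {txt!r}") from None

    text_beg, text_end = _offset(10, 18), _offset(18, 26)
    data_beg, data_end = _offset(26, 34), _offset(34, 42)
    if text_end <= text_beg:
        raise FCSParseError(f"{path}: HEADER segment: invalid TEXT offsets")
    keywords = _parse_text_segment(raw[text_beg : text_end + 1])
    if data_beg == 0 and "$BEGINDATA" in keywords:
        data_beg = int(keywords["$BEGINDATA"])
        data_end = int(keywords["$ENDDATA"])
    for kw in ("$PAR", "$TOT"):
        if kw not in keywords:
            raise FCSParseError(f"{path}: TEXT segment: required keyword {kw} missing")
    n_par = int(keywords["$PAR"])
    channels = []
    for i in range(1, n_par + 1):
        name = keywords.get(f"$P{i}N") or keywords.get(f"$P{i}S") or f"P{i}"
        channels.append(name.strip())
    missing = [c for c in required_channels if c not in channels]
    if missing:
        raise ChannelError(
            f"{path}: required channels {missing} not found; file has {channels}"
        )
    events = (
        _decode_events(raw[data_beg : data_end + 1], keywords)
        if int(keywords["$TOT"]) > 0
        else np.empty((0, n_par))
    )

    sidecar = _sidecar_metadata(path)
    if "$VOL" in keywords:  # FCS 3.1: sample volume in nanoliters
        volume = float(keywords["$VOL"]) / 1000.0
    elif "volume_uL" in sidecar:
        volume = float(sidecar["volume_uL"])
    else:
        volume = DEFAULT_VOLUME_UL
        logger.warning("%s: no volume keyword/sidecar; using %.0f uL", path, volume)
    if "#DILUTION" in keywords:
        dilution = float(keywords["#DILUTION"])
    elif "dilution" in sidecar:
        dilution = float(sidecar["dilution"])
    else:
        dilution = DEFAULT_DILUTION
        logger.warning("%s: no dilution keyword/sidecar; using 1:%.0f", path, dilution)
    timestamp = _parse_timestamp(keywords)
    if timestamp is None and "timestamp" in sidecar:
        timestamp = _dt.datetime.fromisoformat(str(sidecar["timestamp"]))
    sample_id = keywords.get("#SAMPLE_ID") or sidecar.get("sample_id") or path.stem
    extra = {
        k: v
        for k, v in keywords.items()
        if not k.startswith("$") and k not in ("#DILUTION", "#SAMPLE_ID", "#TIMESTAMP")
    }
    return EventTable(
        events=events,
        channel_names=channels,
        acquired_volume_uL=volume,
        dilution_factor=dilution,
        timestamp=timestamp,
        sample_id=sample_id,
        extra_keywords=extra,
    )


def write_fcs(table: EventTable, path: str | Path) -> Path:
    """Write an :class:`EventTable` as a single-precision FCS 3.1 file.

    Metadata round-trips through keywords: $VOL (nL), #DILUTION,
    #TIMESTAMP (ISO-8601), #SAMPLE_ID, plus any ``extra_keywords``.
    """
    path = Path(path)
    n_tot, n_par = table.events.shape
    keywords: dict[str, str] = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$VOL": f"{table.acquired_volume_uL * 1000.0:.1f}",
        "#DILUTION": f"{table.dilution_factor:g}",
        "#SAMPLE_ID": table.sample_id,
    }
    for i, name in enumerate(table.channel_names, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = "16777216"
    if table.timestamp is not None:
        keywords["#TIMESTAMP"] = table.timestamp.isoformat()
        keywords["$DATE"] = table.timestamp.strftime("%d-%b-%Y")
        keywords["$BTIM"] = table.timestamp.strftime("%H:%M:%S")
    keywords.update(table.extra_keywords)

    data = table.events.astype("<f4").tobytes(order="C")

    # $BEGINDATA/$ENDDATA are zero-padded so TEXT length is offset-independent
    def render_text(beg: int, end: int) -> bytes:
        items = {"$BEGINDATA": f"{beg:010d}", "$ENDDATA": f"{end:010d}", **keywords}
        body = "".join(f"/{k}/{v}" for k, v in items.items()) + "/"
        return body.encode("latin-1")

    text = render_text(0, 0)
    text_beg = _HEADER_LEN
    text_end = text_beg + len(text) - 1
    data_beg = text_end + 1
    data_end = data_beg + max(len(data) - 1, 0)
    text = render_text(data_beg, data_end)

    def fmt(x: int) -> bytes:
        return (b"%8d" % x) if x <= 99_999_999 else b"       0"

    header = (
        b"FCS3.1    "
        + fmt(text_beg)
        + fmt(text_end)
        + fmt(data_beg)
        + fmt(data_end)
        + fmt(0)
        + fmt(0)
    )
    assert len(header) == _HEADER_LEN
    try:
        path.write_bytes(header + text + data)
    except OSError as exc:
        raise IOError(f"cannot write FCS file {path}: {exc}") from exc
    return path


def load_series(
    paths: Sequence[str | Path],
    t0: _dt.datetime | None = None,
    interval_min: float = 25.0,
) -> MeasurementSeries:
    """Assemble FCS files into a strictly time-ordered measurement series.

    Files lacking a resolvable timestamp are assigned ``t0 + i * interval``
    in input order (logged).  Duplicate timestamps are rejected rather than
    silently reordered.
    """
    if not paths:
        raise ValueError("load_series requires at least one path")
    tables = [read_fcs(p) for p in paths]
    missing = [t for t in tables if t.timestamp is None]
    if missing:
        if t0 is None:
            t0 = _dt.datetime(2000, 1, 1)
        logger.warning(
            "%d/%d files lack time keywords; assigning %g-min spacing from %s",
            len(missing),
            len(tables),
            interval_min,
            t0,
        )
        for i, t in enumerate(tables):
            if t.timestamp is None:
                t.timestamp = t0 + _dt.timedelta(minutes=i * interval_min)
    tables.sort(key=lambda t: t.timestamp)
    stamps = [t.timestamp for t in tables]
    if len(set(stamps)) != len(stamps):
        dupes = sorted({s for s in stamps if stamps.count(s) > 1})
        raise ValueError(f"duplicate sample timestamps: {dupes}")
    if t0 is None:
        t0 = stamps[0]
    return MeasurementSeries(samples=tables, t0=t0, sampling_interval_min=interval_min)
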
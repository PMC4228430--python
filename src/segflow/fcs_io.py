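"""List-mode cytometry I/O: minimal FCS 3.0/3.1 and the CSV listmode dialect.

The instrument this package models is a benchtop cytometer whose software
exports list-mode data either as FCS files or as plain CSV (one row per
event, one column per channel: FSC, SSC, FL1, FL3). Only list mode
($MODE=L) with integer or float data ($DATATYPE I or F) is supported; no
compensation is applied ($SPILLOVER, if present, is ignored with a warning)
because the analyses downstream operate on raw linear channel values.

CSV dialect: comma delimiter, "." decimal separator, mandatory header row of
channel names, UTF-8. CSV exports carry no acquisition metadata, so fields
that an FCS file would fill are left as the explicit unknown sentinel
(``None``), never silently zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd

logger = logging.getLogger("segflow")

__all__ = [
    "AcquisitionMeta",
    "EventTable",
    "FcsFormatError",
    "CorruptFileError",
    "InvalidTableError",
    "ListmodeParseError",
    "read_fcs",
    "write_fcs",
    "read_listmode_csv",
    "write_listmode_csv",
]


class FcsFormatError(ValueError):
    """Unsupported FCS feature (names the offending keyword)."""


class CorruptFileError(ValueError):
    """File structure inconsistent with its own declarations."""


class InvalidTableError(ValueError):
    """EventTable violates the writer's preconditions."""


class ListmodeParseError(ValueError):
    """CSV listmode cell or header failed to parse."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition context for one sample.

    ``None`` means the value is unknown (e.g. the CSV export dropped it);
    it is an explicit sentinel, distinct from zero.

    Attributes
    ----------
    time_h : sample timestamp, hours from culture start.
    duration_s : acquisition duration in seconds.
    flow_rate_ul_min : cytometer flow rate, μL/min.
    event_cap : maximum number of events the instrument records.
    truncated : whether the cap stopped acquisition early.
    """

    time_h: float | None = None
    duration_s: float | None = None
    flow_rate_ul_min: float | None = None
    event_cap: int | None = None
    truncated: bool = False


@dataclass(frozen=True)
class EventTable:
    """One list-mode cytometry sample: per-event channel values + metadata.

    ``events`` is a DataFrame with one row per event and one column per
    channel (arbitrary-unit, non-negative intensities). Invariants are
    enforced at construction: all values finite and >= 0, and if the
    truncated flag is set the event count must equal the event cap.
    """

    events: pd.DataFrame
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        vals = self.events.to_numpy(dtype=float) if len(self.events.columns) else np.empty((len(self.events), 0))
        if vals.size and not np.all(np.isfinite(vals)):
            raise InvalidTableError("channel values must be finite")
        if vals.size and vals.min() < 0:
            raise InvalidTableError("channel values must be non-negative")
        if self.meta.truncated:
            if self.meta.event_cap is None:
                raise InvalidTableError("truncated table requires an event cap")
            # acquisition produces exactly cap events when truncated; later
            # filtering (FSC threshold) may reduce the count, never raise it
            if len(self.events) > self.meta.event_cap:
                raise InvalidTableError(
                    f"truncated table has {len(self.events)} events, cap is {self.meta.event_cap}"
                )

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def channels(self) -> list[str]:
        return list(self.events.columns)

    def with_events(self, events: pd.DataFrame) -> "EventTable":
        return EventTable(events=events.reset_index(drop=True), meta=self.meta)

    def with_meta(self, **kwargs) -> "EventTable":
        return EventTable(events=self.events, meta=replace(self.meta, **kwargs))


# --------------------------------------------------------------------------
# FCS 3.0 / 3.1
# --------------------------------------------------------------------------

_DELIM = "/"
_BYTEORD_LITTLE = "1,2,3,4"
_BYTEORD_BIG = "4,3,2,1"


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    text = raw.decode("ascii", errors="replace")
    if not text:
        raise CorruptFileError("empty TEXT segment")
    delim = text[0]
    body = text[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise CorruptFileError("TEXT segment has an odd number of delimited fields")
    kw = {}
    for key, value in zip(parts[::2], parts[1::2]):
        kw[key.strip().upper()] = value.strip()
    return kw


def read_fcs(path: str | Path) -> EventTable:
    """Read a minimal list-mode FCS 3.0/3.1 file.

    Supports $MODE=L, $DATATYPE I (unsigned integers, $PnB 8/16/32/64 bits)
    and F (32-bit floats), both byte orders. Raises :class:`FcsFormatError`
    for unsupported keywords and :class:`CorruptFileError` when the declared
    structure disagrees with the file contents.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise CorruptFileError(f"{path}: file too short for an FCS header")
    version = blob[:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsFormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        fragment = blob[lo:hi].decode("ascii", errors="replace").strip()
        try:
            return int(fragment) if fragment else 0
        except ValueError as exc:
            raise CorruptFileError(f"{path}: bad header offset {fragment!r}") from exc

    text_begin, text_end = _offset(10, 18), _offset(18, 26)
    data_begin, data_end = _offset(26, 34), _offset(34, 42)
    if text_begin <= 0 or text_end < text_begin:
        raise CorruptFileError(f"{path}: invalid TEXT segment offsets")
    kw = _parse_text_segment(blob[text_begin : text_end + 1])

    for required in ("$TOT", "$PAR", "$DATATYPE", "$BYTEORD", "$MODE"):
        if required not in kw:
            raise CorruptFileError(f"{path}: TEXT segment missing {required}")
    if kw["$MODE"].upper() != "L":
        raise FcsFormatError(f"{path}: unsupported $MODE={kw['$MODE']!r} (list mode only)")
    datatype = kw["$DATATYPE"].upper()
    if datatype not in ("I", "F"):
        raise FcsFormatError(f"{path}: unsupported $DATATYPE={datatype!r}")
    byteord = kw["$BYTEORD"]
    if byteord not in (_BYTEORD_LITTLE, _BYTEORD_BIG):
        raise FcsFormatError(f"{path}: unsupported $BYTEORD={byteord!r}")
    endian = "<" if byteord == _BYTEORD_LITTLE else ">"

    if "$SPILLOVER" in kw or "SPILL" in kw:
        logger.warning("%s: $SPILLOVER present but ignored (no compensation applied)", path)

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    names, bits = [], []
    for i in range(1, n_par + 1):
        pn = kw.get(f"$P{i}N")
        pb = kw.get(f"$P{i}B")
        if pn is None or pb is None:
            raise CorruptFileError(f"{path}: missing $P{i}N/$P{i}B")
        names.append(pn)
        bits.append(int(pb))

    # data_begin may be zero in the header when deferred to TEXT keywords
    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    data = blob[data_begin : data_end + 1]

    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FcsFormatError(f"{path}: $DATATYPE=F requires $PnB=32")
        expected = n_tot * n_par * 4
        if len(data) < expected:
            raise CorruptFileError(
                f"{path}: $TOT={n_tot} needs {expected} data bytes, segment has {len(data)}"
            )
        arr = np.frombuffer(data[:expected], dtype=np.dtype(f"{endian}f4")).astype(np.float64)
        matrix = arr.reshape(n_tot, n_par)
    else:
        if any(b not in (8, 16, 32, 64) for b in bits):
            raise FcsFormatError(f"{path}: unsupported $PnB values {bits} for $DATATYPE=I")
        row_bytes = sum(b // 8 for b in bits)
        expected = n_tot * row_bytes
        if len(data) < expected:
            raise CorruptFileError(
                f"{path}: $TOT={n_tot} needs {expected} data bytes, segment has {len(data)}"
            )
        matrix = np.empty((n_tot, n_par), dtype=np.float64)
        offset = 0
        cols = []
        for b in bits:
            cols.append((offset, np.dtype(f"{endian}u{b // 8}")))
            offset += b // 8
        raw = np.frombuffer(data[:expected], dtype=np.uint8).reshape(n_tot, row_bytes)
        for j, (off, dt) in enumerate(cols):
            matrix[:, j] = raw[:, off : off + dt.itemsize].copy().view(dt).ravel()

    events = pd.DataFrame(matrix, columns=names)
    meta = AcquisitionMeta(
        time_h=_maybe_float(kw.get("SEGFLOW$TIMEH")),
        duration_s=_maybe_float(kw.get("SEGFLOW$DURS")),
        flow_rate_ul_min=_maybe_float(kw.get("SEGFLOW$FLOW")),
        event_cap=_maybe_int(kw.get("SEGFLOW$CAP")),
        truncated=kw.get("SEGFLOW$TRUNC", "0") == "1",
    )
    return EventTable(events=events, meta=meta)


def _maybe_float(s: str | None) -> float | None:
    return None if s in (None, "") else float(s)


def _maybe_int(s: str | None) -> int | None:
    return None if s in (None, "") else int(s)


def write_fcs(table: EventTable, path: str | Path) -> None:
    """Write a minimal FCS 3.1 file ($MODE=L, $DATATYPE=F, little-endian).

    Acquisition metadata is stored under custom SEGFLOW$ keywords so that
    :func:`read_fcs` round-trips it; standard readers ignore them.
    """
    path = Path(path)
    channels = table.channels
    if not channels:
        raise InvalidTableError("cannot write an FCS file with zero channels")
    for name in channels:
        if not str(name).isascii():
            raise InvalidTableError(f"channel name {name!r} is not ASCII")

    data = table.events.to_numpy(dtype=np.float32) if table.n_events else np.empty(
        (0, len(channels)), dtype=np.float32
    )
    data_bytes = data.astype("<f4").tobytes()

    meta = table.meta
    kw: dict[str, str] = {
        "$BYTEORD": _BYTEORD_LITTLE,
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(len(channels)),
        "$TOT": str(table.n_events),
    }
    for i, name in enumerate(channels, start=1):
        kw[f"$P{i}N"] = str(name)
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(max(float(data[:, i - 1].max()) if len(data) else 0.0, 1)) + 1)
    if meta.time_h is not None:
        kw["SEGFLOW$TIMEH"] = repr(float(meta.time_h))
    if meta.duration_s is not None:
        kw["SEGFLOW$DURS"] = repr(float(meta.duration_s))
    if meta.flow_rate_ul_min is not None:
        kw["SEGFLOW$FLOW"] = repr(float(meta.flow_rate_ul_min))
    if meta.event_cap is not None:
        kw["SEGFLOW$CAP"] = str(meta.event_cap)
    kw["SEGFLOW$TRUNC"] = "1" if meta.truncated else "0"

    header_len = 58
    # iterate because BEGINDATA/ENDDATA digit counts depend on the TEXT length
    begin_data, end_data = 0, 0
    for _ in range(8):
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(end_data)
        text = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in sorted(kw.items())) + _DELIM
        text_begin = header_len
        text_end = text_begin + len(text) - 1
        new_begin = text_end + 1
        new_end = new_begin + max(len(data_bytes) - 1, 0)
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    else:  # pragma: no cover - fixed point always reached in a few passes
        raise RuntimeError("failed to stabilize FCS segment offsets")

    def _fmt(n: int) -> bytes:
        s = str(n)
        if len(s) > 8:
            s = "0"  # too large for the header; rely on TEXT keywords
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + _fmt(text_begin) + _fmt(text_end)
    header += _fmt(begin_data if len(data_bytes) else 0)
    header += _fmt(end_data if len(data_bytes) else 0)
    header += _fmt(0) + _fmt(0)  # no ANALYSIS segment
    assert len(header) == header_len

    path.write_bytes(header + text.encode("ascii") + data_bytes)


# --------------------------------------------------------------------------
# CSV listmode dialect
# --------------------------------------------------------------------------


def read_listmode_csv(path: str | Path) -> EventTable:
    """Read the instrument-software CSV listmode export.

    First row = channel names, one row per event, numeric cells. Metadata
    absent from the CSV is left at the unknown sentinel.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header_line = fh.readline().rstrip("\r\n")
        if not header_line:
            raise ListmodeParseError(f"{path}: empty file or missing header row")
        names = [c.strip() for c in header_line.split(",")]
        seen = set()
        for name in names:
            if name in seen:
                raise ListmodeParseError(f"{path}: duplicate channel name {name!r}")
            seen.add(name)
        try:
            frame = pd.read_csv(fh, header=None, names=names, dtype=str, skip_blank_lines=True)
        except pd.errors.EmptyDataError:
            frame = pd.DataFrame(columns=names, dtype=str)

    numeric = pd.DataFrame(index=frame.index)
    for col in names:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ListmodeParseError(
                f"{path}: non-numeric cell {frame[col][row]!r} at row {row + 2}, column {col!r}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise ListmodeParseError(f"{path}: missing cell at row {row + 2}, column {col!r}")
        numeric[col] = converted.astype(float)
    return EventTable(events=numeric.reset_index(drop=True))


def write_listmode_csv(table: EventTable, path: str | Path) -> None:
    """Write the CSV listmode dialect (header row + one row per event)."""
    if not table.channels:
        raise InvalidTableError("cannot write a CSV with zero channels")
    table.events.to_csv(Path(path), index=False)

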
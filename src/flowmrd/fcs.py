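"""FCS 3.0 list-mode file and CSV event-table input/output.

Flow Cytometry Standard (FCS) 3.0 files carry a fixed-width HEADER with
segment offsets, a delimited TEXT segment of ``$``-prefixed keywords, and a
binary DATA segment holding one row per acquired event and one column per
measured parameter (channel).  This module reads FCS 3.0 list-mode files
(``$DATATYPE`` ``F`` or ``I``), writes minimal valid FCS 3.0 files
(``$DATATYPE F``, little-endian, single data segment) that round-trip
bit-exactly, and converts to/from CSV event tables headed by the channel
short names.

Integer-stored parameters acquired with logarithmic amplification
(``$PnE`` decades ``d > 0``) are decoded to scale values
``10**(d * x / $PnR)`` on read, so the event matrix always holds
linear-scale intensities.  Stored values are otherwise taken as-is: no
fluorescence compensation is computed or applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class FCSError(ValueError):
    """Malformed or unsupported FCS content; the message names the offending keyword."""


class CSVError(ValueError):
    """Malformed CSV event table; the message names the offending row."""


@dataclass(frozen=True)
class ChannelInfo:
    """Per-parameter metadata needed to decode stored values.

    Parameters
    ----------
    short_name
        Mandatory unique key (keyword ``$PnN``), e.g. ``"CD7"`` or ``"FSC"``.
    stain_name
        Optional display label (keyword ``$PnS``), e.g. ``"CD7 FITC"``.
    range
        Parameter range (keyword ``$PnR``); must be positive.
    amplification
        ``(decades, offset)`` from keyword ``$PnE``; ``decades > 0`` marks
        logarithmic storage for integer data.
    """

    short_name: str
    stain_name: str | None = None
    range: float = 262144.0
    amplification: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.short_name:
            raise ValueError("channel short_name ($PnN) must be nonempty")
        if not self.range > 0:
            raise ValueError(f"channel {self.short_name!r}: range ($PnR) must be > 0")
        if self.amplification[0] < 0:
            raise ValueError(
                f"channel {self.short_name!r}: amplification decades ($PnE) must be >= 0"
            )


@dataclass
class EventMatrix:
    """List-mode cytometry events: an ``n_events x n_channels`` intensity matrix.

    Rows are events (cells), columns are channels; values are finite
    linear-scale intensities.  Channel identity for all downstream joins is
    the ``$PnN`` short name, which must be unique within a specimen.
    """

    values: np.ndarray
    channels: list[ChannelInfo]
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.channels) != self.values.shape[1]:
            raise ValueError("channel metadata count must match column count")
        if len(self.channels) < 2:
            raise ValueError("an event matrix needs at least 2 channels")
        names = [c.short_name for c in self.channels]
        if len(set(names)) != len(names):
            raise FCSError(f"duplicate $PnN channel names: {names}")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("event intensities must all be finite")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return [c.short_name for c in self.channels]

    def column(self, name: str) -> np.ndarray:
        """Return the intensity column for channel ``name`` (by ``$PnN``)."""
        try:
            j = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"specimen {self.specimen_id!r} has no channel {name!r}; "
                f"available: {self.channel_names}"
            ) from None
        return self.values[:, j]

    def select(self, names: Sequence[str]) -> np.ndarray:
        """Return the feature sub-matrix with columns in the requested order."""
        return np.column_stack([self.column(n) for n in names]) if self.n_events else (
            np.empty((0, len(names)))
        )


# ---------------------------------------------------------------------------
# FCS 3.0 reading

_HEADER_LEN = 58  # 10-byte version field + six 8-byte ASCII offsets


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # delimiter doubling escapes a literal delimiter inside a value
    parts: list[str] = []
    buf = bytearray()
    i = 0
    while i < len(body):
        b = body[i : i + 1]
        if b == delim:
            if body[i + 1 : i + 2] == delim:
                buf.extend(delim)
                i += 2
                continue
            parts.append(buf.decode("utf-8", errors="replace"))
            buf = bytearray()
            i += 1
        else:
            buf.extend(b)
            i += 1
    parts.append(buf.decode("utf-8", errors="replace"))
    if len(parts) % 2 != 0:
        parts = parts[:-1] if parts[-1] == "" else parts + [""]
    kw = {}
    for k, v in zip(parts[::2], parts[1::2]):
        kw[k.strip().upper()] = v
    return kw


def _require(kw: dict[str, str], key: str) -> str:
    if key not in kw:
        raise FCSError(f"missing required keyword {key}")
    return kw[key]


def read_fcs(path: str | Path) -> EventMatrix:
    """Read an FCS 3.0 list-mode file into an :class:`EventMatrix`.

    Supports ``$DATATYPE`` ``F`` (32-bit float) and ``I`` (unsigned integer,
    ``$PnB`` 8/16/32/64) with ``$BYTEORD`` ``1,2,3,4`` or ``4,3,2,1``.
    Integer parameters with log amplification are decoded to
    ``10**(decades * x / $PnR)``.

    Raises
    ------
    FCSError
        On unsupported version, non-list mode, a truncated DATA segment, or
        ``$TOT``/``$PAR`` inconsistent with the segment length.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < _HEADER_LEN:
        raise FCSError("file shorter than an FCS HEADER")
    version = blob[0:6].decode("ascii", errors="replace")
    if version != "FCS3.0":
        raise FCSError(f"unsupported FCS version {version!r}; only FCS3.0 is supported")

    def _offset(a: int, b: int) -> int:
        txt = blob[a:b].decode("ascii", errors="replace").strip() or "0"
        try:
            return int(txt)
        except ValueError:
            raise FCSError(f"non-numeric HEADER offset field {txt!r}") from None

    text_beg, text_end = _offset(10, 18), _offset(18, 26)
    data_beg, data_end = _offset(26, 34), _offset(34, 42)
    kw = _parse_text_segment(blob[text_beg : text_end + 1])

    mode = _require(kw, "$MODE").strip().upper()
    if mode != "L":
        raise FCSError(f"$MODE {mode!r} is not list mode ('L')")
    datatype = _require(kw, "$DATATYPE").strip().upper()
    if datatype not in ("F", "I"):
        raise FCSError(f"$DATATYPE {datatype!r} unsupported (need 'F' or 'I')")
    byteord = _require(kw, "$BYTEORD").strip()
    if byteord == "1,2,3,4":
        endian = "<"
    elif byteord == "4,3,2,1":
        endian = ">"
    else:
        raise FCSError(f"$BYTEORD {byteord!r} unsupported")

    try:
        n_par = int(_require(kw, "$PAR"))
        n_tot = int(_require(kw, "$TOT"))
    except ValueError as exc:
        raise FCSError(f"non-integer $PAR/$TOT: {exc}") from None

    if data_beg == 0:
        data_beg = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    if data_end <= 0 or data_end < data_beg:
        data = b""
    else:
        if data_end + 1 > len(blob):
            raise FCSError("truncated DATA segment: file ends before declared $ENDDATA")
        data = blob[data_beg : data_end + 1]

    channels: list[ChannelInfo] = []
    bits: list[int] = []
    for i in range(1, n_par + 1):
        pnn = _require(kw, f"$P{i}N")
        pnb = int(_require(kw, f"$P{i}B"))
        pnr = float(_require(kw, f"$P{i}R"))
        pne = kw.get(f"$P{i}E", "0,0")
        try:
            dec_s, off_s = pne.split(",")
            amp = (float(dec_s), float(off_s))
        except ValueError:
            raise FCSError(f"malformed $P{i}E value {pne!r}") from None
        channels.append(
            ChannelInfo(
                short_name=pnn,
                stain_name=kw.get(f"$P{i}S"),
                range=pnr,
                amplification=amp,
            )
        )
        bits.append(pnb)

    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FCSError("$PnB must be 32 for $DATATYPE F")
        expected = 4 * n_par * n_tot
        if len(data) < expected:
            raise FCSError(
                f"DATA segment holds {len(data)} bytes but $TOT={n_tot}, "
                f"$PAR={n_par} require {expected}"
            )
        arr = np.frombuffer(data[:expected], dtype=f"{endian}f4").astype(np.float64)
        values = arr.reshape(n_tot, n_par)
    else:
        widths = {8: "u1", 16: "u2", 32: "u4", 64: "u8"}
        for b in bits:
            if b not in widths:
                raise FCSError(f"$PnB {b} unsupported for $DATATYPE I")
        if len(set(bits)) == 1:
            nbytes = bits[0] // 8
            expected = nbytes * n_par * n_tot
            if len(data) < expected:
                raise FCSError(
                    f"DATA segment holds {len(data)} bytes but $TOT={n_tot}, "
                    f"$PAR={n_par} require {expected}"
                )
            arr = np.frombuffer(data[:expected], dtype=f"{endian}{widths[bits[0]]}")
            values = arr.astype(np.float64).reshape(n_tot, n_par)
        else:  # mixed widths: decode event by event
            row_bytes = sum(b // 8 for b in bits)
            expected = row_bytes * n_tot
            if len(data) < expected:
                raise FCSError(
                    f"DATA segment holds {len(data)} bytes but $TOT={n_tot}, "
                    f"$PAR={n_par} require {expected}"
                )
            values = np.empty((n_tot, n_par))
            pos = 0
            for r in range(n_tot):
                for c, b in enumerate(bits):
                    w = b // 8
                    values[r, c] = int.from_bytes(
                        data[pos : pos + w], "little" if endian == "<" else "big"
                    )
                    pos += w
        # log-amplified integer channels store ADC counts; decode to scale values
        for j, ch in enumerate(channels):
            d, off = ch.amplification
            if d > 0:
                scale = off if off > 0 else 1.0
                values[:, j] = scale * 10.0 ** (d * values[:, j] / ch.range)

    return EventMatrix(values=values, channels=channels, specimen_id=path.stem)


# ---------------------------------------------------------------------------
# FCS 3.0 writing

def _format_text(pairs: list[tuple[str, str]], delim: str = "/") -> bytes:
    out = [delim]
    for k, v in pairs:
        if delim in k or delim in v:
            raise FCSError(f"keyword or value may not contain the delimiter {delim!r}: {k}={v}")
        out.append(f"{k}{delim}{v}{delim}")
    return "".join(out).encode("ascii")


def write_fcs(events: EventMatrix, path: str | Path) -> Path:
    """Write a minimal valid FCS 3.0 file that :func:`read_fcs` round-trips bit-exactly.

    Values are stored as little-endian 32-bit floats (``$DATATYPE F``,
    ``$PnE`` ``0,0``) in a single DATA segment.  Intensities outside float32
    range are rejected rather than silently truncated.
    """
    path = Path(path)
    n_tot, n_par = events.values.shape
    data32 = events.values.astype("<f4")
    if n_tot and not np.isfinite(data32).all():
        raise FCSError("values exceed float32 range; cannot store as $DATATYPE F")
    data = data32.tobytes()

    pairs: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    for i, ch in enumerate(events.channels, start=1):
        pairs.append((f"$P{i}B", "32"))
        pairs.append((f"$P{i}E", "0,0"))
        pairs.append((f"$P{i}N", ch.short_name))
        pairs.append((f"$P{i}R", f"{ch.range:g}"))
        if ch.stain_name:
            pairs.append((f"$P{i}S", ch.stain_name))

    # DATA offsets depend on TEXT length, which depends on the offset digit
    # count; iterate to a fixed point (converges in <=3 rounds).
    data_beg = _HEADER_LEN
    for _ in range(8):
        text = _format_text(
            [("$BEGINDATA", str(data_beg)), ("$ENDDATA", str(data_beg + len(data) - 1))]
            + pairs
        )
        new_beg = _HEADER_LEN + len(text)
        if new_beg == data_beg:
            break
        data_beg = new_beg
    else:  # pragma: no cover
        raise FCSError("failed to stabilize segment offsets")

    text_beg = _HEADER_LEN
    text_end = text_beg + len(text) - 1
    hdr_beg, hdr_end = (data_beg, data_beg + len(data) - 1) if data else (0, 0)
    if hdr_end > 99_999_999:  # offsets too wide for the HEADER; TEXT keywords carry them
        hdr_beg = hdr_end = 0
    header = (
        b"FCS3.0    "
        + f"{text_beg:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{hdr_beg:>8d}".encode()
        + f"{hdr_end:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)
    return path


# ---------------------------------------------------------------------------
# CSV event tables

def export_csv(events: EventMatrix, path: str | Path) -> Path:
    """Write the event matrix as CSV: header row of channel short names, one row per event."""
    path = Path(path)
    df = pd.DataFrame(events.values, columns=events.channel_names)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_csv(path: str | Path) -> EventMatrix:
    """Read a CSV event table written by :func:`export_csv`.

    Channel metadata is reconstructed with linear amplification and a range
    covering the observed values.  Ragged or non-numeric rows raise
    :class:`CSVError` naming the offending data row (1-based, excluding the
    header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise CSVError(f"malformed CSV {path.name}: {exc}") from None
    if df.shape[1] < 2:
        raise CSVError(f"{path.name}: need at least 2 channel columns")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise CSVError(f"{path.name}: non-numeric cell in row {row}, column {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 1
        raise CSVError(f"{path.name}: missing cell in row {row}")
    channels = [
        ChannelInfo(short_name=str(c), range=float(max(df[c].max(), 1.0)) if len(df) else 262144.0)
        for c in df.columns
    ]
    return EventMatrix(values=df.to_numpy(dtype=np.float64), channels=channels,
                       specimen_id=path.stem)
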
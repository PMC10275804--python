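"""Minimal FCS 3.0/3.1 list-mode codec.

Supports exactly what a reporter-timecourse workflow needs: single-dataset
files, list mode (``$MODE L``), float (``$DATATYPE F``/``D``) or integer
(``$DATATYPE I`` with byte-aligned ``$PnB``) data, little- or big-endian
byte order. Writing always produces FCS 3.1 float32 little-endian.
"""

from __future__ import annotations

import io
import os
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_fcs", "write_fcs", "FcsFormatError"]

_DELIM = "/"
_HEADER_LEN = 58


class FcsFormatError(ValueError):
    """Raised for files that are not parseable FCS 3.0/3.1."""


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if len(raw) < 2:
        raise FcsFormatError("TEXT segment too short")
    delim = raw[0:1].decode("latin-1")
    body = raw[1:].decode("latin-1")
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        # trailing empty value is tolerated
        parts.append("")
    return {
        parts[i].strip().upper(): parts[i + 1]
        for i in range(0, len(parts) - 1, 2)
        if parts[i].strip()
    }


def read_fcs(path: str | os.PathLike) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read an FCS 3.0/3.1 file.

    Returns
    -------
    (events, keywords)
        ``events`` is a DataFrame with one column per parameter, named by
        ``$PnN``; ``keywords`` is the raw TEXT-segment keyword dict.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_LEN)
        if len(header) < _HEADER_LEN:
            raise FcsFormatError(f"{path}: truncated FCS header")
        version = header[0:6].decode("latin-1", "replace")
        if version not in ("FCS3.0", "FCS3.1"):
            raise FcsFormatError(f"{path}: unsupported FCS version {version!r}")

        def _offset(field: bytes) -> int:
            txt = field.decode("latin-1").strip()
            return int(txt) if txt else 0

        text_begin = _offset(header[10:18])
        text_end = _offset(header[18:26])
        data_begin = _offset(header[26:34])
        data_end = _offset(header[34:42])
        if text_begin <= 0 or text_end <= text_begin:
            raise FcsFormatError(f"{path}: malformed FCS header offsets")
        fh.seek(text_begin)
        keywords = _parse_text_segment(fh.read(text_end - text_begin + 1))

        if data_begin == 0:
            data_begin = int(keywords.get("$BEGINDATA", 0))
            data_end = int(keywords.get("$ENDDATA", 0))
        if data_begin <= 0 or data_end < data_begin:
            raise FcsFormatError(f"{path}: missing DATA segment offsets")

        n_par = int(keywords["$PAR"])
        n_tot = int(keywords["$TOT"])
        mode = keywords.get("$MODE", "L").upper()
        if mode != "L":
            raise FcsFormatError(f"{path}: only list mode supported, got $MODE {mode}")
        datatype = keywords.get("$DATATYPE", "F").upper()
        byteord = keywords.get("$BYTEORD", "1,2,3,4")
        endian = "<" if byteord.startswith("1") else ">"
        if datatype == "F":
            dtype = np.dtype(endian + "f4")
        elif datatype == "D":
            dtype = np.dtype(endian + "f8")
        elif datatype == "I":
            bits = {int(keywords[f"$P{i}B"]) for i in range(1, n_par + 1)}
            if len(bits) != 1 or next(iter(bits)) not in (8, 16, 32):
                raise FcsFormatError(f"{path}: unsupported integer widths {bits}")
            dtype = np.dtype(endian + f"u{next(iter(bits)) // 8}")
        else:
            raise FcsFormatError(f"{path}: unsupported $DATATYPE {datatype}")

        fh.seek(data_begin)
        raw = fh.read(data_end - data_begin + 1)

    n_values = n_par * n_tot
    values = np.frombuffer(raw[: n_values * dtype.itemsize], dtype=dtype)
    if values.size != n_values:
        raise FcsFormatError(
            f"{path}: DATA segment holds {values.size} values, expected {n_values}"
        )
    names = [keywords.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    table = pd.DataFrame(
        values.reshape(n_tot, n_par).astype(np.float64), columns=names
    )
    return table, keywords


def write_fcs(
    path: str | os.PathLike,
    events: pd.DataFrame,
    extra_keywords: dict[str, str] | None = None,
) -> None:
    """Write *events* (one column per channel) as FCS 3.1, float32."""
    events = pd.DataFrame(events)
    n_tot, n_par = events.shape
    if n_par == 0:
        raise ValueError("cannot write an FCS file with zero channels")
    for name in events.columns:
        if _DELIM in str(name):
            raise ValueError(f"channel name {name!r} contains the delimiter {_DELIM!r}")
    data = np.ascontiguousarray(events.to_numpy(dtype=np.float32))
    data_bytes = data.tobytes()

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, name in enumerate(events.columns, start=1):
        col = data[:, i - 1]
        rng = float(col.max()) if n_tot else 0.0
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(max(1, int(np.ceil(rng)) + 1))
    for key, value in (extra_keywords or {}).items():
        keywords[key.upper()] = str(value)

    # Two-pass layout: offsets appear inside TEXT, so reserve stable widths.
    text_begin = 256

    def render_text(data_begin: int, data_end: int) -> bytes:
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(data_begin)
        kw["$ENDDATA"] = str(data_end)
        buf = io.StringIO()
        buf.write(_DELIM)
        for key in sorted(kw):
            buf.write(f"{key}{_DELIM}{kw[key]}{_DELIM}")
        return buf.getvalue().encode("latin-1")

    placeholder = render_text(99999999, 99999999)
    text_end = text_begin + len(placeholder) - 1
    data_begin = text_end + 1
    data_end = data_begin + max(len(data_bytes), 1) - 1
    text = render_text(data_begin, data_end)
    # widths of the real offsets never exceed the 8-digit placeholder
    text = text.ljust(len(placeholder), b" ")

    header = (
        f"{'FCS3.1':<10s}"
        f"{text_begin:>8d}{text_end:>8d}"
        f"{data_begin:>8d}{data_end:>8d}"
        f"{0:>8d}{0:>8d}"
    ).encode("latin-1")
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b" " * (text_begin - _HEADER_LEN))
        fh.write(text)
        fh.write(data_bytes if data_bytes else b"\x00")
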
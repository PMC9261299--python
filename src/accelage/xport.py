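"""Minimal SAS transport (XPORT version 5) writer.

NHANES distributes its tables as SAS transport files.  pandas can *read*
that format (``pandas.read_sas``) but cannot write it, so the synthetic
cohort needs its own writer to exercise the XPT ingestion path.  Only the
features NHANES tables actually use are supported: one dataset member per
file, numeric (double) and fixed-width character variables.

Numeric values are stored in the IBM System/360 hexadecimal floating point
layout that the transport format mandates; missing numerics use the SAS
"." sentinel (0x2E padded with zeros).  Timestamps in the headers are fixed
so that identical inputs produce byte-identical files.
"""

from __future__ import annotations

import math
import struct
from os import PathLike

import numpy as np
import pandas as pd

__all__ = ["write_xport", "read_xport"]

# Fixed creation stamp: the transport format requires one, determinism
# requires it constant.
_STAMP = "01JAN20:00:00:00"

_LIB_HEADER = (
    "HEADER RECORD*******LIBRARY HEADER RECORD!!!!!!!"
    "000000000000000000000000000000  "
)
_MEMBER_HEADER = (
    "HEADER RECORD*******MEMBER  HEADER RECORD!!!!!!!"
    "000000000000000001600000000140  "
)
_DSCRPTR_HEADER = (
    "HEADER RECORD*******DSCRPTR HEADER RECORD!!!!!!!"
    "000000000000000000000000000000  "
)
_OBS_HEADER = (
    "HEADER RECORD*******OBS     HEADER RECORD!!!!!!!"
    "000000000000000000000000000000  "
)


def _ibm_from_float(value: float) -> bytes:
    """Encode an IEEE double as an 8-byte IBM hexadecimal float."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return b"\x2e" + b"\x00" * 7  # SAS numeric missing "."
    if value == 0:
        return b"\x00" * 8
    sign = 0x80 if value < 0 else 0x00
    mag = abs(float(value))
    if mag < 16.0**-65:  # below IBM range: underflow to zero
        return b"\x00" * 8
    # exponent e such that mag / 16**e lies in [1/16, 1)
    exp = math.floor(math.log(mag, 16)) + 1
    mantissa = mag / (16.0**exp)
    # guard against log/pow rounding at power-of-16 boundaries
    while mantissa >= 1.0:
        mantissa /= 16.0
        exp += 1
    while mantissa < 1.0 / 16.0:
        mantissa *= 16.0
        exp -= 1
    if exp > 63:
        raise ValueError(f"value {value!r} out of IBM float exponent range")
    mant_int = int(round(mantissa * (1 << 56)))
    if mant_int >= 1 << 56:  # rounding overflow
        mant_int >>= 4
        exp += 1
        if exp > 63:
            raise ValueError(f"value {value!r} out of IBM float exponent range")
    return bytes([sign | (exp + 64)]) + mant_int.to_bytes(7, "big")


def _ibm_from_float_array(values: np.ndarray) -> np.ndarray:
    """Vectorised IBM encoding: float64 array -> (n, 8) uint8 array."""
    a = np.asarray(values, dtype=np.float64)
    n = a.shape[0]
    out = np.zeros((n, 8), dtype=np.uint8)
    miss = np.isnan(a)
    out[miss, 0] = 0x2E
    nz = ~miss & (a != 0)
    if not nz.any():
        return out
    nz &= np.abs(a) >= 16.0**-65  # IBM underflow -> zero bytes
    if not nz.any():
        return out
    v = np.abs(a[nz])
    sign = np.where(a[nz] < 0, 0x80, 0x00).astype(np.uint8)
    m2, e2 = np.frexp(v)  # v = m2 * 2**e2, m2 in [0.5, 1)
    exp16 = np.ceil(e2 / 4.0).astype(np.int64)  # v = m16 * 16**exp16
    m16 = np.ldexp(m2, e2 - 4 * exp16)  # in (1/16, 1]
    mant = np.round(m16 * float(1 << 56)).astype(np.uint64)
    over = mant >= np.uint64(1 << 56)
    mant[over] >>= np.uint64(4)
    exp16[over] += 1
    exp16 = np.maximum(exp16, -64)
    if (exp16 > 63).any():
        raise ValueError("value out of IBM float exponent range")
    packed = (
        (np.uint64(sign).astype(np.uint64) | (exp16 + 64).astype(np.uint64))
        << np.uint64(56)
    ) | mant
    out[nz] = packed[:, None].view(np.uint8).reshape(-1, 8)[:, ::-1]
    return out


def _pad80(data: bytes, fill: bytes = b" ") -> bytes:
    rem = len(data) % 80
    return data if rem == 0 else data + fill * (80 - rem)


def _real_header(kind: str, name: str) -> bytes:
    line1 = f"SAS     {name:<8}{kind:<8}6.06    bsd4.2  ".ljust(64) + _STAMP
    line2 = _STAMP.ljust(80)
    return line1.encode("ascii") + line2.encode("ascii")


def _namestr(varnum: int, name: str, is_char: bool, length: int, pos: int) -> bytes:
    return struct.pack(
        ">hhhh8s40s8shhh2s8shhl52s",
        2 if is_char else 1,  # ntype
        0,  # nhfun
        length,  # nlng
        varnum,  # nvar0
        name.upper()[:8].ljust(8).encode("ascii"),
        name[:40].ljust(40).encode("ascii"),  # label: reuse name
        b"        ",
        0,
        0,
        0,
        b"  ",
        b"        ",
        0,
        0,
        pos,  # npos: byte offset within an observation
        b" " * 52,
    )


def write_xport(
    frame: pd.DataFrame, path: str | PathLike, name: str = "DATA"
) -> None:
    """Write ``frame`` as a single-member SAS transport v5 file.

    Object/string columns become fixed-width character variables (width =
    longest value, min 1); everything else is coerced to float64.  Column
    names must fit the 8-character SAS v5 limit.
    """
    name = name.upper()[:8]
    columns = list(frame.columns)
    for col in columns:
        if len(str(col)) > 8:
            raise ValueError(f"column name {col!r} exceeds 8 characters (XPT v5)")

    nrows = len(frame)
    specs: list[tuple[str, bool, int]] = []  # (name, is_char, width)
    encoded_cols: list[np.ndarray] = []  # each (nrows, width) uint8
    for col in columns:
        series = frame[col]
        if series.dtype == object or pd.api.types.is_string_dtype(series):
            vals = ["" if pd.isna(v) else str(v) for v in series]
            width = max([1] + [len(v) for v in vals])
            specs.append((str(col), True, width))
            raw = b"".join(v.ljust(width).encode("ascii") for v in vals)
            encoded_cols.append(
                np.frombuffer(raw, dtype=np.uint8).reshape(nrows, width)
            )
        else:
            vals = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
            specs.append((str(col), False, 8))
            encoded_cols.append(_ibm_from_float_array(vals))

    out = bytearray()
    out += _LIB_HEADER.encode("ascii")
    out += _real_header("SASLIB", "SAS")
    out += _MEMBER_HEADER.encode("ascii")
    out += _DSCRPTR_HEADER.encode("ascii")
    out += _real_header("SASDATA", name)

    nvars = len(specs)
    # field count sits in columns 54:58 of the namestr header record
    out += (
        "HEADER RECORD*******NAMESTR HEADER RECORD!!!!!!!"
        f"000000{nvars:04d}{'0' * 20}  "
    ).encode("ascii")
    namestrs = bytearray()
    pos = 0
    for i, (colname, is_char, width) in enumerate(specs, start=1):
        namestrs += _namestr(i, colname, is_char, width, pos)
        pos += width
    out += _pad80(bytes(namestrs))

    out += _OBS_HEADER.encode("ascii")
    if nrows:
        obs_bytes = np.hstack(encoded_cols).tobytes()  # row-major block
        record_length = sum(width for _, _, width in specs)
        out += obs_bytes + _tail_padding(obs_bytes, record_length, nrows)
    with open(path, "wb") as fh:
        fh.write(bytes(out))


def _decoded_record_count(total: int, last_card: bytes, record_length: int) -> int:
    """Record count as standard transport readers infer it.

    Readers have no explicit row count: they take the observation block
    length, subtract trailing 8-byte blank words of the final 80-byte card,
    and floor-divide by the record length.
    """
    if record_length > 80:
        return total // record_length
    blank_words = sum(
        last_card[i : i + 8] == b" " * 8 for i in range(0, 80, 8)
    )
    return (total - 8 * blank_words) // record_length


def _tail_padding(obs_bytes: bytes, record_length: int, nrows: int) -> bytes:
    """Pad the observation block to a card boundary without corrupting the
    inferred record count.

    Because readers classify any 8-aligned blank word of the last card as
    padding, a record whose character field ends in blanks can be mistaken
    for padding (or NUL fill can masquerade as extra records).  Search the
    small space of NUL/blank tail mixes — optionally with one extra card —
    for one that decodes back to exactly ``nrows``.
    """
    for extra in (0, 80):
        pad = (-len(obs_bytes)) % 80 + extra
        total = len(obs_bytes) + pad
        for blanks in range(0, pad + 1, 8):
            padding = b"\x00" * (pad - blanks) + b" " * blanks
            last_card = (obs_bytes + padding)[-80:]
            if _decoded_record_count(total, last_card, record_length) == nrows:
                return padding
    raise ValueError("cannot pad observation block unambiguously")


def read_xport(path: str | PathLike) -> pd.DataFrame:
    """Read an XPT file via pandas, decoding character columns to ``str``."""
    df = pd.read_sas(path, format="xport")
    for col in df.columns:
        if df[col].dtype.kind == "f":
            # pandas decodes the all-zero IBM float as 2**-260, not 0
            df.loc[df[col].abs() < 1e-70, col] = 0.0
        if df[col].dtype == object:
            df[col] = (
                df[col]
                .map(lambda v: v.decode("ascii") if isinstance(v, bytes) else v)
                .str.strip()
            )
    return df
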
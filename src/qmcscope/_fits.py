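"""Minimal FITS primary-HDU image I/O.

Covers exactly what the acquisition format needs: single primary HDU, 2-D or
3-D arrays, BITPIX 16 (unsigned via BZERO=32768), -32 and -64, plus scalar
header keywords.  FITS stores arrays big-endian in 2880-byte blocks with
80-character ASCII header cards; NAXIS1 is the fastest-varying (column) axis.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

BLOCK = 2880
CARD = 80

_BITPIX_DTYPE = {16: ">i2", -32: ">f4", -64: ">f8"}


def _format_value(value) -> str:
    if isinstance(value, bool):
        return "T" if value else "F"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    # string: FITS quotes with doubled internal quotes, min 8 chars
    s = str(value).replace("'", "''")
    return f"'{s:<8s}'"


def _card(key: str, value, comment: str = "") -> bytes:
    if len(key) > 8:
        raise ValueError(f"FITS keyword {key!r} longer than 8 characters")
    text = f"{key:<8s}= {_format_value(value):>20s}"
    if comment:
        text += f" / {comment}"
    return text[:CARD].ljust(CARD).encode("ascii")


def _pad(buf: bytes, fill: bytes = b" ") -> bytes:
    rem = len(buf) % BLOCK
    return buf if rem == 0 else buf + fill * (BLOCK - rem)


def write_image(path: str | Path, data: np.ndarray, header: dict | None = None) -> Path:
    """Write ``data`` (2-D or 3-D) as a primary-HDU FITS image."""
    path = Path(path)
    data = np.asarray(data)
    if data.ndim not in (2, 3):
        raise ValueError("only 2-D or 3-D images are supported")

    bzero = 0.0
    if data.dtype == np.uint16:
        bitpix, payload, bzero = 16, (data.astype(np.int32) - 32768).astype(">i2"), 32768.0
    elif np.issubdtype(data.dtype, np.integer):
        if data.min() < np.iinfo(np.int16).min or data.max() > np.iinfo(np.int16).max:
            raise ValueError("integer data out of 16-bit range")
        bitpix, payload = 16, data.astype(">i2")
    elif data.dtype == np.float32:
        bitpix, payload = -32, data.astype(">f4")
    else:
        bitpix, payload = -64, data.astype(">f8")

    cards = [
        _card("SIMPLE", True, "conforms to FITS standard"),
        _card("BITPIX", bitpix),
        _card("NAXIS", data.ndim),
    ]
    # NAXIS1 = fastest axis = last numpy axis
    for i, n in enumerate(reversed(data.shape), start=1):
        cards.append(_card(f"NAXIS{i}", int(n)))
    cards.append(_card("BSCALE", 1.0))
    cards.append(_card("BZERO", bzero))
    for key, value in (header or {}).items():
        cards.append(_card(key.upper()[:8], value))
    cards.append(b"END".ljust(CARD))

    with open(path, "wb") as fh:
        fh.write(_pad(b"".join(cards)))
        fh.write(_pad(payload.tobytes(), b"\x00"))
    return path


def _parse_value(raw: str):
    raw = raw.strip()
    if raw.startswith("'"):
        return raw.strip("'").rstrip()
    if raw == "T":
        return True
    if raw == "F":
        return False
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        return raw


def read_image(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a primary-HDU FITS image; returns (array, header dict).

    BITPIX 16 data with BZERO=32768 come back as uint16; other BITPIX as
    their native types.  Raises ``ValueError`` on truncated files.
    """
    path = Path(path)
    raw = path.read_bytes()
    header: dict = {}
    pos = 0
    done = False
    while not done:
        block = raw[pos : pos + BLOCK]
        if len(block) < BLOCK:
            raise ValueError(f"truncated FITS header in {path}")
        pos += BLOCK
        for i in range(0, BLOCK, CARD):
            card = block[i : i + CARD].decode("ascii", errors="replace")
            key = card[:8].strip()
            if key == "END":
                done = True
                break
            if not key or card[8:10] != "= ":
                continue
            value = card[10:].split(" / ")[0]
            header[key] = _parse_value(value)

    bitpix = header["BITPIX"]
    naxis = header["NAXIS"]
    shape = tuple(int(header[f"NAXIS{i}"]) for i in range(naxis, 0, -1))
    dtype = np.dtype(_BITPIX_DTYPE[bitpix])
    count = int(np.prod(shape))
    nbytes = count * dtype.itemsize
    if len(raw) - pos < nbytes:
        raise ValueError(f"truncated FITS data in {path}")
    data = np.frombuffer(raw[pos : pos + nbytes], dtype=dtype).reshape(shape)

    bzero = float(header.get("BZERO", 0.0))
    bscale = float(header.get("BSCALE", 1.0))
    if bitpix == 16 and bzero == 32768.0 and bscale == 1.0:
        data = (data.astype(np.int32) + 32768).astype(np.uint16)
    elif bzero != 0.0 or bscale != 1.0:
        data = data.astype(np.float64) * bscale + bzero
    else:
        data = data.astype(dtype.newbyteorder("="))
    return data, header
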
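"""Minimal FCS 3.1 writer/reader for list-mode float data.

Only the subset of the FCS 3.1 standard needed to exchange feature tables
with cytometry software is implemented: single data set, list mode,
little-endian float32 values, no ANALYSIS segment.  The reader parses the
standard byte layout (58-byte HEADER with ASCII segment offsets, delimited
TEXT segment, DATA segment) and is used to verify round trips.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_fcs", "read_fcs"]

_DELIM = "/"
_HEADER_LEN = 58


def _text_segment(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for k, v in keywords.items():
        parts.append(f"{k}{_DELIM}{v}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(path: str | Path, data: np.ndarray, names: list[str]) -> None:
    """Write ``data`` (n_events × n_params, float32) as FCS 3.1."""
    data = np.asarray(data, dtype="<f4")
    if data.ndim != 2:
        raise ValueError("data must be 2-D (events × parameters)")
    n_tot, n_par = data.shape
    if n_par != len(names):
        raise ValueError("one name per parameter required")
    if n_tot == 0 or n_par == 0:
        raise ValueError("empty data matrix")

    n_bytes = data.size * 4
    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        # placeholders, fixed width so TEXT length is offset-independent
        "$BEGINDATA": "%08d" % 0,
        "$ENDDATA": "%08d" % 0,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n_tot),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(names, start=1):
        clean = str(name).replace(_DELIM, "_")
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}N"] = clean
        finite = data[:, i - 1][np.isfinite(data[:, i - 1])]
        rng = float(finite.max()) if finite.size else 0.0
        keywords[f"$P{i}R"] = str(int(max(rng, 1.0)) + 1)

    text = _text_segment(keywords)
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + n_bytes - 1

    keywords["$BEGINDATA"] = "%08d" % data_begin
    keywords["$ENDDATA"] = "%08d" % data_end
    text = _text_segment(keywords)
    assert text_begin + len(text) - 1 == text_end  # fixed-width placeholders

    header = b"FCS3.1    " + (
        "%8d%8d%8d%8d%8d%8d"
        % (text_begin, text_end, data_begin, data_end, 0, 0)
    ).encode("ascii")
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes(order="C"))


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read an FCS file written in the supported subset.

    Returns (data matrix float32, parameter names).
    """
    raw = Path(path).read_bytes()
    if not raw.startswith(b"FCS3"):
        raise ValueError("not an FCS 3.x file")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_begin : text_end + 1].decode("ascii")
    delim = text[0]
    tokens = text[1:].split(delim)
    # keyword/value alternation; trailing empty token from final delimiter
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    kw = {tokens[i]: tokens[i + 1] for i in range(0, len(tokens) - 1, 2)}

    n_tot = int(kw["$TOT"])
    n_par = int(kw["$PAR"])
    if kw.get("$DATATYPE") != "F":
        raise ValueError("only $DATATYPE F supported")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    dtype = "<f4" if byteord == "1,2,3,4" else ">f4"
    data_begin = int(kw["$BEGINDATA"])
    data_end = int(kw["$ENDDATA"])
    buf = raw[data_begin : data_end + 1]
    data = np.frombuffer(buf, dtype=dtype).reshape(n_tot, n_par).astype(np.float32)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return data, names
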
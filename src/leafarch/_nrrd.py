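"""Minimal NRRD0004 reader/writer for label and scalar volumes.

Supports the subset of the format this package emits: raw or gzip encoding,
little-endian, C-contiguous payload with header ``sizes`` in NRRD's
fastest-axis-first convention (i.e. the reverse of the numpy shape).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np

_TYPE_TO_DTYPE = {
    "signed char": "i1",
    "int8": "i1",
    "uchar": "u1",
    "uint8": "u1",
    "short": "i2",
    "int16": "i2",
    "ushort": "u2",
    "uint16": "u2",
    "int": "i4",
    "int32": "i4",
    "uint": "u4",
    "uint32": "u4",
    "long long": "i8",
    "int64": "i8",
    "float": "f4",
    "double": "f8",
}

_DTYPE_TO_TYPE = {
    np.dtype(np.int8): "int8",
    np.dtype(np.uint8): "uint8",
    np.dtype(np.int16): "int16",
    np.dtype(np.uint16): "uint16",
    np.dtype(np.int32): "int32",
    np.dtype(np.uint32): "uint32",
    np.dtype(np.int64): "int64",
    np.dtype(np.float32): "float",
    np.dtype(np.float64): "double",
}


def write_nrrd(path: str | Path, data: np.ndarray, encoding: str = "raw") -> None:
    path = Path(path)
    data = np.ascontiguousarray(data)
    if data.dtype not in _DTYPE_TO_TYPE:
        raise ValueError(f"unsupported dtype for NRRD: {data.dtype}")
    if encoding not in ("raw", "gzip"):
        raise ValueError(f"unsupported NRRD encoding: {encoding}")
    header = [
        "NRRD0004",
        "# minimal NRRD written by leafarch",
        f"type: {_DTYPE_TO_TYPE[data.dtype]}",
        f"dimension: {data.ndim}",
        "sizes: " + " ".join(str(s) for s in data.shape[::-1]),
        f"encoding: {encoding}",
        "endian: little",
    ]
    payload = data.astype(data.dtype.newbyteorder("<")).tobytes(order="C")
    if encoding == "gzip":
        payload = gzip.compress(payload)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n\n").encode("ascii"))
        fh.write(payload)


def read_nrrd(path: str | Path) -> np.ndarray:
    path = Path(path)
    with open(path, "rb") as fh:
        blob = fh.read()
    head_end = blob.find(b"\n\n")
    if not blob.startswith(b"NRRD") or head_end < 0:
        raise ValueError(f"not a NRRD file: {path}")
    fields: dict[str, str] = {}
    for line in blob[:head_end].decode("ascii").splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, _, value = line.partition(":")
        fields[key.strip().lower()] = value.strip()
    try:
        dtype = np.dtype(_TYPE_TO_DTYPE[fields["type"]])
        sizes = [int(s) for s in fields["sizes"].split()]
        encoding = fields["encoding"]
    except KeyError as exc:
        raise ValueError(f"missing NRRD header field in {path}: {exc}") from exc
    if fields.get("endian", "little") == "big":
        dtype = dtype.newbyteorder(">")
    else:
        dtype = dtype.newbyteorder("<")
    payload = blob[head_end + 2 :]
    if encoding == "gzip":
        payload = gzip.decompress(payload)
    elif encoding != "raw":
        raise ValueError(f"unsupported NRRD encoding: {encoding}")
    arr = np.frombuffer(payload, dtype=dtype, count=int(np.prod(sizes)))
    # NRRD lists sizes fastest axis first; numpy C order is slowest first.
    return arr.reshape(sizes[::-1]).astype(dtype.newbyteorder("="))
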
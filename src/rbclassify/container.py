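"""Single-file binary container for index serialization.

Layout: magic, a length-prefixed JSON header describing the (nested)
metadata with placeholders for arrays, then the arrays in order in npy
format. Version and magic mismatches raise :class:`ContainerError`.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

MAGIC = b"RBCIDX1\n"
VERSION = 1


class ContainerError(ValueError):
    """Raised for unreadable, truncated, or incompatible index files."""


def _strip_arrays(obj, arrays: list):
    if isinstance(obj, np.ndarray):
        arrays.append(obj)
        return {"__array__": len(arrays) - 1}
    if isinstance(obj, dict):
        return {k: _strip_arrays(v, arrays) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_strip_arrays(v, arrays) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _restore_arrays(obj, arrays: list):
    if isinstance(obj, dict):
        if set(obj) == {"__array__"}:
            return arrays[obj["__array__"]]
        return {k: _restore_arrays(v, arrays) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_restore_arrays(v, arrays) for v in obj]
    return obj


def save_state(path, state: dict) -> None:
    arrays: list[np.ndarray] = []
    meta = _strip_arrays(state, arrays)
    header = json.dumps({"version": VERSION, "n_arrays": len(arrays), "state": meta}).encode()
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<Q", len(header)))
        fh.write(header)
        for arr in arrays:
            np.lib.format.write_array(fh, np.ascontiguousarray(arr), allow_pickle=False)


def load_state(path) -> dict:
    path = Path(path)
    try:
        fh = open(path, "rb")
    except OSError as exc:
        raise ContainerError(f"cannot open index file {path}: {exc}") from exc
    with fh:
        magic = fh.read(len(MAGIC))
        if magic != MAGIC:
            raise ContainerError(f"{path} is not an index file (bad magic)")
        raw = fh.read(8)
        if len(raw) != 8:
            raise ContainerError(f"{path} is truncated")
        (hlen,) = struct.unpack("<Q", raw)
        header = fh.read(hlen)
        if len(header) != hlen:
            raise ContainerError(f"{path} is truncated")
        try:
            meta = json.loads(header)
        except json.JSONDecodeError as exc:
            raise ContainerError(f"{path} has a corrupt header") from exc
        if meta.get("version") != VERSION:
            raise ContainerError(
                f"{path}: unsupported index version {meta.get('version')} (expected {VERSION})"
            )
        arrays = []
        try:
            for _ in range(meta["n_arrays"]):
                arrays.append(np.lib.format.read_array(fh, allow_pickle=False))
        except (ValueError, EOFError) as exc:
            raise ContainerError(f"{path} is truncated or corrupt") from exc
        return _restore_arrays(meta["state"], arrays)
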
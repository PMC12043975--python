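"""Deterministic checkpoint archives: JSON manifest + raw parameter bytes.

A checkpoint is a ZIP file (stored, not compressed, with a fixed timestamp)
holding ``manifest.json`` — config, hyperparameters, seed, loss trace,
transform/calibration payloads, and a tensor directory with shapes, dtypes
and byte offsets — and ``params.bin``, the concatenated little-endian array
bytes in manifest order.  save -> load -> save is byte-identical.
"""

from __future__ import annotations

import json
import zipfile

import numpy as np

FORMAT_VERSION = "1"
_EPOCH = (1980, 1, 1, 0, 0, 0)  # fixed zip timestamp for byte-identical saves


def save_checkpoint(path, manifest: dict, tensors: dict[str, np.ndarray]) -> None:
    """Write manifest + tensors; ``manifest`` must be JSON-serializable."""
    names = sorted(tensors)
    directory = []
    blobs = []
    offset = 0
    for name in names:
        arr = np.ascontiguousarray(tensors[name], dtype="<f8")
        raw = arr.tobytes()
        directory.append(
            {"name": name, "shape": list(arr.shape), "dtype": "<f8", "offset": offset,
             "nbytes": len(raw)}
        )
        blobs.append(raw)
        offset += len(raw)
    full = dict(manifest)
    full["format_version"] = FORMAT_VERSION
    full["tensors"] = directory
    payload = json.dumps(full, sort_keys=True, separators=(",", ":")).encode()
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        zf.writestr(zipfile.ZipInfo("manifest.json", date_time=_EPOCH), payload)
        zf.writestr(zipfile.ZipInfo("params.bin", date_time=_EPOCH), b"".join(blobs))


def load_checkpoint(path) -> tuple[dict, dict[str, np.ndarray]]:
    """Read back (manifest, tensors); arrays are bit-exact copies."""
    with zipfile.ZipFile(path, "r") as zf:
        manifest = json.loads(zf.read("manifest.json"))
        blob = zf.read("params.bin")
    tensors = {}
    for entry in manifest["tensors"]:
        start = entry["offset"]
        raw = blob[start : start + entry["nbytes"]]
        tensors[entry["name"]] = np.frombuffer(raw, dtype=entry["dtype"]).reshape(
            entry["shape"]
        ).copy()
    return manifest, tensors
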
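"""Versioned, byte-reproducible model archives.

A trained model is stored as a single zip archive holding one
``meta.json`` (scalars, config snapshot, format version) plus one
``.npy`` member per array.  Zip member timestamps are pinned so that
identical contents always produce identical bytes, which makes
"same seed, same data -> same archive" checkable at the byte level.
"""

from __future__ import annotations

import io
import json
import zipfile
from pathlib import Path

import numpy as np

FORMAT_VERSION = 1
_EPOCH = (1980, 1, 1, 0, 0, 0)


class ArchiveError(RuntimeError):
    """Raised for unreadable or version-incompatible archives."""


def _npy_bytes(arr: np.ndarray) -> bytes:
    buf = io.BytesIO()
    np.save(buf, np.ascontiguousarray(arr))
    return buf.getvalue()


def save_archive(path, meta: dict, arrays: dict[str, np.ndarray]) -> Path:
    """Write meta + arrays to a byte-reproducible zip archive."""
    path = Path(path)
    meta = dict(meta)
    meta["format_version"] = FORMAT_VERSION
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        def _write(name: str, data: bytes) -> None:
            info = zipfile.ZipInfo(name, date_time=_EPOCH)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            zf.writestr(info, data)

        _write("meta.json", json.dumps(meta, sort_keys=True, indent=1).encode())
        for name in sorted(arrays):
            _write(f"{name}.npy", _npy_bytes(arrays[name]))
    return path


def load_archive(path) -> tuple[dict, dict[str, np.ndarray]]:
    """Read back (meta, arrays); rejects unknown format versions."""
    path = Path(path)
    if not path.exists():
        raise ArchiveError(f"no such archive: {path}")
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            arrays = {}
            for name in zf.namelist():
                if name.endswith(".npy"):
                    arrays[name[:-4]] = np.load(io.BytesIO(zf.read(name)),
                                                allow_pickle=False)
    except (zipfile.BadZipFile, KeyError) as exc:
        raise ArchiveError(f"unreadable model archive {path}: {exc}") from exc
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise ArchiveError(
            f"archive format version {version} is incompatible with {FORMAT_VERSION}"
        )
    return meta, arrays
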
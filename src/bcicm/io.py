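"""Stable on-disk artifact contracts: atomic writes and the run manifest.

Every artifact is written temp-then-rename, and the manifest records a
SHA-256 content hash per artifact so reruns can be compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

from .errors import BcicmError


class IncompleteRunError(BcicmError):
    """An expected artifact was missing when the manifest was assembled."""


def _atomic_write(path: Path, data: bytes) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def sha256_of(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def write_results(
    artifacts: dict[str, str | bytes],
    out_dir: str | Path,
    *,
    config: dict | None = None,
    seeds: dict | None = None,
    timings: dict | None = None,
    warnings: list[str] | None = None,
) -> dict:
    """Write named artifacts plus a ``manifest.json`` and return the manifest.

    ``artifacts`` maps a file name to its full text (or bytes) content.
    Artifact hashes depend only on content, so identical inputs yield
    identical hashes on rerun.
    """
    from . import __version__

    if not artifacts:
        raise IncompleteRunError("no artifacts to write")
    out_dir = Path(out_dir)
    hashes: dict[str, str] = {}
    for name, content in artifacts.items():
        if content is None:
            raise IncompleteRunError(f"artifact {name!r} is missing")
        data = content.encode() if isinstance(content, str) else bytes(content)
        _atomic_write(out_dir / name, data)
        hashes[name] = sha256_of(data)
    manifest = {
        "tool": "bcicm",
        "version": __version__,
        "config": config or {},
        "seeds": seeds or {},
        "timings": timings or {},
        "warnings": warnings or [],
        "artifacts": hashes,
    }
    _atomic_write(out_dir / "manifest.json", json.dumps(manifest, indent=2).encode() + b"\n")
    return manifest
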
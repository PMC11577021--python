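"""Run-manifest and atomic-output helpers for the CLI."""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from contextlib import contextmanager
from datetime import datetime, timezone
from pathlib import Path


@contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to a temporary file and rename into place on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def sha256_of(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_run_manifest(
    out_path: str | Path,
    command: str,
    parameters: dict,
    inputs: list[str | Path],
    seed: int | None = None,
) -> None:
    """Record what produced a run's outputs: command, parameters, input digests."""
    from ciber import __version__

    manifest = {
        "command": command,
        "parameters": {k: (str(v) if isinstance(v, Path) else v) for k, v in parameters.items()},
        "inputs": {str(p): sha256_of(p) for p in inputs if p and Path(p).exists()},
        "version": __version__,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with atomic_write(out_path) as handle:
        json.dump(manifest, handle, indent=2)
        handle.write("\n")
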
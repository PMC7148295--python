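"""Run manifests: enough metadata next to every output to replay it."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any, Iterable


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_path: str | Path,
    *,
    command: str,
    config: dict[str, Any],
    seed: int | None,
    outputs: Iterable[str | Path],
    wall_time_s: float,
    n_failures: int = 0,
) -> Path:
    """Write ``<out_path>`` as JSON describing one CLI run.

    Contains the tool version, fully resolved configuration, root seed,
    SHA-256 checksum per output file, wall time and replicate-failure count —
    sufficient to re-run the command and compare outputs bit-for-bit.
    """
    from . import __version__

    manifest = {
        "tool": "multibatch",
        "version": __version__,
        "command": command,
        "config": config,
        "seed": seed,
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        "wall_time_s": round(wall_time_s, 3),
        "n_failures": n_failures,
        "written_at_unix": int(time.time()),
    }
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_path
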
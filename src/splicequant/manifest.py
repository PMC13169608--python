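"""Run manifests: provenance for every output directory."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

from . import __version__

MANIFEST_NAME = "manifest.json"


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, settings: dict,
                   inputs: Sequence[str] = (), seed: Optional[int] = None) -> Path:
    """Write the single manifest of an output directory.

    Records tool version, the command, settings, input digests, seed (for
    simulation runs) and a wall-clock timestamp.  The timestamp is the one
    run-specific field; all data outputs are deterministic given inputs and
    settings.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {
        "tool": "splicequant",
        "version": __version__,
        "command": command,
        "settings": settings,
        "inputs": [{"path": str(p), "sha256": sha256_of(p)} for p in inputs],
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / MANIFEST_NAME
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path
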
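"""Output writing and run manifests.

Every pipeline run emits CSV tables with stable column order plus one
JSON manifest (written last) recording the config snapshot, seed,
package version, timestamp and a checksummed inventory of the files
written.  Re-running with the same config and seed reproduces the
CSVs byte for byte (the manifest differs only in its timestamp).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__

logger = logging.getLogger("ojipscreen")

__all__ = ["RunManifest", "write_outputs"]


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    seed: int
    command: str = ""
    version: str = __version__
    timestamp: str = ""
    files: dict = field(default_factory=dict)  # name -> sha256

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "version": self.version,
            "seed": self.seed,
            "timestamp": self.timestamp,
            "config": self.config,
            "files": self.files,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    tables: dict[str, pd.DataFrame],
    manifest: RunManifest,
    out_dir: str | Path,
    *,
    json_tables: tuple[str, ...] = (),
) -> dict[str, str]:
    """Write CSV tables and the manifest; returns the file inventory.

    Tables are written in name order with ``index=False`` (stable
    headers and column order); names listed in ``json_tables`` are
    additionally written as record-oriented JSON.  The manifest JSON is
    written last so a complete manifest implies a complete run.
    Idempotent: rerunning with identical tables rewrites identical
    CSVs.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    inventory: dict[str, str] = {}
    for name in sorted(tables):
        path = out / f"{name}.csv"
        try:
            tables[name].to_csv(path, index=False)
        except OSError as exc:
            raise OSError(f"failed writing {path}: {exc}") from exc
        inventory[path.name] = _sha256(path)
        logger.info("wrote %s (%d rows)", path, len(tables[name]))
        if name in json_tables:
            jpath = out / f"{name}.json"
            jpath.write_text(tables[name].to_json(orient="records", indent=2))
            inventory[jpath.name] = _sha256(jpath)
    manifest.files = inventory
    manifest.timestamp = datetime.now(timezone.utc).isoformat()
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest.to_dict(), indent=2, default=str))
    logger.info("wrote %s", manifest_path)
    return inventory
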
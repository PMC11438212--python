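"""Run manifests: config hash, input checksums, seed, per-stage counts.

Two runs on identical inputs and config produce identical stage outputs;
the manifest records enough to verify that (timestamps excepted).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path


def _package_version() -> str:
    try:
        return version("dmrscreen")
    except PackageNotFoundError:
        return "unknown"


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def build_manifest(
    stage: str,
    inputs: dict[str, str | Path] | None = None,
    outputs: dict[str, str | Path] | None = None,
    config: dict | None = None,
    seed: int | None = None,
    stage_counts: dict[str, int] | None = None,
) -> dict:
    return {
        "tool": "dmrscreen",
        "version": _package_version(),
        "stage": stage,
        "seed": seed,
        "config_hash": sha256_text(json.dumps(config, sort_keys=True, default=str))
        if config is not None
        else None,
        "input_checksums": {
            name: sha256_file(p) for name, p in (inputs or {}).items()
        },
        "output_checksums": {
            name: sha256_file(p) for name, p in (outputs or {}).items()
        },
        "stage_counts": stage_counts or {},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
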
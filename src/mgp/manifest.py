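"""Lossless CSV manifests with provenance sidecars.

Every table written by a pipeline stage carries a ``<name>.meta.json``
sidecar recording the config hash, master seed and package version, so
any artifact can be regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__


def config_hash(config) -> str:
    """Stable hash of any JSON-serializable config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(df: pd.DataFrame, path, seed: int | None = None,
                   config: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")  # lossless floats
    meta = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config or {}),
        "columns": list(df.columns),
        "n_rows": int(len(df)),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_manifest(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return df, meta
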
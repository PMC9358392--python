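"""Tabular I/O with a small provenance header convention.

All tables are plain TSV. Output tables emitted by the pipeline carry
``# key<TAB>value`` comment lines (tool version, config hash, seed) before
the header row; :func:`read_table` skips them transparently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = ["read_table", "write_table", "config_hash", "write_json"]


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path, provenance: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}\t{value}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_json(obj, path, provenance: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"provenance": provenance or {}, **obj} if isinstance(obj, dict) else obj
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")


def config_hash(config) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
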
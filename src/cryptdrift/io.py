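"""Delimited-text output with provenance headers.

Every table the CLI writes starts with '#'-prefixed comment lines recording
the package version, the seed and a hash of the configuration, so a run can
be traced back to its inputs. ``read_table`` skips those lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = ["config_hash", "write_table", "read_table"]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration summary."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed=None, meta: dict | None = None) -> Path:
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# cryptdrift {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if meta:
        lines.append(f"# config_sha256={config_hash(meta)}")
        for key, value in sorted(meta.items()):
            lines.append(f"# {key}={value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
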
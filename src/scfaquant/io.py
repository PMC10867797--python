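"""File readers/writers with reproducibility headers.

Every CSV written by the pipeline starts with ``#``-prefixed header lines
recording the tool version, a hash of the run configuration, and the seed,
so any output file can be traced back to the exact run that produced it.
Readers skip those lines transparently. No timestamps are embedded:
re-running with identical inputs reproduces files byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _meta_lines(meta: Optional[dict]) -> str:
    from . import __version__

    lines = [f"# scfaquant {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}={value}")
    return "".join(line + "\n" for line in lines)


def write_csv(df: pd.DataFrame, path: Union[str, Path], meta: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(_meta_lines(meta))
        df.to_csv(fh, index=False)


def read_csv(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: dict, path: Union[str, Path], meta: Optional[dict] = None) -> None:
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"_meta": {"tool": f"scfaquant {__version__}", **(meta or {})}, **obj}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")


def read_json(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())
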
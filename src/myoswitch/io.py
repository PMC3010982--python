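"""Cell-table and manifest I/O.

Cell tables are plain UTF-8 CSV with a mandatory header, comma
separators and '.' decimals.  Two layouts exist:

* simulation snapshots: ``id,x,y,heading,P,phenotype,founder_class,step``
* microscopy-style tables: ``id,x,y,<channel>...``

Numeric fields are written at full shortest-round-trip precision so that
``read(write(t)) == t`` bit for bit.

Every CLI run emits a ``RunManifest`` JSON recording the resolved
configuration, seed, package version and SHA-256 hashes of all output
files, which suffices to reproduce the run exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "SIMULATION_COLUMNS",
    "write_cell_table",
    "read_cell_table",
    "RunManifest",
    "file_sha256",
]

SIMULATION_COLUMNS = ["id", "x", "y", "heading", "P", "phenotype", "founder_class", "step"]
_REQUIRED = ["id", "x", "y"]


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table as CSV at full numeric precision."""
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise FormatError(f"cell table lacks required column(s): {', '.join(missing)}")
    # shortest round-trip representation keeps read(write(t)) bitwise exact
    table.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a cell table CSV, checking the mandatory columns."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cell table {path} does not exist")
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise FormatError(
            f"cell table {path} lacks required column(s): {', '.join(missing)}"
        )
    return table


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    command: str
    config: dict[str, Any]
    seed: int
    package_version: str
    outputs: dict[str, str] = field(default_factory=dict)  # relative path -> sha256

    @classmethod
    def collect(
        cls,
        command: str,
        config: dict[str, Any],
        seed: int,
        out_dir: str | Path,
        outputs: Iterable[str | Path],
    ) -> "RunManifest":
        from . import __version__

        out_dir = Path(out_dir)
        hashes = {
            str(Path(p).relative_to(out_dir)): file_sha256(p) for p in outputs
        }
        return cls(
            command=command,
            config=config,
            seed=seed,
            package_version=__version__,
            outputs=hashes,
        )

    def write(self, path: str | Path) -> None:
        payload = {
            "command": self.command,
            "config": _jsonable(self.config),
            "seed": self.seed,
            "package_version": self.package_version,
            "outputs": self.outputs,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
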
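"""Delimited-table I/O, configuration and run manifests.

Tab-separated values are the canonical on-disk format (comma-separated
files are accepted on read); YAML for configuration, JSON for run
manifests.  Schemas are small named column sets validated on read and
write, with unit conventions carried in the documentation: time in hours,
medium amounts in nmol, concentrations in mM, fluxes in fmol/cell/h.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "read_mid_table",
    "write_manifest",
]

#: required columns per table kind
SCHEMAS: dict[str, list[str]] = {
    "timecourse": ["condition", "replicate", "time_h", "analyte", "value"],
    "dish_weights": ["time_h", "weight_g"],
    "mid": ["experiment", "metabolite", "mass_shift", "fraction"],
    "isotopologue": ["metabolite", "formula", "mass_shift", "area"],
    "flux_observations": ["reaction", "value", "sd"],
    "fluxmap": ["type", "id", "flux"],
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a delimited table and validate it against a named schema."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; options: {sorted(SCHEMAS)}")
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing} for schema {schema!r}")
    if schema == "mid":
        _validate_mid(df, path)
    return df


def _validate_mid(df: pd.DataFrame, path, tol: float = 1e-3) -> None:
    group_cols = [c for c in df.columns if c not in ("mass_shift", "fraction", "sd")]
    for keys, grp in df.groupby(group_cols, dropna=False):
        total = grp["fraction"].sum()
        if not np.isfinite(total) or abs(total - 1.0) > tol:
            raise ValueError(
                f"{path}: MID for {keys} sums to {total:.5f} (off-simplex by more than {tol})"
            )


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> None:
    if schema is not None:
        missing = [c for c in SCHEMAS[schema] if c not in df.columns]
        if missing:
            raise ValueError(f"cannot write {schema!r} table: missing {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_mid_table(path: str | Path) -> pd.DataFrame:
    return read_table(path, "mid")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    inputs: dict[str, str | Path],
    seed: int | None = None,
    extra: dict | None = None,
) -> dict:
    """Write a JSON run manifest with input checksums and versions."""
    from . import __version__

    manifest = {
        "package": {"name": "cellflux", "version": __version__},
        "python": platform.python_version(),
        "seed": seed,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in inputs.items()
            if Path(p).exists()
        },
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
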
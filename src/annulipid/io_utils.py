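"""CSV/metadata writers shared by the pipeline and CLI.

Tabular outputs are CSV with ``# key: value`` header comments recording the
parameters that produced them; density grids are a CSV matrix plus a YAML
sidecar with the bin geometry.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


def write_table(df: pd.DataFrame, path, meta: dict | None = None,
                index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=index)
    return path


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_grid(grid, path_prefix) -> tuple[Path, Path]:
    """DensityGrid -> <prefix>.csv (matrix, rows = x bins) + <prefix>.meta.yaml."""
    path_prefix = Path(path_prefix)
    path_prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = path_prefix.with_suffix(".csv")
    np.savetxt(csv_path, grid.values, delimiter=",")
    meta = {
        "species": grid.species,
        "leaflet": grid.leaflet,
        "x_edges_nm": [float(v) for v in grid.x_edges],
        "y_edges_nm": [float(v) for v in grid.y_edges],
        **{k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
           for k, v in grid.meta.items()},
    }
    meta_path = path_prefix.with_suffix(".meta.yaml")
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return csv_path, meta_path


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return path
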
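"""Readers, writers and run manifests.

Point tables are CSV with columns ``species, lon, lat``; rasters are ESRI
ASCII grids (see :mod:`phylogrid.grids`); trees are newick; region polygons
are WKT or GeoJSON; every pipeline stage writes a JSON manifest recording
the seed, the settings and SHA-256 hashes of its inputs so any output can
be reproduced from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import shapely

from .trees import read_tree  # noqa: F401  (re-exported reader)

__all__ = ["read_occurrences", "read_tree", "read_region", "write_manifest", "file_sha256"]

log = logging.getLogger(__name__)


def read_occurrences(path, extent=None) -> pd.DataFrame:
    """Read and validate a species occurrence table.

    Requires header columns ``species, lon, lat`` (extra columns are
    ignored), numeric coordinates in valid ranges.  Duplicate exact points
    are retained.  If ``extent`` (a GridSpec) is given, rows outside it are
    dropped with the count logged.
    """
    df = pd.read_csv(path)
    missing = {"species", "lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no occurrence rows")
    df = df[["species", "lon", "lat"]].copy()
    df["species"] = df["species"].astype(str).str.strip()
    for col, lim in (("lon", 180.0), ("lat", 90.0)):
        df[col] = pd.to_numeric(df[col], errors="raise")
        bad = df[col].abs() > lim
        if bad.any():
            raise ValueError(
                f"{path}: {int(bad.sum())} rows with {col} outside [-{lim}, {lim}] "
                f"(first offending value {df.loc[bad, col].iloc[0]})"
            )
    if extent is not None:
        inside = extent.contains(df["lon"].to_numpy(), df["lat"].to_numpy())
        if not inside.all():
            log.warning("dropping %d occurrences outside the model extent", (~inside).sum())
        df = df[inside].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"{path}: no occurrences inside the model extent")
    return df


def read_region(path_or_wkt) -> shapely.Geometry:
    """Region polygon from a WKT string, a .wkt file, or a GeoJSON file."""
    text = str(path_or_wkt)
    p = Path(text)
    if p.exists():
        text = p.read_text().strip()
    if text.lstrip().startswith("{"):
        obj = json.loads(text)
        if obj.get("type") == "FeatureCollection":
            obj = obj["features"][0]["geometry"]
        elif obj.get("type") == "Feature":
            obj = obj["geometry"]
        return shapely.geometry.shape(obj)
    return shapely.from_wkt(text)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, seed, settings: dict, inputs: dict) -> None:
    """Record what produced an output: seed, settings, input hashes."""
    manifest = {
        "seed": seed,
        "settings": settings,
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in inputs.items()
            if Path(p).exists()
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
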
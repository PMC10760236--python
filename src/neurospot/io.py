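"""Readers and writers for spot tables, geometry outlines and result tables.

Spot tables are tab-separated text, one row per detected spot, the format
spot-detection tools export. Coordinate columns may be nanometres
(``x_nm, y_nm, z_nm``) or pixels (``x_px, y_px, z_px``, converted with the
xy pixel size and z-step); the plain names ``x, y, z`` are accepted as
pixels. Geometry files are JSON polygon lists with vertices in pixels,
0-based, y increasing downward (image convention); everything is converted
to nm on read and all internal computation is in nm.

Result tables are written as CSV (reals at 12 significant digits, so a
write/read round-trip is exact at that precision) next to a JSON run
manifest recording the configuration, seed and package version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .errors import FormatError, GeometryError
from .geometry import DendriteBranch, NeuronGeometry
from .spots import SpotTable

__all__ = [
    "read_spot_table",
    "write_spot_table",
    "read_geometry",
    "write_geometry",
    "write_results",
    "read_results",
]

_FLOAT_FMT = "%.12g"


def _coordinate_columns(columns) -> tuple[dict, bool]:
    """Map axis -> column name; returns (mapping, in_pixels)."""
    cols = {c.strip().lower(): c for c in columns}
    for suffix, px in (("_nm", False), ("_px", True), ("", True)):
        names = {ax: cols.get(f"{ax}{suffix}") for ax in "xyz"}
        if names["x"] and names["y"]:
            return names, px
    raise FormatError(
        "missing coordinate columns: need x/y (suffix _nm or _px), "
        f"got {list(columns)}")


def read_spot_table(path, channel_label: str,
                    config: AnalysisConfig | None = None,
                    cell_id: str = "") -> SpotTable:
    """Read a tab-separated spot table into nm coordinates.

    Pixel-unit columns are scaled by ``config.pixel_size_xy`` (xy) and
    ``config.z_step`` (z). A missing z column yields z = 0 (2D data). An
    ``id`` column is honoured when present; otherwise ids are row numbers.
    """
    config = config or AnalysisConfig()
    path = Path(path)
    if not path.exists():
        raise FormatError(f"spot table not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty and df.columns.size == 0:
        raise FormatError(f"{path}: empty file, no header")
    names, in_pixels = _coordinate_columns(df.columns)
    icol = next((c for c in df.columns
                 if c.strip().lower() in ("intensity", "int", "amplitude")),
                None)
    if icol is None:
        raise FormatError(f"{path}: missing column 'intensity'")

    def numeric(col):
        out = pd.to_numeric(df[col], errors="coerce")
        bad = out.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, data row {row + 1}")
        return out.to_numpy(dtype=float)

    x = numeric(names["x"])
    y = numeric(names["y"])
    z = numeric(names["z"]) if names["z"] in df.columns else np.zeros(len(df))
    if in_pixels:
        x = x * config.pixel_size_xy
        y = y * config.pixel_size_xy
        z = z * config.z_step
    intensity = numeric(icol)
    ids = None
    idcol = next((c for c in df.columns if c.strip().lower() == "id"), None)
    if idcol:
        ids = numeric(idcol).astype(int)
    return SpotTable(
        xyz=np.column_stack([x, y, z]), intensity=intensity,
        channel_label=channel_label, cell_id=cell_id,
        source_file=str(path), ids=ids)


def write_spot_table(spots: SpotTable, path) -> None:
    """Write a spot table as tab-separated nm coordinates."""
    spots.to_frame().to_csv(path, sep="\t", index=False,
                            float_format=_FLOAT_FMT)


def read_geometry(path, pixel_size_xy: float | None = None) -> NeuronGeometry:
    """Read a JSON outline file into a :class:`NeuronGeometry` (nm).

    The file holds ``pixel_size_xy`` (nm), a ``soma`` vertex ring (pixels,
    explicitly closed: first vertex repeated last) and ``dendrites``, each
    with a ``skeleton`` polyline (pixels, soma end first) and
    ``half_width_px``. An open soma ring or a self-intersecting polygon is a
    :class:`GeometryError`; a skeleton not starting at the soma boundary is
    re-attached with a warning.
    """
    with open(path) as fh:
        data = json.load(fh)
    ps = float(data.get("pixel_size_xy", pixel_size_xy or 0) or 0)
    if ps <= 0:
        raise GeometryError(f"{path}: pixel_size_xy missing or <= 0")
    soma_px = np.asarray(data.get("soma", []), dtype=float)
    if soma_px.ndim != 2 or len(soma_px) < 4:
        raise GeometryError(f"{path}: soma needs >= 3 vertices plus closure")
    if not np.allclose(soma_px[0], soma_px[-1]):
        raise GeometryError(f"{path}: soma polygon is not closed "
                            "(first vertex must be repeated last)")
    branches = []
    for i, d in enumerate(data.get("dendrites", [])):
        sk = np.asarray(d["skeleton"], dtype=float) * ps
        hw = float(d.get("half_width_px", 0)) * ps
        if hw <= 0:
            raise GeometryError(f"{path}: dendrite {i} half_width_px must be > 0")
        branches.append(DendriteBranch(skeleton=sk, half_width=hw))
    return NeuronGeometry(soma=soma_px[:-1] * ps, branches=branches,
                          pixel_size_xy=ps)


def write_geometry(geometry: NeuronGeometry, path) -> None:
    """Write geometry back to the JSON outline dialect (pixels)."""
    ps = geometry.pixel_size_xy
    soma = np.asarray(geometry.soma.exterior.coords) / ps
    data = {
        "pixel_size_xy": ps,
        "soma": soma.tolist(),
        "dendrites": [
            {"skeleton": (b.skeleton / ps).tolist(),
             "half_width_px": b.half_width / ps}
            for b in geometry.branches
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")


def write_results(results: pd.DataFrame, path,
                  config: AnalysisConfig | None = None,
                  seed: int | None = None, **manifest_extra) -> None:
    """Write a result table as CSV plus a machine-readable run manifest.

    The manifest (``<path>.manifest.json``) records the analysis config,
    the RNG seed and the package version so a run can be reproduced.
    """
    path = Path(path)
    results.to_csv(path, index=False, float_format=_FLOAT_FMT)
    manifest = {
        "software": "neurospot",
        "version": __version__,
        "rng_seed": seed,
        "config": (config or AnalysisConfig()).to_dict(),
        "n_rows": int(len(results)),
        "columns": list(map(str, results.columns)),
    }
    manifest.update(manifest_extra)
    mpath = path.with_name(path.name + ".manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
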
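"""File formats: year-banded raster stacks, truth vectors, configs.

Raster stacks are multi-page TIFFs (one band per year) carrying a JSON
ImageDescription tag with the year axis, pixel size, and origin.  Truth
events are written as a GeoJSON FeatureCollection of pixel-boundary
polygons plus a CSV event table.  Configs round-trip through YAML or
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .config import RunConfig
from .synth import TruthLedger


def write_raster_stack(path, array: np.ndarray, years,
                       pixel_size_m: float = 30.0,
                       origin=(0.0, 0.0)) -> None:
    """Write a (year, row, col) stack as a multi-page TIFF with year tags."""
    array = np.asarray(array)
    if array.ndim != 3:
        raise ValueError("expected a (year, row, col) stack")
    years = [None if y is None else int(y) for y in years]
    if len(years) != array.shape[0]:
        raise ValueError("years length does not match band count")
    desc = json.dumps({"years": years, "pixel_size_m": float(pixel_size_m),
                       "origin": [float(origin[0]), float(origin[1])]})
    tifffile.imwrite(str(path), array, description=desc, metadata=None,
                     photometric="minisblack")


def read_raster_stack(path):
    """Read a year-banded stack; returns ``(array, years, meta)``.

    Raises if the year tags are missing, malformed, or mismatched with
    the band count, naming the offending band where possible.
    """
    with tifffile.TiffFile(str(path)) as tf:
        array = tf.asarray()
        desc = tf.pages[0].description
    if array.ndim == 2:
        array = array[None]
    try:
        meta = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        meta = {}
    years = meta.get("years")
    if years is None:
        raise ValueError(f"{path}: stack has no year tags")
    if len(years) != array.shape[0]:
        raise ValueError(
            f"{path}: {array.shape[0]} bands but {len(years)} year tags")
    for i, y in enumerate(years):
        if y is None:
            raise ValueError(f"{path}: band {i} has no year tag")
    return array, np.asarray(years, dtype=int), meta


def _pixel_polygon(pixels: np.ndarray, pixel_size_m: float):
    boxes = [box(c * pixel_size_m, -(r + 1) * pixel_size_m,
                 (c + 1) * pixel_size_m, -r * pixel_size_m)
             for r, c in pixels]
    return unary_union(boxes)


def write_truth(truth: TruthLedger, outdir, pixel_size_m: float = 30.0,
                pixel_area_ha: float = 0.09) -> None:
    """Write the truth ledger: events.geojson + events.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    features = []
    for ev in truth.events:
        geom = _pixel_polygon(ev.pixels, pixel_size_m)
        features.append({
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {
                "event_id": ev.event_id, "class": ev.cls, "year": ev.year,
                "n_pixels": ev.n_pixels,
                "area_ha": ev.n_pixels * pixel_area_ha,
            },
        })
    with open(outdir / "events.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    truth.event_table().to_csv(outdir / "events.csv", index=False)


def write_config(config: RunConfig, path) -> None:
    path = Path(path)
    data = config.to_dict()
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(data, fh, sort_keys=False)
        else:
            json.dump(data, fh, indent=2)


def read_config(path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        data = (yaml.safe_load(fh) if path.suffix in (".yaml", ".yml")
                else json.load(fh))
    return RunConfig.from_dict(data)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")
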
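"""Field CSV / sidecar-JSON readers and writers.

A field on disk is a CSV with header
``x_um,y_um[,diameter_um][,area_um2][,feret_max_um][,feret_min_um][,edge_included]``
plus a sidecar JSON carrying ``field_id``, ``quadrant``, ``region_index`` and
the window geometry.  Floats are serialized with fixed precision so that
re-running an analysis reproduces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import MosaicField, Window

__all__ = ["read_field", "write_field", "field_to_frame", "FLOAT_FORMAT"]

FLOAT_FORMAT = "%.6f"

_OPT_COLUMNS = {
    "diameter_um": "diameter",
    "area_um2": "cross_section_area",
    "feret_max_um": "feret_max",
    "feret_min_um": "feret_min",
}


def field_to_frame(field: MosaicField) -> pd.DataFrame:
    cols = {"x_um": field.x, "y_um": field.y}
    for col, attr in _OPT_COLUMNS.items():
        val = getattr(field, attr)
        if val is not None:
            cols[col] = val
    if field.edge_included is not None:
        cols["edge_included"] = field.edge_included.astype(int)
    return pd.DataFrame(cols)


def write_field(field: MosaicField, csv_path, meta_path=None) -> None:
    csv_path = Path(csv_path)
    field_to_frame(field).to_csv(csv_path, index=False, float_format=FLOAT_FORMAT)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".json")
    meta = {
        "field_id": field.field_id,
        "quadrant": field.quadrant,
        "region_index": field.region_index,
        "window": {
            "x_min": field.window.x_min,
            "y_min": field.window.y_min,
            "side_x": field.window.side_x,
            "side_y": field.window.side_y,
        },
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_field(csv_path, meta_path=None) -> MosaicField:
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".json")
    meta_path = Path(meta_path)
    df = pd.read_csv(csv_path)
    if "x_um" not in df.columns or "y_um" not in df.columns:
        raise ValueError(f"{csv_path}: field CSV must have x_um and y_um columns")
    window = Window()
    field_id, quadrant, region = csv_path.stem, None, None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        win = meta.get("window", {})
        window = Window(
            x_min=win.get("x_min", 0.0),
            y_min=win.get("y_min", 0.0),
            side_x=win.get("side_x", Window().side_x),
            side_y=win.get("side_y", Window().side_y),
        )
        field_id = meta.get("field_id", field_id)
        quadrant = meta.get("quadrant")
        region = meta.get("region_index")
    kwargs = {}
    for col, attr in _OPT_COLUMNS.items():
        if col in df.columns:
            kwargs[attr] = df[col].to_numpy(dtype=float)
    edge = (
        df["edge_included"].to_numpy().astype(bool)
        if "edge_included" in df.columns
        else np.zeros(len(df), dtype=bool)
    )
    return MosaicField(
        x=df["x_um"].to_numpy(dtype=float),
        y=df["y_um"].to_numpy(dtype=float),
        window=window,
        field_id=field_id,
        quadrant=quadrant,
        region_index=region,
        edge_included=edge,
        **kwargs,
    )
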
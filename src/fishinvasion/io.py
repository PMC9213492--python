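"""Reading and writing the pipeline's interchange formats.

Communities travel as long-format CSV (site_id, species, origin,
moyle_class, body_size_class); sites and barriers as GeoJSON point
collections; reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import REQUIRED_COLUMNS


def read_community_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"community CSV missing columns: {missing}")
    return df


def write_community_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def sites_to_geojson(sites: pd.DataFrame, path: str | Path | None = None) -> dict:
    """Site table (site_id, x_km, y_km, covariates) as a GeoJSON point layer."""
    features = []
    covars = [c for c in sites.columns if c not in ("site_id", "x_km", "y_km")]
    for _, row in sites.iterrows():
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(row["x_km"]), float(row["y_km"])],
                },
                "properties": {
                    "site_id": row["site_id"],
                    **{c: _jsonable(row[c]) for c in covars},
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(doc))
    return doc


def sites_from_geojson(path: str | Path) -> pd.DataFrame:
    doc = json.loads(Path(path).read_text())
    rows = []
    for feat in doc["features"]:
        x, y = feat["geometry"]["coordinates"]
        rows.append({"x_km": x, "y_km": y, **feat["properties"]})
    df = pd.DataFrame(rows)
    front = ["site_id", "x_km", "y_km"]
    return df[front + [c for c in df.columns if c not in front]]


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_default))


def _default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON-serializable: {type(o)}")
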
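"""Readers and writers for the package's plain-text interchange formats.

Site measurements and addresses travel as comma-separated tables with fixed
headers; configs are YAML or JSON; sites can be exported as GeoJSON points.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

SITE_COLUMNS = ["site_id", "lon", "lat", "medium", "chemical", "concentration"]
ADDRESS_COLUMNS = ["participant_id", "address_class", "lon", "lat"]

__all__ = [
    "SITE_COLUMNS",
    "ADDRESS_COLUMNS",
    "read_sites",
    "read_addresses",
    "read_participants",
    "load_config",
    "sites_to_geojson",
]


def _require(df: pd.DataFrame, columns: list[str], what: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing columns {missing}; header must "
                         f"contain {columns}")
    return df


def read_sites(path) -> pd.DataFrame:
    """Site-measurement table: site_id, lon, lat, medium, chemical, concentration."""
    return _require(pd.read_csv(path, float_precision="round_trip"), SITE_COLUMNS, "site-measurement")


def read_addresses(path) -> pd.DataFrame:
    """Address table: participant_id, address_class, lon, lat."""
    return _require(pd.read_csv(path, float_precision="round_trip"), ADDRESS_COLUMNS, "address")


def read_participants(path) -> pd.DataFrame:
    """Participant table: participant_id, ana (0/1), personal covariates."""
    return _require(pd.read_csv(path, float_precision="round_trip"), ["participant_id", "ana"], "participant")


def load_config(path) -> dict:
    """YAML (or JSON — a YAML subset) pipeline/simulation config."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must parse to a mapping")
    return cfg


def sites_to_geojson(sites: pd.DataFrame, path=None) -> dict:
    """Export sites as a GeoJSON FeatureCollection of points (WGS84)."""
    feats = []
    for _, row in sites.iterrows():
        props = {k: row[k] for k in sites.columns if k not in ("lon", "lat")}
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [float(row["lon"]), float(row["lat"])]},
                "properties": {k: (v.item() if hasattr(v, "item") else v)
                               for k, v in props.items()},
            }
        )
    fc = {"type": "FeatureCollection", "features": feats}
    if path is not None:
        Path(path).write_text(json.dumps(fc) + "\n")
    return fc
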
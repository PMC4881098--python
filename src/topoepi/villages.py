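"""Village polygon layer and GeoJSON I/O.

Villages are administrative polygons with stable string ids; their area
``A`` (km²) enters the RDLS index directly. Geometry is handled by
shapely; files are GeoJSON FeatureCollections with a ``village_id``
property on each feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import explain_validity

from topoepi.errors import DataError


@dataclass
class VillageSet:
    """Ordered collection of village polygons.

    Attributes
    ----------
    ids : list of str
        Unique village identifiers, in a fixed order that every
        downstream table and weights matrix follows.
    geometries : list of shapely geometry
        One (multi)polygon per id, valid and non-empty.
    crs_note : str
        Identifier of the projected CRS (coordinates in meters).
    """

    ids: list[str]
    geometries: list[BaseGeometry]
    crs_note: str = "local-projected-meters"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.geometries):
            raise DataError("ids and geometries must have equal length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise DataError(f"duplicate village ids: {dupes}")
        for vid, geom in zip(self.ids, self.geometries):
            if geom.is_empty:
                raise DataError(f"village {vid} has empty geometry")
            if not geom.is_valid:
                raise DataError(
                    f"village {vid} geometry invalid: {explain_validity(geom)}"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def areas_km2(self) -> np.ndarray:
        """Vector polygon areas in km² (coordinates are meters)."""
        return np.array([g.area for g in self.geometries]) / 1e6

    def centroids(self) -> np.ndarray:
        """(n, 2) array of centroid coordinates."""
        return np.array([[g.centroid.x, g.centroid.y] for g in self.geometries])

    def subset(self, keep_ids) -> "VillageSet":
        keep = set(keep_ids)
        pairs = [(i, g) for i, g in zip(self.ids, self.geometries) if i in keep]
        missing = keep - {i for i, _ in pairs}
        if missing:
            raise DataError(f"unknown village ids: {sorted(missing)}")
        return VillageSet(
            ids=[i for i, _ in pairs],
            geometries=[g for _, g in pairs],
            crs_note=self.crs_note,
        )


def write_villages_geojson(
    villages: VillageSet,
    path: str | Path,
    properties: dict[str, dict] | None = None,
) -> None:
    """Write villages (plus optional per-id property dicts) as GeoJSON."""
    features = []
    for vid, geom in zip(villages.ids, villages.geometries):
        props = {"village_id": vid}
        if properties is not None:
            props.update(properties.get(vid, {}))
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(geom)}
        )
    doc = {
        "type": "FeatureCollection",
        "crs_note": villages.crs_note,
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_villages_geojson(path: str | Path) -> VillageSet:
    """Read a GeoJSON FeatureCollection with ``village_id`` properties."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise DataError(f"{path} is not a GeoJSON FeatureCollection")
    ids, geoms = [], []
    for k, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        vid = props.get("village_id")
        if vid is None:
            raise DataError(f"feature {k} in {path} lacks a village_id property")
        ids.append(str(vid))
        geoms.append(shape(feat["geometry"]))
    return VillageSet(
        ids=ids,
        geometries=geoms,
        crs_note=doc.get("crs_note", "local-projected-meters"),
    )
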
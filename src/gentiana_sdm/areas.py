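"""Protected-area polygons and their GeoJSON round-trip."""

from __future__ import annotations

import json
from dataclasses import dataclass

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

DESIGNATIONS = ("natura2000", "ramsar")


@dataclass(frozen=True)
class ProtectedArea:
    designation: str
    name: str
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            raise ValueError(f"invalid polygon for {self.name}")


def write_geojson(areas: list[ProtectedArea], path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"designation": a.designation, "name": a.name},
            "geometry": mapping(a.geometry),
        }
        for a in areas
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path) -> list[ProtectedArea]:
    with open(path) as fh:
        collection = json.load(fh)
    return [
        ProtectedArea(
            designation=f["properties"]["designation"],
            name=f["properties"]["name"],
            geometry=shape(f["geometry"]),
        )
        for f in collection["features"]
    ]
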
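"""Shared containers: multi-channel images and polygonal regions of interest.

Conventions used throughout the package
---------------------------------------
* Images are 2-D ``numpy`` arrays indexed ``[row, col]``.
* ROI polygon vertices are ``(x, y)`` pairs in 0-based pixel coordinates,
  with ``x = col`` and ``y = row`` (GeoJSON-style axis order).
* Physical scale always comes from ``pixel_size_um`` metadata; nothing in
  the package assumes an acquisition pixel size.
* Point-in-polygon queries are boundary inclusive; rasterised ROI masks use
  :func:`skimage.draw.polygon2mask` (a single convention used consistently
  for both sides of every area comparison).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import tifffile
from shapely.geometry import Point, Polygon
from skimage.draw import polygon2mask

__all__ = ["MultiChannelImage", "RegionOfInterest", "LabelMap"]

#: Integer-labelled segmentation of one channel; 0 is background.
LabelMap = np.ndarray


@dataclass
class MultiChannelImage:
    """Named 2-D intensity channels sharing geometry and a physical pixel size.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``"DAPI"``, ``"Emcn"``) to a 2-D
        non-negative float array. All channels must share a shape.
    pixel_size_um
        Physical edge length of one pixel in micrometres. Must be positive.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if not self.channels:
            raise ValueError("image must contain at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on geometry: {sorted(shapes)}")
        self.channels = {name: np.asarray(ch, dtype=np.float32) for name, ch in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(f"unknown channel {name!r}; available: {sorted(self.channels)}") from None

    # ---- I/O ------------------------------------------------------------

    def to_tiff(self, path: str | Path) -> None:
        """Write a multi-page TIFF, one page per channel, names in metadata."""
        names = list(self.channels)
        stack = np.stack([self.channels[n] for n in names])
        meta = {"channel_names": names, "pixel_size_um": self.pixel_size_um}
        tifffile.imwrite(str(path), stack, description=json.dumps(meta))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "MultiChannelImage":
        with tifffile.TiffFile(str(path)) as tif:
            stack = tif.asarray()
            meta = json.loads(tif.pages[0].description)
        names = meta["channel_names"]
        if stack.ndim == 2:
            stack = stack[None]
        return cls(
            channels={n: stack[i] for i, n in enumerate(names)},
            pixel_size_um=float(meta["pixel_size_um"]),
        )


#: ROI names used by the analysis; ``custom`` covers everything else.
ROI_NAMES = (
    "gap",
    "gap_adjacent",
    "bone_marrow",
    "emcn_hi",
    "emcn_lo",
    "proximal_adjacent",
    "distal_adjacent",
    "homeostatic_control",
    "custom",
)


@dataclass
class RegionOfInterest:
    """A named simple polygon in pixel coordinates.

    ``provenance`` distinguishes hand-annotated ROIs from ones derived by
    the package (e.g. Emcn-hi regions thresholded from smoothed intensity).
    """

    name: str
    vertices: np.ndarray  # (N, 2) array of (x, y) pixel coordinates
    provenance: str = "annotated"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("ROI needs at least 3 (x, y) vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError(f"ROI {self.name!r} polygon is not simple/valid")
        if poly.area <= 0:
            raise ValueError(f"ROI {self.name!r} has zero area")
        if self.provenance not in ("annotated", "derived"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_px(self) -> float:
        return self.polygon.area

    def contains(self, x: float, y: float) -> bool:
        """Boundary-inclusive point-in-polygon test."""
        return bool(self.polygon.covers(Point(x, y)))

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterise to a boolean mask of the given image shape."""
        # polygon2mask wants (row, col) vertex order
        return polygon2mask(shape, self.vertices[:, ::-1])

    # ---- GeoJSON --------------------------------------------------------

    def to_geojson_feature(self) -> dict:
        ring = self.vertices.tolist()
        if ring[0] != ring[-1]:
            ring = ring + [ring[0]]
        return {
            "type": "Feature",
            "properties": {"name": self.name, "provenance": self.provenance},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        }

    @classmethod
    def from_geojson_feature(cls, feature: Mapping) -> "RegionOfInterest":
        ring = feature["geometry"]["coordinates"][0]
        verts = np.asarray(ring, dtype=float)
        if len(verts) > 3 and np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        props = feature.get("properties", {})
        return cls(
            name=props.get("name", "custom"),
            vertices=verts,
            provenance=props.get("provenance", "annotated"),
        )


def rois_to_geojson(rois: Iterable[RegionOfInterest], path: str | Path) -> None:
    fc = {"type": "FeatureCollection", "features": [r.to_geojson_feature() for r in rois]}
    Path(path).write_text(json.dumps(fc, indent=1))


def rois_from_geojson(path: str | Path) -> dict[str, RegionOfInterest]:
    fc = json.loads(Path(path).read_text())
    rois = [RegionOfInterest.from_geojson_feature(f) for f in fc["features"]]
    return {r.name: r for r in rois}
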
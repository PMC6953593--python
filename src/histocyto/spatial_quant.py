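"""ROI-based quantification and vessel-proximity banding.

Implements the region measurements used throughout the analysis: object
counts per phenotype inside polygonal ROIs, ROI mean intensity normalized
to the image maximum, positive-pixel area fractions, and distance-banded
proximity of cells to the endothelium (direct <= 3.5 um, distant > 7 um,
with the intermediate band retained so the three bands always partition the
population). Distances are Euclidean pixel distances from the exact
distance transform; a cell's distance is the minimum over its object pixels
(or its centroid distance, configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator
from scipy.ndimage import distance_transform_edt, gaussian_filter
from shapely.geometry import MultiPoint, Polygon
from skimage.filters import threshold_multiotsu
from skimage.measure import find_contours, label as cc_label

from .core import RegionOfInterest
from .phenotyping import CellTable
from .segmentation import SegmentationConfig, threshold_map

__all__ = [
    "ProximityConfig",
    "ProximityResult",
    "gap_roi_from_landmarks",
    "count_objects_in_roi",
    "mean_intensity_normalized",
    "positive_pixel_area_fraction",
    "proximity_bands",
    "derive_emcn_regions",
    "RegionOfInterest",
]

BANDS = ("direct", "intermediate", "distant")


class ProximityConfig(BaseModel):
    """Distance bands around the reference (endothelium) mask.

    ``direct_max_um`` / ``distant_min_um`` are the published cut points
    (<= 3.5 um: within about half a nucleus diameter; > 7 um: beyond one
    cell layer). ``inclusive`` controls whether the direct band uses <= or
    strict < at the cut (the two readings differ by less than a pixel).
    """

    direct_max_um: float = 3.5
    distant_min_um: float = 7.0
    reference_channel: str = "Emcn"
    distance_basis: str = "object_min"  # "object_min" | "centroid"
    inclusive: bool = True

    @model_validator(mode="after")
    def _check(self):
        if not 0 < self.direct_max_um < self.distant_min_um:
            raise ValueError("need 0 < direct_max_um < distant_min_um")
        if self.distance_basis not in ("object_min", "centroid"):
            raise ValueError("distance_basis must be 'object_min' or 'centroid'")
        return self


#: Per-ROI, per-phenotype band counts with fractions normalized to the
#: population total (DataFrame with columns roi, phenotype, n_direct,
#: n_intermediate, n_distant, n_total, frac_direct, frac_intermediate,
#: frac_distant).
ProximityResult = pd.DataFrame


# ---------------------------------------------------------------------------
# ROIs from landmarks
# ---------------------------------------------------------------------------


def gap_roi_from_landmarks(
    cortical_end_points: Sequence[Sequence[float]],
    cut_lines: Optional[Sequence[Sequence[Sequence[float]]]] = None,
    void_outline: Optional[Sequence[Sequence[float]]] = None,
) -> RegionOfInterest:
    """Construct the fracture-gap ROI from section landmarks.

    The gap is the convex hull of the cortical end points and osteotomy-cut
    endpoints (a rectangle/quadrilateral in practice), minus the lens-void
    outline when one is present in the section. Collinear landmarks raise
    ``ValueError``.
    """
    pts = [tuple(map(float, p)) for p in cortical_end_points]
    for line in cut_lines or []:
        pts.extend(tuple(map(float, p)) for p in line)
    if len(pts) < 3:
        raise ValueError("need at least 3 landmark points")
    hull = MultiPoint(pts).convex_hull
    if not isinstance(hull, Polygon) or hull.area <= 0:
        raise ValueError("landmarks are collinear/degenerate; cannot form a gap region")
    poly = hull
    if void_outline is not None:
        poly = hull.difference(Polygon([tuple(map(float, p)) for p in void_outline]))
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        if poly.is_empty or poly.area <= 0:
            raise ValueError("lens void covers the whole landmark hull")
        if list(poly.interiors):
            raise ValueError(
                "lens void lies strictly inside the landmark hull; the gap "
                "region must be a simple polygon (place the void on its edge)"
            )
    verts = np.asarray(poly.exterior.coords[:-1], dtype=float)
    return RegionOfInterest(name="gap", vertices=verts, provenance="derived")


# ---------------------------------------------------------------------------
# counting and intensity measures
# ---------------------------------------------------------------------------


def count_objects_in_roi(cells: CellTable, roi: RegionOfInterest) -> dict[str, int]:
    """Per-phenotype counts of cells whose centroid lies in the ROI
    (boundary inclusive). Includes an ``"all"`` total."""
    counts: dict[str, int] = {"all": 0}
    if len(cells) == 0:
        return counts
    poly = roi.polygon
    from shapely.geometry import Point

    for _, row in cells.table.iterrows():
        if poly.covers(Point(row["centroid_x_px"], row["centroid_y_px"])):
            counts["all"] += 1
            counts[row["phenotype"]] = counts.get(row["phenotype"], 0) + 1
    return counts


def mean_intensity_normalized(
    channel: np.ndarray, rois: Iterable[RegionOfInterest]
) -> dict[str, float]:
    """Per-ROI mean intensity divided by the whole-image maximum.

    An all-zero image has no maximum to normalize by; every ROI then
    reports 0 with a warning.
    """
    channel = np.asarray(channel, dtype=float)
    img_max = float(channel.max())
    out = {}
    for roi in rois:
        mask = roi.mask(channel.shape)
        if img_max == 0:
            warnings.warn("image maximum is 0; normalized mean intensity reported as 0")
            out[roi.name] = 0.0
        elif not mask.any():
            out[roi.name] = 0.0
        else:
            out[roi.name] = float(channel[mask].mean() / img_max)
    return out


def positive_pixel_area_fraction(
    channel: np.ndarray,
    roi: RegionOfInterest,
    threshold_strategy: float | SegmentationConfig | None = None,
    pixel_size_um: float = 1.0,
) -> float:
    """Fraction of ROI pixels above threshold.

    ``threshold_strategy`` is a fixed intensity, a ``SegmentationConfig``
    (reusing the segmentation thresholding, computed on the whole image), or
    ``None`` for the default three-class global Otsu. A channel with no
    attainable threshold (constant) yields 0.
    """
    channel = np.asarray(channel, dtype=float)
    mask = roi.mask(channel.shape)
    if not mask.any():
        return 0.0
    if isinstance(threshold_strategy, (int, float)):
        pos = channel > float(threshold_strategy)
    else:
        cfg = threshold_strategy or SegmentationConfig(threshold_mode="global")
        tm = threshold_map(channel, cfg, pixel_size_um)
        if tm is None:
            return 0.0
        pos = channel > tm
    return float(pos[mask].mean())


# ---------------------------------------------------------------------------
# proximity banding
# ---------------------------------------------------------------------------


def _band(d_um: float, cfg: ProximityConfig) -> str:
    direct = d_um <= cfg.direct_max_um if cfg.inclusive else d_um < cfg.direct_max_um
    if direct:
        return "direct"
    if d_um > cfg.distant_min_um:
        return "distant"
    return "intermediate"


def cell_distances_um(
    cells: CellTable, reference_mask: np.ndarray, config: ProximityConfig
) -> pd.Series:
    """Distance of every cell to the nearest reference pixel, in um."""
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference mask is empty; distances are undefined")
    dist_px = distance_transform_edt(~reference_mask)
    s = cells.pixel_size_um
    out = {}
    for cid in cells.table.index:
        if config.distance_basis == "object_min":
            d = float(dist_px[cells.labels == cid].min())
        else:
            r = cells.table.loc[cid]
            d = float(dist_px[int(round(r["centroid_y_px"])), int(round(r["centroid_x_px"]))])
        out[cid] = d * s
    return pd.Series(out, name="distance_um")


def proximity_bands(
    cells: CellTable,
    reference_mask: np.ndarray,
    config: ProximityConfig = ProximityConfig(),
    roi: Optional[RegionOfInterest] = None,
) -> ProximityResult:
    """Band cells by distance to the endothelium within an ROI.

    Returns one row per phenotype (plus ``"all"``) with band counts and
    fractions normalized to the population total; the three bands always
    partition the population. An empty reference mask is an error.
    """
    distances = cell_distances_um(cells, reference_mask, config)
    table = cells.table
    if roi is not None:
        poly = roi.polygon
        from shapely.geometry import Point

        in_roi = [
            poly.covers(Point(r["centroid_x_px"], r["centroid_y_px"]))
            for _, r in table.iterrows()
        ]
        table = table[np.asarray(in_roi, dtype=bool)] if len(table) else table
    roi_name = roi.name if roi is not None else "image"

    rows = []
    groups: dict[str, list[int]] = {"all": list(table.index)}
    for cid, pheno in table["phenotype"].items() if len(table) else []:
        groups.setdefault(pheno, []).append(cid)
    for pheno, ids in groups.items():
        tally = {b: 0 for b in BANDS}
        for cid in ids:
            tally[_band(float(distances.loc[cid]), config)] += 1
        n_total = len(ids)
        row = {"roi": roi_name, "phenotype": pheno, "n_total": n_total}
        for b in BANDS:
            row[f"n_{b}"] = tally[b]
            row[f"frac_{b}"] = tally[b] / n_total if n_total else 0.0
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["roi", "phenotype", "n_total"]
        + [f"n_{b}" for b in BANDS]
        + [f"frac_{b}" for b in BANDS],
    )


# ---------------------------------------------------------------------------
# derived Emcn-hi / Emcn-lo regions
# ---------------------------------------------------------------------------


def derive_emcn_regions(
    emcn_channel: np.ndarray, pixel_size_um: float, smooth_um: float = 10.0
) -> dict[str, RegionOfInterest]:
    """Optional helper: derive Emcn-hi / Emcn-lo ROIs by three-class
    thresholding of smoothed Emcn intensity (the study drew these freehand;
    the returned ROIs carry ``provenance="derived"``).

    Each ROI outlines the largest connected region of its intensity class.
    """
    smooth = gaussian_filter(np.asarray(emcn_channel, dtype=float), smooth_um / pixel_size_um)
    if np.ptp(smooth) == 0 or len(np.unique(smooth)) < 3:
        raise ValueError("Emcn channel has no intensity structure to derive regions from")
    t_lo, t_hi = threshold_multiotsu(smooth, classes=3)
    out = {}
    for name, mask in (("emcn_hi", smooth > t_hi), ("emcn_lo", (smooth > t_lo) & (smooth <= t_hi))):
        lbl = cc_label(mask)
        if lbl.max() == 0:
            continue
        largest = np.argmax(np.bincount(lbl.ravel())[1:]) + 1
        contours = find_contours((lbl == largest).astype(float), 0.5)
        contour = max(contours, key=len)[:, ::-1]  # (row,col) -> (x,y)
        contour = contour[:: max(1, len(contour) // 200)]  # thin the polygon
        if len(contour) < 3:
            continue
        poly = Polygon(contour)
        if not poly.is_valid:
            poly = poly.buffer(0)
            if poly.geom_type == "MultiPolygon":
                poly = max(poly.geoms, key=lambda g: g.area)
        if poly.is_empty or poly.area <= 0:
            continue
        out[name] = RegionOfInterest(
            name=name,
            vertices=np.asarray(poly.exterior.coords[:-1]),
            provenance="derived",
        )
    return out
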
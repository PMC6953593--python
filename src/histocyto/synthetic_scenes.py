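"""Synthetic multi-channel fluorescence scenes with exhaustive ground truth.

The generator emulates confocal tile scans of the fracture callus used for
histocytometric quantification: DAPI-stained nuclei (3.1-12.5 um envelope),
myeloid marker channels (CX3CR1, F4/80, Gr-1) with planted co-expression
frequencies, tubular vessel structures carrying Endomucin (Emcn) and CD31
with high/low Emcn intensity classes, additive Gaussian noise, a smooth
background gradient, and a controllable proximal-vs-distal density asymmetry
around a central osteotomy-gap band. Every planted cell, vessel segment and
ROI is recorded so downstream segmentation, phenotyping and scoring stages
can be validated against known truth.

Scene layout
------------
The image is split into vertical bands (fractions of width)::

    [homeostatic_control] ... [proximal_adjacent][gap][distal_adjacent] ...

mirroring a longitudinal bone section with the osteotomy gap in the middle
and unaffected marrow far from the injury. Cell and vessel placement density
is uniform except for the two gap-adjacent bands, whose densities are scaled
by ``sqrt(ratio)`` (favoured side) and ``1/sqrt(ratio)`` when a polarized
scene is requested, keeping the control band at the geometric-mean density.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.ndimage import distance_transform_edt
from skimage.draw import line as draw_line

from .core import MultiChannelImage, RegionOfInterest, rois_to_geojson

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "PlantedCell",
    "VesselSegment",
    "PackingError",
    "generate_scene",
    "generate_polarized_pair",
    "write_scene",
    "canonical_phenotype",
]

MARKERS = ("CX3CR1", "F4/80", "Gr1")
CELL_CHANNELS = ("DAPI",) + MARKERS
VESSEL_CHANNELS = ("Emcn", "CD31")
CHANNELS = CELL_CHANNELS + VESSEL_CHANNELS

#: Peak rendering amplitudes (arbitrary fluorescence units).
DAPI_AMPLITUDE = 200.0
MARKER_AMPLITUDE = 200.0
EMCN_LO_AMPLITUDE = 60.0
EMCN_HI_AMPLITUDE = 180.0  # >= 3x the low class, making hi/lo annotation well defined
CD31_LO_AMPLITUDE = 80.0
CD31_HI_AMPLITUDE = 200.0  # type H endothelium is CD31-hi as well as Emcn-hi

#: Marker (cytoplasmic) footprint relative to the nuclear footprint.
MARKER_SCALE = 1.3
#: Axis ratio of stretched, non-round marker footprints.
NONROUND_AXIS_RATIO = 4.0
#: Fraction of the diameter envelope actually sampled (central 80%): the
#: configured range is the analyst's permissive size gate, not the size
#: distribution itself, so planted diameters stay clear of the gate edges.
ENVELOPE_MARGIN = 0.1

SIDES = ("proximal", "distal")


class PackingError(RuntimeError):
    """Raised when non-overlapping nucleus placement is infeasible."""


def canonical_phenotype(markers: Sequence[str] | str | frozenset) -> str:
    """Canonical phenotype label: markers in fixed order joined by '+'.

    The empty set maps to ``"negative"`` (marker-negative, DAPI-only cells).
    """
    if isinstance(markers, str):
        markers = [m for m in markers.replace("∧", "+").split("+") if m]
    ms = set(markers)
    unknown = ms - set(MARKERS)
    if unknown:
        raise ValueError(f"unknown markers {sorted(unknown)}; known: {MARKERS}")
    ordered = [m for m in MARKERS if m in ms]
    return "+".join(ordered) if ordered else "negative"


class SceneConfig(BaseModel):
    """Parameters of one synthetic scene (the study conditions).

    ``phenotype_frequencies`` maps phenotype labels (subsets of
    ``{CX3CR1, F4/80, Gr1}``) to fractions; the remainder up to 1 are
    marker-negative cells. ``vessel_density`` is skeleton length per area
    (um/um^2). ``polarization_ratio`` is the expected cell/vessel density of
    the favoured gap-adjacent band relative to the opposite band.
    """

    image_size_px: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.5
    n_nuclei: int = 300
    nucleus_diameter_range_um: tuple[float, float] = (3.1, 12.5)
    phenotype_frequencies: dict[str, float] = Field(
        default_factory=lambda: {
            "CX3CR1+F4/80": 0.40,
            "F4/80": 0.15,
            "CX3CR1": 0.10,
            "Gr1": 0.15,
        }
    )
    round_fraction: float = 0.6
    #: skeleton length per area (um/um^2): ~50 um sinusoid spacing, giving
    #: the pervasive vessel network of marrow tissue
    vessel_density: float = 0.02
    vessel_width_range_um: tuple[float, float] = (5.0, 15.0)
    emcn_hi_fraction: float = 0.5
    polarization_ratio: float = 1.0
    noise_sd: float = 5.0
    background_gradient_amplitude: float = 20.0
    seed: int = 0

    @field_validator("pixel_size_um")
    @classmethod
    def _positive_pixel(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("pixel_size_um must be positive")
        return v

    @field_validator("nucleus_diameter_range_um", "vessel_width_range_um")
    @classmethod
    def _ordered_range(cls, v: tuple[float, float]) -> tuple[float, float]:
        lo, hi = v
        if not (0 < lo <= hi):
            raise ValueError(f"range must be positive and ordered, got {v}")
        return v

    @field_validator("phenotype_frequencies")
    @classmethod
    def _canonical_freqs(cls, v: dict[str, float]) -> dict[str, float]:
        out: dict[str, float] = {}
        for label, f in v.items():
            if f < 0:
                raise ValueError(f"negative frequency for {label!r}")
            key = canonical_phenotype(label)
            out[key] = out.get(key, 0.0) + f
        if sum(out.values()) > 1 + 1e-9:
            raise ValueError(f"phenotype frequencies sum to {sum(out.values()):.3f} > 1")
        return out

    @model_validator(mode="after")
    def _check_scalars(self) -> "SceneConfig":
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.noise_sd < 0 or self.background_gradient_amplitude < 0:
            raise ValueError("noise_sd and background_gradient_amplitude must be >= 0")
        if not 0 <= self.round_fraction <= 1:
            raise ValueError("round_fraction must be in [0, 1]")
        if not 0 <= self.emcn_hi_fraction <= 1:
            raise ValueError("emcn_hi_fraction must be in [0, 1]")
        if self.polarization_ratio <= 0:
            raise ValueError("polarization_ratio must be positive")
        if self.vessel_density < 0:
            raise ValueError("vessel_density must be >= 0")
        return self


@dataclass
class PlantedCell:
    """Ground-truth record of one planted cell."""

    center_xy_px: tuple[float, float]  # (x=col, y=row)
    diameter_um: float  # nuclear diameter
    phenotype: str
    round: bool
    orientation_rad: float = 0.0

    @property
    def center_xy_um(self) -> tuple[float, float]:
        raise AttributeError("use GroundTruth.cells_table for physical coordinates")


@dataclass
class VesselSegment:
    """One vessel profile: skeleton polyline plus width and intensity class.

    Profiles are short (tens of um), as expected for a thin section through
    a 3-D sinusoidal network. ``brightness`` is the polarization-dependent
    rendering factor (1 in symmetric scenes).
    """

    points_xy_px: np.ndarray  # (N, 2) array of (x, y)
    width_um: float
    intensity_class: str  # "hi" | "lo"
    brightness: float = 1.0


@dataclass
class GroundTruth:
    """Everything the generator planted, the oracle for all recovery tests."""

    cells: list[PlantedCell]
    vessels: list[VesselSegment]
    rois: dict[str, RegionOfInterest]
    pixel_size_um: float
    polarization_side: Optional[str] = None
    vessel_mask: Optional[np.ndarray] = None  # rendered tube footprint (in-memory)
    emcn_hi_mask: Optional[np.ndarray] = None

    def counts_by_phenotype(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.cells:
            counts[c.phenotype] = counts.get(c.phenotype, 0) + 1
        return counts

    def cells_table(self) -> pd.DataFrame:
        s = self.pixel_size_um
        rows = [
            {
                "x_px": c.center_xy_px[0],
                "y_px": c.center_xy_px[1],
                "x_um": c.center_xy_px[0] * s,
                "y_um": c.center_xy_px[1] * s,
                "diameter_um": c.diameter_um,
                "phenotype": c.phenotype,
                "round": c.round,
            }
            for c in self.cells
        ]
        return pd.DataFrame(
            rows,
            columns=["x_px", "y_px", "x_um", "y_um", "diameter_um", "phenotype", "round"],
        )

    def cells_in_roi(self, roi_name: str) -> list[PlantedCell]:
        roi = self.rois[roi_name]
        return [c for c in self.cells if roi.contains(*c.center_xy_px)]

    def side_counts(self) -> dict[str, int]:
        """Planted cell counts in the proximal/distal gap-adjacent bands."""
        return {s: len(self.cells_in_roi(f"{s}_adjacent")) for s in SIDES}

    def to_manifest(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size_um,
            "polarization_side": self.polarization_side,
            "cells": [
                {
                    "x_px": c.center_xy_px[0],
                    "y_px": c.center_xy_px[1],
                    "diameter_um": c.diameter_um,
                    "phenotype": c.phenotype,
                    "round": c.round,
                    "orientation_rad": c.orientation_rad,
                }
                for c in self.cells
            ],
            "vessels": [
                {
                    "points_xy_px": v.points_xy_px.tolist(),
                    "width_um": v.width_um,
                    "intensity_class": v.intensity_class,
                    "brightness": v.brightness,
                }
                for v in self.vessels
            ],
            "rois": {name: r.to_geojson_feature() for name, r in self.rois.items()},
        }


# ---------------------------------------------------------------------------
# scene layout
# ---------------------------------------------------------------------------

#: Vertical bands as fractions of image width: (x0, x1) per ROI name.
#: The control band sits clear of the cell-placement edge margin so its
#: density is comparable to the interior bands.
BAND_FRACTIONS = {
    "homeostatic_control": (0.05, 0.20),
    "proximal_adjacent": (0.25, 0.45),
    "gap": (0.45, 0.55),
    "distal_adjacent": (0.55, 0.75),
}


def _layout_rois(shape: tuple[int, int]) -> dict[str, RegionOfInterest]:
    h, w = shape
    y0, y1 = 0.02 * h, 0.98 * h
    rois = {}
    for name, (f0, f1) in BAND_FRACTIONS.items():
        x0, x1 = f0 * w, f1 * w
        rois[name] = RegionOfInterest(
            name=name,
            vertices=np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]]),
        )
    return rois


def _placement_regions(shape, ratio: float, side: Optional[str]) -> list[tuple[float, float, float]]:
    """Vertical placement regions ``(x0, x1, density_weight)``.

    Density mass is allocated to regions *before* positions are drawn, so
    packing interactions cannot compress the configured ratio: the favoured
    adjacent band carries weight ``sqrt(ratio)``, the opposite band
    ``1/sqrt(ratio)`` (the homeostatic-control band stays at the geometric
    mean), everything else weight 1.
    """
    h, w = shape
    if ratio == 1.0 or side is None:
        return [(0.0, float(w), 1.0)]
    hi, lo = float(np.sqrt(ratio)), float(1.0 / np.sqrt(ratio))
    p0, p1 = (f * w for f in BAND_FRACTIONS["proximal_adjacent"])
    g0, g1 = (f * w for f in BAND_FRACTIONS["gap"])
    d0, d1 = (f * w for f in BAND_FRACTIONS["distal_adjacent"])
    w_prox, w_dist = (hi, lo) if side == "proximal" else (lo, hi)
    return [
        (0.0, p0, 1.0),
        (p0, p1, w_prox),
        (g0, g1, 1.0),
        (d0, d1, w_dist),
        (d1, float(w), 1.0),
    ]


def _choose_region(
    regions: list[tuple[float, float, float]], rng: np.random.Generator
) -> tuple[float, float]:
    probs = np.array([(x1 - x0) * wt for x0, x1, wt in regions])
    probs /= probs.sum()
    i = int(rng.choice(len(regions), p=probs))
    return regions[i][0], regions[i][1]


def _brightness_factor(regions: list[tuple[float, float, float]], x: float) -> float:
    """Marker/vessel brightness modulation in polarized scenes.

    Polarized regions in injured bone show brighter staining as well as
    higher structure density; brightness co-varies as the fourth root of
    the density weight (weight itself is sqrt(ratio)), so the stained-
    signal density contrast between sides reflects both effects.
    """
    for x0, x1, wt in regions:
        if x0 <= x < x1:
            return float(np.sqrt(wt))
    return 1.0


# ---------------------------------------------------------------------------
# placement and rendering
# ---------------------------------------------------------------------------


def _place_nuclei(cfg: SceneConfig, rng: np.random.Generator, side: Optional[str]) -> list[tuple[float, float, float]]:
    """Dart-throwing placement of non-overlapping nuclei.

    Returns (x, y, radius_px) triples; raises PackingError when the area
    cannot accommodate the requested count.
    """
    h, w = cfg.image_size_px
    s = cfg.pixel_size_um
    lo, hi = cfg.nucleus_diameter_range_um
    span = hi - lo
    d_lo, d_hi = lo + ENVELOPE_MARGIN * span, hi - ENVELOPE_MARGIN * span
    regions = _placement_regions((h, w), cfg.polarization_ratio, side)

    placed: list[tuple[float, float, float]] = []
    max_attempts = max(2000, 400 * cfg.n_nuclei)
    attempts = 0
    # extra clearance so cytoplasmic marker footprints rarely touch
    clearance = MARKER_SCALE + 0.15
    while len(placed) < cfg.n_nuclei:
        d_um = rng.uniform(d_lo, d_hi)
        r = d_um / 2 / s  # radius in px
        margin = MARKER_SCALE * NONROUND_AXIS_RATIO ** 0.5 * r + 2
        # band chosen before position: collisions retry the position only,
        # so packing pressure cannot shift density mass between bands
        x0, x1 = _choose_region(regions, rng)
        while True:
            if attempts >= max_attempts:
                raise PackingError(
                    f"placed {len(placed)}/{cfg.n_nuclei} nuclei after {attempts} attempts; "
                    "the configured area cannot hold this many non-overlapping nuclei"
                )
            attempts += 1
            x = rng.uniform(max(x0, margin), min(x1, w - margin))
            y = rng.uniform(margin, h - margin)
            if all(
                (px - x) ** 2 + (py - y) ** 2 >= (clearance * (r + pr)) ** 2
                for px, py, pr in placed
            ):
                placed.append((x, y, r))
                break
    return placed


def _super_gaussian_patch(r_px: float, axis_ratio: float, theta: float) -> np.ndarray:
    """Render one cell footprint on a small patch.

    The radial profile is a super-Gaussian ``exp(-ln2 * rho**8)`` where
    ``rho`` is the (possibly anisotropic) normalised radius: smooth edges,
    but half-maximum at the nominal radius so measured equivalent diameters
    track planted diameters. ``axis_ratio > 1`` stretches the footprint at
    constant area (unambiguous non-round ground truth).
    """
    a = r_px * np.sqrt(axis_ratio)
    b = r_px / np.sqrt(axis_ratio)
    half = int(np.ceil(1.45 * a)) + 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * xx + st * yy
    v = -st * xx + ct * yy
    rho2 = (u / a) ** 2 + (v / b) ** 2
    patch = np.exp(-np.log(2) * rho2 ** 4)  # rho**8
    patch[patch < 1e-3] = 0.0
    return patch


def _paint(canvas: np.ndarray, patch: np.ndarray, cx: float, cy: float, amplitude: float) -> None:
    """Max-composite a patch centred at (cx, cy) into the canvas."""
    half = patch.shape[0] // 2
    r0, c0 = int(round(cy)) - half, int(round(cx)) - half
    r1, c1 = r0 + patch.shape[0], c0 + patch.shape[1]
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r1, canvas.shape[0]), min(c1, canvas.shape[1])
    if rr0 >= rr1 or cc0 >= cc1:
        return
    sub = patch[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0] * amplitude
    np.maximum(canvas[rr0:rr1, cc0:cc1], sub, out=canvas[rr0:rr1, cc0:cc1])


def _draw_phenotypes(cfg: SceneConfig, rng: np.random.Generator, n: int) -> list[str]:
    labels = list(cfg.phenotype_frequencies)
    probs = [cfg.phenotype_frequencies[k] for k in labels]
    labels.append("negative")
    probs.append(max(0.0, 1.0 - sum(probs)))
    probs = np.asarray(probs) / np.sum(probs)
    idx = rng.choice(len(labels), size=n, p=probs)
    return [labels[i] for i in idx]


def _generate_vessels(
    cfg: SceneConfig, rng: np.random.Generator, side: Optional[str]
) -> list[VesselSegment]:
    h, w = cfg.image_size_px
    s = cfg.pixel_size_um
    area_um2 = h * w * s * s
    budget_px = cfg.vessel_density * area_um2 / s
    regions = _placement_regions((h, w), cfg.polarization_ratio, side)
    margin = cfg.vessel_width_range_um[1] / 2 / s + 2
    segments: list[VesselSegment] = []
    step = 8.0
    while budget_px > step:
        # the tube is confined to the region its start was allocated to, so
        # wandering walks cannot dilute the configured side asymmetry
        x0, x1 = _choose_region(regions, rng)
        xa, xb = max(x0, margin), min(x1, w - margin)
        x = rng.uniform(xa, xb)
        y = rng.uniform(margin, h - margin)
        # short profiles: a 7 um section through a 3-D network yields vessel
        # fragments of tens of um, not continuous tubes
        length = min(budget_px, rng.uniform(40, 160))
        theta = rng.uniform(0, 2 * np.pi)
        pts = [(x, y)]
        travelled = 0.0
        while travelled < length:
            theta += rng.normal(0, 0.35)
            nx = x + step * np.cos(theta)
            ny = y + step * np.sin(theta)
            if not xa <= nx <= xb:  # reflect rather than hug the wall
                theta = np.pi - theta
                nx = float(np.clip(x + step * np.cos(theta), xa, xb))
            if not margin <= ny <= h - margin:
                theta = -theta
                ny = float(np.clip(y + step * np.sin(theta), margin, h - margin))
            x, y = float(nx), float(ny)
            pts.append((x, y))
            travelled += step
        cls = "hi" if rng.uniform() < cfg.emcn_hi_fraction else "lo"
        segments.append(
            VesselSegment(
                points_xy_px=np.asarray(pts),
                width_um=float(rng.uniform(*cfg.vessel_width_range_um)),
                intensity_class=cls,
                brightness=_brightness_factor(regions, float(pts[0][0])),
            )
        )
        budget_px -= travelled
    return segments


def _render_vessels(
    segments: list[VesselSegment], shape: tuple[int, int], pixel_size_um: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Rasterise tubes; returns (emcn, cd31, vessel_mask, hi_mask)."""
    emcn = np.zeros(shape, dtype=np.float32)
    cd31 = np.zeros(shape, dtype=np.float32)
    vessel_mask = np.zeros(shape, dtype=bool)
    hi_mask = np.zeros(shape, dtype=bool)
    for seg in segments:
        radius_px = seg.width_um / 2 / pixel_size_um
        pts = np.round(seg.points_xy_px).astype(int)
        pad = int(np.ceil(radius_px)) + 2
        r0 = max(int(pts[:, 1].min()) - pad, 0)
        r1 = min(int(pts[:, 1].max()) + pad + 1, shape[0])
        c0 = max(int(pts[:, 0].min()) - pad, 0)
        c1 = min(int(pts[:, 0].max()) + pad + 1, shape[1])
        box = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        for (xa, ya), (xb, yb) in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(ya - r0, xa - c0, yb - r0, xb - c0)
            keep = (rr >= 0) & (rr < box.shape[0]) & (cc >= 0) & (cc < box.shape[1])
            box[rr[keep], cc[keep]] = True
        if not box.any():
            continue
        tube = np.zeros(shape, dtype=bool)
        tube[r0:r1, c0:c1] = distance_transform_edt(~box) <= radius_px
        vessel_mask |= tube
        b = seg.brightness
        if seg.intensity_class == "hi":
            hi_mask |= tube
            np.maximum(emcn, tube * (EMCN_HI_AMPLITUDE * b), out=emcn)
            np.maximum(cd31, tube * (CD31_HI_AMPLITUDE * b), out=cd31)
        else:
            np.maximum(emcn, tube * (EMCN_LO_AMPLITUDE * b), out=emcn)
            np.maximum(cd31, tube * (CD31_LO_AMPLITUDE * b), out=cd31)
    return emcn, cd31, vessel_mask, hi_mask


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _generate(cfg: SceneConfig, side: Optional[str]) -> tuple[MultiChannelImage, GroundTruth]:
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size_px
    shape = (h, w)

    placements = _place_nuclei(cfg, rng, side)
    phenotypes = _draw_phenotypes(cfg, rng, len(placements))
    roundness = rng.uniform(size=len(placements)) < cfg.round_fraction
    orientations = rng.uniform(0, np.pi, size=len(placements))

    channels = {name: np.zeros(shape, dtype=np.float32) for name in CHANNELS}
    cells: list[PlantedCell] = []
    s = cfg.pixel_size_um
    regions = _placement_regions(shape, cfg.polarization_ratio, side)
    for (x, y, r), pheno, is_round, theta in zip(placements, phenotypes, roundness, orientations):
        nucleus = _super_gaussian_patch(r, 1.0, 0.0)
        _paint(channels["DAPI"], nucleus, x, y, DAPI_AMPLITUDE)
        markers = [] if pheno == "negative" else pheno.split("+")
        if markers:
            ratio = 1.0 if is_round else NONROUND_AXIS_RATIO
            body = _super_gaussian_patch(MARKER_SCALE * r, ratio, theta)
            amp = MARKER_AMPLITUDE * _brightness_factor(regions, x)
            for m in markers:
                _paint(channels[m], body, x, y, amp)
        cells.append(
            PlantedCell(
                center_xy_px=(x, y),
                diameter_um=2 * r * s,
                phenotype=pheno,
                round=bool(is_round),
                orientation_rad=float(theta),
            )
        )

    segments = _generate_vessels(cfg, rng, side)
    emcn, cd31, vessel_mask, hi_mask = _render_vessels(segments, shape, s)
    channels["Emcn"] = emcn
    channels["CD31"] = cd31

    if cfg.background_gradient_amplitude > 0:
        ramp = (np.arange(w, dtype=np.float32) / max(w - 1, 1)) * cfg.background_gradient_amplitude
        for name in CHANNELS:
            channels[name] += ramp[None, :]
    if cfg.noise_sd > 0:
        for name in CHANNELS:
            channels[name] += rng.normal(0, cfg.noise_sd, size=shape).astype(np.float32)
            np.clip(channels[name], 0, None, out=channels[name])

    image = MultiChannelImage(channels=channels, pixel_size_um=s)
    truth = GroundTruth(
        cells=cells,
        vessels=segments,
        rois=_layout_rois(shape),
        pixel_size_um=s,
        polarization_side=side,
        vessel_mask=vessel_mask,
        emcn_hi_mask=hi_mask,
    )
    return image, truth


def generate_scene(config: SceneConfig) -> tuple[MultiChannelImage, GroundTruth]:
    """Generate one scene. With ``polarization_ratio > 1`` the distal band is
    favoured (use :func:`generate_polarized_pair` to choose the side)."""
    side = "distal" if config.polarization_ratio != 1.0 else None
    return _generate(config, side)


def generate_polarized_pair(
    config: SceneConfig, side: str
) -> tuple[MultiChannelImage, GroundTruth]:
    """Generate a scene whose cell and vessel density on ``side`` exceeds the
    opposite gap-adjacent band by ``config.polarization_ratio``."""
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}; expected one of {SIDES}")
    if config.polarization_ratio < 1:
        raise ValueError("polarization_ratio must be >= 1 (choose the favoured side instead)")
    return _generate(config, side if config.polarization_ratio != 1.0 else None)


def write_scene(
    image: MultiChannelImage, truth: GroundTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Persist a scene: multi-page TIFF, JSON manifest, CSV cell list, GeoJSON ROIs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / "scene.tif",
        "manifest": out / "manifest.json",
        "cells": out / "cells_truth.csv",
        "rois": out / "rois.geojson",
    }
    image.to_tiff(paths["image"])
    paths["manifest"].write_text(json.dumps(truth.to_manifest(), indent=1))
    truth.cells_table().to_csv(paths["cells"], index=False)
    rois_to_geojson(truth.rois.values(), paths["rois"])
    return paths
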
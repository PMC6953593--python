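"""Ordinal spatial-polarization scoring of gap-adjacent regions.

Each sample receives a score in {-2..2} per channel (DAPI, F4/80, vessel)
and side (proximal, distal to the fracture gap), judged against a
homeostatic-control region of unaffected marrow on the same section. A
sample is classified from the F4/80 and vessel scores: with
``D = (distal F4/80 + distal vessel) - (proximal F4/80 + proximal vessel)``,
``D > 2`` is polarized distally, ``D < -2`` proximally, otherwise neutral;
a card whose four classification scores are all zero is reported separately
as ``all_zero``. A difference of exactly 2 is classified neutral (the
conservative reading of the published ">2 polarized / <2 neutral" rule,
which leaves =2 unaddressed). DAPI scores are recorded as an internal
control but never enter the rule.

:func:`auto_score_side` is an automated surrogate for the manual scoring
procedure, used to validate the pipeline on synthetic scenes; it maps
intensity and abundance ratios relative to the control region onto the
ordinal scale with documented cutoffs and makes no claim to replicate
human scoring of real sections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .core import RegionOfInterest

__all__ = [
    "PolarizationScoreCard",
    "ScoreCutoffs",
    "classify_polarization",
    "auto_score_side",
    "score_scene",
    "scorecards_to_csv",
    "scorecards_from_csv",
    "classification_summary",
]

SCORED_CHANNELS = ("DAPI", "F4/80", "vessel")
SIDES = ("proximal", "distal")
CLASSES = ("polarized_proximal", "polarized_distal", "neutral", "all_zero")
#: The four scores entering the classification rule.
RULE_KEYS = tuple((ch, side) for ch in ("F4/80", "vessel") for side in SIDES)


@dataclass
class PolarizationScoreCard:
    """Per-sample ordinal scores: one per (channel, side)."""

    sample_id: str
    day: Optional[int] = None
    scores: dict[tuple[str, str], int] = field(default_factory=dict)

    def set_score(self, channel: str, side: str, score: int) -> None:
        if side not in SIDES:
            raise ValueError(f"unknown side {side!r}")
        if not float(score).is_integer() or not -2 <= int(score) <= 2:
            raise ValueError(f"score must be an integer in [-2, 2], got {score}")
        self.scores[(channel, side)] = int(score)

    def score(self, channel: str, side: str) -> int:
        try:
            return self.scores[(channel, side)]
        except KeyError:
            raise ValueError(
                f"sample {self.sample_id!r} is missing the {channel}/{side} score"
            ) from None

    @property
    def classification(self) -> str:
        return classify_polarization(self)

    def to_records(self) -> list[dict]:
        return [
            {"sample": self.sample_id, "day": self.day, "channel": ch, "side": sd, "score": v}
            for (ch, sd), v in sorted(self.scores.items())
        ]


def classify_polarization(card: PolarizationScoreCard, mode: str = "sum") -> str:
    """Apply the score-difference decision rule to a complete scorecard.

    ``mode="sum"`` (default) combines F4/80 and vessel by their side sums.
    ``mode="per_marker"`` additionally requires each marker's own difference
    to favor the same side (exposed as the alternative reading of the rule).
    """
    if mode not in ("sum", "per_marker"):
        raise ValueError(f"unknown mode {mode!r}")
    vals = {key: card.score(*key) for key in RULE_KEYS}
    if all(v == 0 for v in vals.values()):
        return "all_zero"
    d_f480 = vals[("F4/80", "distal")] - vals[("F4/80", "proximal")]
    d_ves = vals[("vessel", "distal")] - vals[("vessel", "proximal")]
    D = d_f480 + d_ves
    if mode == "per_marker" and (d_f480 * d_ves < 0 or (d_f480 == 0 and d_ves == 0)):
        return "neutral"
    if D > 2:
        return "polarized_distal"
    if D < -2:
        return "polarized_proximal"
    return "neutral"


# ---------------------------------------------------------------------------
# automated surrogate scorer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreCutoffs:
    """Mapping from the control-normalized ratio onto the ordinal scale.

    ``r`` is the ratio of stained-signal density (summed supra-threshold
    intensity per unit area — brightness and abundance jointly) between the
    scored region and the homeostatic control. ``r <= absent_max`` -> -2
    (absence of staining); ``r < reduced_max`` -> -1;
    ``reduced_max <= r <= elevated_min`` -> 0; above that, +2 when the
    signal runs along (nearly) the full contour between gap and adjacent
    tissue or extends beyond ``full_extent_um``, else +1.
    """

    absent_max: float = 0.10
    reduced_max: float = 2.0 / 3.0
    elevated_min: float = 1.5
    full_extent_coverage: float = 0.9
    full_extent_um: float = 400.0
    #: extent is judged at cell scale: a bin counts as covered when any
    #: positive pixel projects into it
    extent_bin_um: float = 20.0


def _positive_mask(channel: np.ndarray) -> np.ndarray:
    if np.ptp(channel) == 0:
        return np.zeros(channel.shape, dtype=bool)
    return channel > threshold_otsu(channel)


def _axis_extent(
    pos: np.ndarray, roi: RegionOfInterest, pixel_size_um: float, bin_um: float = 5.0
) -> tuple[float, float]:
    """Coverage fraction and absolute extent (um) of positive signal
    projected onto the long axis of the ROI's minimum rotated rectangle."""
    rect = roi.polygon.minimum_rotated_rectangle
    corners = np.asarray(rect.exterior.coords[:4])
    edges = np.diff(np.vstack([corners, corners[:1]]), axis=0)
    lens = np.hypot(edges[:, 0], edges[:, 1])
    axis = edges[int(np.argmax(lens))]
    axis = axis / np.hypot(*axis)
    rr, cc = np.nonzero(pos)
    if len(rr) == 0:
        return 0.0, 0.0
    proj = cc * axis[0] + rr * axis[1]
    length_px = float(lens.max())
    bins = max(int(round(length_px * pixel_size_um / bin_um)), 1)
    origin = float(np.dot(np.asarray(roi.polygon.exterior.coords[0]), axis))
    # project ROI corners to anchor the axis interval
    all_proj = np.asarray(roi.polygon.exterior.coords) @ axis
    lo, hi = float(all_proj.min()), float(all_proj.max())
    hist, _ = np.histogram(proj, bins=bins, range=(lo, hi))
    coverage = float((hist > 0).mean())
    return coverage, coverage * length_px * pixel_size_um


def auto_score_side(
    channel: np.ndarray,
    side_roi: RegionOfInterest,
    control_roi: RegionOfInterest,
    pixel_size_um: float,
    cutoffs: ScoreCutoffs = ScoreCutoffs(),
) -> int:
    """Score one channel on one side against the homeostatic control.

    Deterministic, and invariant to global positive rescaling of the image
    (every quantity is a ratio to the control region). A control region with
    zero signal cannot normalize anything and raises ``ValueError``.
    """
    channel = np.asarray(channel, dtype=float)
    control_mask = control_roi.mask(channel.shape)
    side_mask = side_roi.mask(channel.shape)
    if not control_mask.any():
        raise ValueError("control ROI rasterizes to an empty mask")
    if float(channel[control_mask].max()) <= 0:
        raise ValueError("control region has zero signal; scores are undefined")

    pos = _positive_mask(channel)

    # "intensity and abundance" judged jointly as stained-signal density:
    # summed intensity of supra-threshold pixels per unit region area.
    # Brightness and coverage both scale it, and sub-threshold background
    # (shading gradients, noise floor) is excluded from the comparison.
    def _mass(mask: np.ndarray) -> float:
        return float(channel[mask & pos].sum() / mask.sum())

    # fallback when a control region has no stained structures at all:
    # mean above the region's own low percentile
    def _residual(mask: np.ndarray) -> float:
        vals = channel[mask]
        return float(max(vals.mean() - np.percentile(vals, 10.0), 0.0))

    control_mass = _mass(control_mask)
    side_mass = _mass(side_mask) if side_mask.any() else 0.0
    if control_mass > 0:
        r = side_mass / control_mass
    else:
        control_res = _residual(control_mask)
        if control_res <= 0:
            raise ValueError("control region has zero signal; scores are undefined")
        r = (_residual(side_mask) if side_mask.any() else 0.0) / control_res

    if r <= cutoffs.absent_max:
        return -2
    if r < cutoffs.reduced_max:
        return -1
    if r <= cutoffs.elevated_min:
        return 0
    coverage, extent_um = _axis_extent(
        pos & side_mask, side_roi, pixel_size_um, bin_um=cutoffs.extent_bin_um
    )
    if coverage >= cutoffs.full_extent_coverage or extent_um > cutoffs.full_extent_um:
        return 2
    return 1


def score_scene(
    channels: Mapping[str, np.ndarray],
    rois: Mapping[str, RegionOfInterest],
    pixel_size_um: float,
    sample_id: str = "sample",
    day: Optional[int] = None,
    vessel_channel: str = "CD31",
    cutoffs: ScoreCutoffs = ScoreCutoffs(),
) -> PolarizationScoreCard:
    """Score DAPI, F4/80 and the vessel channel on both sides of the gap.

    Requires ``proximal_adjacent``, ``distal_adjacent`` and
    ``homeostatic_control`` ROIs.
    """
    for name in ("proximal_adjacent", "distal_adjacent", "homeostatic_control"):
        if name not in rois:
            raise ValueError(f"missing required ROI {name!r}")
    card = PolarizationScoreCard(sample_id=sample_id, day=day)
    source = {"DAPI": "DAPI", "F4/80": "F4/80", "vessel": vessel_channel}
    for scored, ch_name in source.items():
        for side in SIDES:
            card.set_score(
                scored,
                side,
                auto_score_side(
                    channels[ch_name],
                    rois[f"{side}_adjacent"],
                    rois["homeostatic_control"],
                    pixel_size_um,
                    cutoffs,
                ),
            )
    return card


# ---------------------------------------------------------------------------
# scorecard I/O
# ---------------------------------------------------------------------------


def scorecards_to_csv(cards: Iterable[PolarizationScoreCard], path: str | Path) -> None:
    records = [r for c in cards for r in c.to_records()]
    pd.DataFrame(records, columns=["sample", "day", "channel", "side", "score"]).to_csv(
        path, index=False
    )


def scorecards_from_csv(path: str | Path) -> list[PolarizationScoreCard]:
    df = pd.read_csv(path)
    cards = []
    for (sample, day), grp in df.groupby(["sample", "day"], dropna=False, sort=True):
        card = PolarizationScoreCard(
            sample_id=str(sample), day=None if pd.isna(day) else int(day)
        )
        for _, row in grp.iterrows():
            card.set_score(row["channel"], row["side"], int(row["score"]))
        cards.append(card)
    return cards


def scorecards_to_json(cards: Iterable[PolarizationScoreCard], path: str | Path) -> None:
    payload = [
        {
            "sample": c.sample_id,
            "day": c.day,
            "scores": {f"{ch}/{sd}": v for (ch, sd), v in sorted(c.scores.items())},
            "classification": classify_polarization(c),
        }
        for c in cards
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def classification_summary(
    cards: Iterable[PolarizationScoreCard], mode: str = "sum"
) -> pd.DataFrame:
    """Class tally over a set of scorecards (one row per classification)."""
    counts = {cls: 0 for cls in CLASSES}
    for c in cards:
        counts[classify_polarization(c, mode=mode)] += 1
    return pd.DataFrame(
        [{"classification": k, "n": v} for k, v in counts.items()],
        columns=["classification", "n"],
    )
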
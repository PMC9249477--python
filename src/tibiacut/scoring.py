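"""Radiological scoring of tibial-plateau fractures from CT measurements.

The scoring engine implements a Rasmussen-style anatomical grading of the
reduced tibial plateau.  Three displacement categories — articular surface
collapse (mm), plateau broadening (mm) and varus/valgus angular deformity
(degrees) — each score 6/4/2/0 points, for a displacement total out of 18:

==================  =========  =========  ==========  ======
category            6 points   4 points   2 points    0 points
==================  =========  =========  ==========  ======
collapse (mm)       0          (0, 5]     (5, 10]     > 10
broadening (mm)     0          (0, 5)     [5, 10]     > 10
angulation (deg)    0          (0, 10)    [10, 20]    > 20
==================  =========  =========  ==========  ======

Displacement grade: 18 excellent, 12-17 good, 6-11 common, 0-5 bad.

Two further categories grade the articular surface itself.  The plateau
top view is divided into five areas: a central intercondylar-eminence band
and four weight-bearing quadrants (anterolateral, anteromedial,
posterolateral, posteromedial).  Damage confined to the eminence (or no
damage) scores 6; 1-2 damaged articular areas 4; 3 areas 2; all 4 areas 0.
Comminution by fragment count: 0 fragments 6 (fracture line only through
the eminence), 1 fragment 4, 2 fragments 2, >= 3 fragments 0.

Total imaging score out of 30; grade: 28-30 excellent, 20-27 good,
10-19 common, 0-9 bad.

The printed band edges leave boundary values ambiguous (e.g. a collapse
strictly between 5 and 6 mm); the closures above assign every real
measurement to a band, with boundary values joining the lower-scoring band
(conservative grading).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import ValidationError
from .graphcut import SegmentationMask

__all__ = [
    "Region",
    "Grade",
    "DisplacementMeasurement",
    "SurfaceDamage",
    "DisplacementScore",
    "ImagingScore",
    "RegionLabelMap",
    "score_displacement",
    "score_surface",
    "total_score",
    "divide_plateau",
    "count_damaged_regions",
]


class Region(str, Enum):
    """The five areas of the tibial articular surface (top view)."""

    INTERCONDYLAR = "intercondylar"
    ANTEROLATERAL = "anterolateral"
    ANTEROMEDIAL = "anteromedial"
    POSTEROLATERAL = "posterolateral"
    POSTEROMEDIAL = "posteromedial"


ARTICULAR_REGIONS = frozenset(Region) - {Region.INTERCONDYLAR}


class Grade(str, Enum):
    EXCELLENT = "excellent"
    GOOD = "good"
    COMMON = "common"
    BAD = "bad"


@dataclass(frozen=True)
class DisplacementMeasurement:
    """Displacement of the reduced plateau: collapse depth (mm), plateau
    broadening (mm) and angular deformity (degrees), all non-negative."""

    collapse_mm: float
    broadening_mm: float
    angulation_deg: float

    def __post_init__(self) -> None:
        for name in ("collapse_mm", "broadening_mm", "angulation_deg"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class SurfaceDamage:
    """Damaged-area set and fragment count read off the reconstruction.

    A fragment count of 0 means the fracture line passes only through the
    intercondylar eminence, so it is inconsistent with damage recorded in
    any articular area.
    """

    damaged_regions: frozenset[Region]
    fragment_count: int

    def __post_init__(self) -> None:
        regions = frozenset(Region(r) for r in self.damaged_regions)
        object.__setattr__(self, "damaged_regions", regions)
        if self.fragment_count < 0 or self.fragment_count != int(self.fragment_count):
            raise ValidationError("fragment_count must be a non-negative integer")
        if self.fragment_count == 0 and regions & ARTICULAR_REGIONS:
            raise ValidationError(
                "fragment_count 0 implies damage confined to the intercondylar "
                f"eminence, but articular areas are damaged: {sorted(r.value for r in regions & ARTICULAR_REGIONS)}"
            )


@dataclass(frozen=True)
class DisplacementScore:
    collapse_pts: int
    broadening_pts: int
    angulation_pts: int
    displacement_total: int
    displacement_grade: Grade


@dataclass(frozen=True)
class ImagingScore:
    """All five sub-scores, the 30-point total and both grades."""

    collapse_pts: int
    broadening_pts: int
    angulation_pts: int
    displacement_total: int
    displacement_grade: Grade
    damage_pts: int
    comminution_pts: int
    total: int
    total_grade: Grade

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["displacement_grade"] = self.displacement_grade.value
        d["total_grade"] = self.total_grade.value
        return d


def _band_points(value: float, upper_4: float, upper_2: float, open_4: bool) -> int:
    """Map a non-negative measurement to {6, 4, 2, 0} band points.

    ``open_4`` controls whether the 4-point band excludes its upper edge
    (broadening/angulation: boundary joins the 2-point band) or includes
    it (collapse).
    """
    if value == 0:
        return 6
    in_4 = value < upper_4 if open_4 else value <= upper_4
    if in_4:
        return 4
    if value <= upper_2:
        return 2
    return 0


def _displacement_grade(total: int) -> Grade:
    if total == 18:
        return Grade.EXCELLENT
    if total >= 12:
        return Grade.GOOD
    if total >= 6:
        return Grade.COMMON
    return Grade.BAD


def _total_grade(total: int) -> Grade:
    if total >= 28:
        return Grade.EXCELLENT
    if total >= 20:
        return Grade.GOOD
    if total >= 10:
        return Grade.COMMON
    return Grade.BAD


def score_displacement(m: DisplacementMeasurement) -> DisplacementScore:
    """Score the three displacement categories and grade their 18-pt total."""
    collapse = _band_points(m.collapse_mm, 5.0, 10.0, open_4=False)
    broadening = _band_points(m.broadening_mm, 5.0, 10.0, open_4=True)
    angulation = _band_points(m.angulation_deg, 10.0, 20.0, open_4=True)
    total = collapse + broadening + angulation
    return DisplacementScore(
        collapse_pts=collapse,
        broadening_pts=broadening,
        angulation_pts=angulation,
        displacement_total=total,
        displacement_grade=_displacement_grade(total),
    )


def score_surface(d: SurfaceDamage) -> tuple[int, int]:
    """Score damaged-area extent and comminution, each on {6, 4, 2, 0}.

    Only the four weight-bearing articular areas count toward the damage
    score; involvement of the intercondylar eminence alone (or no damage
    at all) takes the best band.
    """
    n_articular = len(d.damaged_regions & ARTICULAR_REGIONS)
    damage_pts = {0: 6, 1: 4, 2: 4, 3: 2, 4: 0}[n_articular]
    frag = min(int(d.fragment_count), 3)
    comminution_pts = {0: 6, 1: 4, 2: 2, 3: 0}[frag]
    return damage_pts, comminution_pts


def total_score(m: DisplacementMeasurement, d: SurfaceDamage) -> ImagingScore:
    """Combine displacement, damage-area and comminution into the 30-pt score."""
    disp = score_displacement(m)
    damage_pts, comminution_pts = score_surface(d)
    total = disp.displacement_total + damage_pts + comminution_pts
    return ImagingScore(
        collapse_pts=disp.collapse_pts,
        broadening_pts=disp.broadening_pts,
        angulation_pts=disp.angulation_pts,
        displacement_total=disp.displacement_total,
        displacement_grade=disp.displacement_grade,
        damage_pts=damage_pts,
        comminution_pts=comminution_pts,
        total=total,
        total_grade=_total_grade(total),
    )


@dataclass(frozen=True)
class RegionLabelMap:
    """Per-pixel assignment of plateau foreground to the five regions.

    ``labels`` holds ``None``-equivalent empty string for background and a
    :class:`Region` value name for each foreground pixel, stored as an
    integer grid with 0 = background and 1..5 indexing ``REGION_ORDER``.
    """

    labels: np.ndarray

    REGION_ORDER = (
        Region.INTERCONDYLAR,
        Region.ANTEROLATERAL,
        Region.ANTEROMEDIAL,
        Region.POSTEROLATERAL,
        Region.POSTEROMEDIAL,
    )

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int8)
        if lab.ndim != 2 or lab.min(initial=0) < 0 or lab.max(initial=0) > 5:
            raise ValidationError("region labels must be a 2-D grid over 0..5")
        object.__setattr__(self, "labels", lab)

    def region_mask(self, region: Region) -> np.ndarray:
        return self.labels == (self.REGION_ORDER.index(region) + 1)

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0

    def pixel_counts(self) -> dict[Region, int]:
        return {r: int(self.region_mask(r).sum()) for r in self.REGION_ORDER}


def divide_plateau(
    mask: SegmentationMask | np.ndarray, eminence_halfwidth_frac: float = 0.15
) -> RegionLabelMap:
    """Divide a plateau top-view mask into the five articular areas.

    A vertical band of half-width ``eminence_halfwidth_frac * width``
    centred on the foreground centroid column is the intercondylar
    eminence; the remaining foreground is split left/right of the centroid
    column (lateral/medial) and above/below the centroid row
    (anterior/posterior) into the four weight-bearing quadrants.  The
    centroid-anchored axis-aligned geometry stands in for the manual line
    placement a reader would do on anatomy.
    """
    fg = mask.labels if isinstance(mask, SegmentationMask) else np.asarray(mask, dtype=bool)
    if fg.ndim != 2:
        raise ValidationError("plateau mask must be a 2-D grid")
    if not fg.any():
        raise ValidationError("plateau mask is empty; cannot divide regions")
    if not 0.0 < eminence_halfwidth_frac < 0.5:
        raise ValidationError("eminence_halfwidth_frac must lie in (0, 0.5)")

    rows, cols = np.nonzero(fg)
    c_row = rows.mean()
    c_col = cols.mean()
    halfwidth = eminence_halfwidth_frac * fg.shape[1]

    col_grid = np.arange(fg.shape[1])[None, :] * np.ones((fg.shape[0], 1))
    row_grid = np.arange(fg.shape[0])[:, None] * np.ones((1, fg.shape[1]))
    in_band = np.abs(col_grid - c_col) <= halfwidth
    lateral = col_grid < c_col  # lateral drawn on the left, medial on the right
    anterior = row_grid < c_row  # top of the image is anterior

    labels = np.zeros(fg.shape, dtype=np.int8)
    order = RegionLabelMap.REGION_ORDER
    labels[fg & in_band] = order.index(Region.INTERCONDYLAR) + 1
    quad = {
        Region.ANTEROLATERAL: anterior & lateral,
        Region.ANTEROMEDIAL: anterior & ~lateral,
        Region.POSTEROLATERAL: ~anterior & lateral,
        Region.POSTEROMEDIAL: ~anterior & ~lateral,
    }
    for region, sel in quad.items():
        labels[fg & ~in_band & sel] = order.index(region) + 1
    return RegionLabelMap(labels=labels)


def count_damaged_regions(
    regions: RegionLabelMap,
    damage: SegmentationMask | np.ndarray,
    min_overlap_px: int = 1,
) -> frozenset[Region]:
    """Which of the five areas a damage mask touches.

    A region counts as damaged iff at least ``min_overlap_px`` damage
    pixels fall inside it.
    """
    dmg = damage.labels if isinstance(damage, SegmentationMask) else np.asarray(damage, dtype=bool)
    if dmg.shape != regions.labels.shape:
        raise ValidationError("damage mask dimensions must match the region map")
    damaged = {
        r
        for r in RegionLabelMap.REGION_ORDER
        if int((regions.region_mask(r) & dmg).sum()) >= min_overlap_px
    }
    return frozenset(damaged)
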
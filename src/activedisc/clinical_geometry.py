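"""Clinically relevant geometry of the fitted disc and cup circles.

Everything here is exact circle geometry: the vertical cup-to-disc ratio
(CDR), the narrowest neuroretinal rim width and the rim-to-disc ratio (RDR),
directional rim widths for the ISNT check, and the angular extent over which
the rim is absent (the quantity that drives the late DDLS stages).

Conventions
-----------
* Image coordinates: ``x`` is the column index increasing rightward, ``y`` is
  the row index increasing downward.  Circle centers live in continuous pixel
  coordinates; integer coordinates are pixel centers.
* Angles are in degrees, measured from the +x axis toward +y.  Because +y
  points down, "superior" (image up) is 270 deg and "inferior" is 90 deg.
* Laterality: for a right eye (OD) the temporal side is image-left (180 deg);
  for a left eye (OS) it is image-right (0 deg).  Nasal is the opposite side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .errors import InvalidArgumentError, InvalidGeometryError

__all__ = [
    "Circle",
    "IsntWidths",
    "ClinicalParams",
    "narrowest_rim",
    "vertical_cdr",
    "rdr",
    "rim_width_along",
    "isnt_widths",
    "isnt_satisfied",
    "rim_absence_extent",
    "clinical_params",
]

_EPS = 1e-9


@dataclass(frozen=True)
class Circle:
    """A disc or cup outline: center (cx, cy) and radius r, in pixels."""

    cx: float
    cy: float
    r: float

    def __post_init__(self):
        if not (self.r > 0):
            raise InvalidArgumentError(f"circle radius must be positive, got {self.r}")

    def contains(self, x: float, y: float, tol: float = _EPS) -> bool:
        return math.hypot(x - self.cx, y - self.cy) <= self.r + tol


@dataclass(frozen=True)
class IsntWidths:
    """Rim widths (pixels) along the four clinical meridians."""

    inferior: float
    superior: float
    nasal: float
    temporal: float
    laterality: str = "right"


@dataclass(frozen=True)
class ClinicalParams:
    """Scalar parameters derived from a (disc, cup) circle pair."""

    cdr: float
    rdr: float
    narrowest_rim_width: float
    narrowest_meridian: float
    isnt: IsntWidths
    rim_absence_extent: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["isnt"] = asdict(self.isnt)
        return d


def _center_distance(disc: Circle, cup: Circle) -> float:
    return math.hypot(cup.cx - disc.cx, cup.cy - disc.cy)


def _require_cup_center_inside(disc: Circle, cup: Circle) -> float:
    d = _center_distance(disc, cup)
    if d > disc.r + _EPS:
        raise InvalidGeometryError(
            f"cup center lies outside the disc (d={d:.3f} > R_d={disc.r:.3f})"
        )
    return d


def narrowest_rim(disc: Circle, cup: Circle) -> tuple[float, float]:
    """Narrowest neuroretinal rim width and its meridian.

    For two circles with the cup center inside the disc, the narrowest rim
    lies on the line through both centers, extended beyond the cup to the
    disc periphery: ``l = R_d - (d + R_c)``, clamped at zero when the cup
    reaches or crosses the disc boundary.

    Returns
    -------
    (l, meridian) : width in pixels and the meridian in degrees (direction
        from the disc center through the cup center).  For concentric
        circles the meridian is undefined and reported as 0 by convention.
    """
    d = _require_cup_center_inside(disc, cup)
    width = max(0.0, disc.r - (d + cup.r))
    if d <= _EPS:
        meridian = 0.0
    else:
        meridian = math.degrees(math.atan2(cup.cy - disc.cy, cup.cx - disc.cx)) % 360.0
    return width, meridian


def vertical_cdr(disc: Circle, cup: Circle) -> float:
    """Vertical cup-to-disc ratio.

    For circular outlines the vertical extent is the diameter regardless of
    orientation, so the ratio reduces to ``R_c / R_d``.
    """
    return cup.r / disc.r


def rdr(disc: Circle, cup: Circle) -> float:
    """Rim-to-disc ratio: narrowest rim width over the disc diameter.

    Normalizing by the diameter ``2 R_d`` makes the attainable range
    ``[0, 0.5)``, with 0.5 the supremum approached as the cup shrinks to a
    point; this matches the DDLS normal band topping out at 0.50.
    """
    width, _ = narrowest_rim(disc, cup)
    return width / (2.0 * disc.r)


def rim_width_along(disc: Circle, cup: Circle, angle: float) -> float:
    """Rim width along the ray from the disc center at ``angle`` degrees.

    The width is the distance from the far cup boundary to the disc boundary
    along the ray.  Writing ``delta`` for the angle between the ray and the
    center-to-center direction, the far intersection of the ray with the cup
    sits at distance ``g = d cos(delta) + sqrt(R_c^2 - d^2 sin^2(delta))``
    from the disc center.  If the ray misses the cup (or the cup lies wholly
    behind the origin) the nearest cup point projects onto the ray at
    ``max(0, d cos(delta))`` and the width is measured from there.  The
    result is clamped at zero.
    """
    d = _require_cup_center_inside(disc, cup)
    if d <= _EPS:
        return max(0.0, disc.r - cup.r)
    phi = math.atan2(cup.cy - disc.cy, cup.cx - disc.cx)
    delta = math.radians(angle) - phi
    s = d * math.sin(delta)
    p = d * math.cos(delta)
    disc_sq = cup.r * cup.r - s * s
    if disc_sq >= 0.0:
        g = p + math.sqrt(disc_sq)
        g = max(0.0, g)
    else:
        g = max(0.0, p)
    return max(0.0, disc.r - g)


def isnt_widths(disc: Circle, cup: Circle, laterality: str = "right") -> IsntWidths:
    """Rim widths along the inferior, superior, nasal and temporal meridians.

    ``laterality`` maps the horizontal directions: right eye (OD) has its
    temporal side at image-left, left eye (OS) at image-right.
    """
    if laterality not in ("left", "right"):
        raise InvalidArgumentError(f"laterality must be 'left' or 'right', got {laterality!r}")
    inferior = rim_width_along(disc, cup, 90.0)
    superior = rim_width_along(disc, cup, 270.0)
    left_dir = rim_width_along(disc, cup, 180.0)
    right_dir = rim_width_along(disc, cup, 0.0)
    if laterality == "right":
        temporal, nasal = left_dir, right_dir
    else:
        temporal, nasal = right_dir, left_dir
    return IsntWidths(inferior=inferior, superior=superior, nasal=nasal,
                      temporal=temporal, laterality=laterality)


def isnt_satisfied(w: IsntWidths) -> bool:
    """ISNT rule: inferior >= superior >= nasal >= temporal (non-strict)."""
    if min(w.inferior, w.superior, w.nasal, w.temporal) < 0:
        raise InvalidArgumentError("rim widths must be non-negative")
    return w.inferior >= w.superior >= w.nasal >= w.temporal


def rim_absence_extent(disc: Circle, cup: Circle) -> float:
    """Angular extent (degrees, seen from the disc center) of absent rim.

    Zero while the cup stays inside the disc (``d + R_c <= R_d``).  Once the
    cup reaches past the disc boundary, the arc of disc-boundary directions
    with no rim subtends ``2 arccos((R_d^2 + d^2 - R_c^2) / (2 d R_d))``.
    A cup covering the whole disc yields 360.
    """
    d = _require_cup_center_inside(disc, cup)
    if d + cup.r <= disc.r + _EPS:
        return 0.0
    if d <= _EPS:
        # concentric with R_c > R_d: no rim anywhere
        return 360.0
    cos_half = (disc.r * disc.r + d * d - cup.r * cup.r) / (2.0 * d * disc.r)
    cos_half = min(1.0, max(-1.0, cos_half))
    return math.degrees(2.0 * math.acos(cos_half))


def clinical_params(disc: Circle, cup: Circle, laterality: str = "right") -> ClinicalParams:
    """Bundle all clinical measurements for one (disc, cup) pair."""
    width, meridian = narrowest_rim(disc, cup)
    return ClinicalParams(
        cdr=vertical_cdr(disc, cup),
        rdr=rdr(disc, cup),
        narrowest_rim_width=width,
        narrowest_meridian=meridian,
        isnt=isnt_widths(disc, cup, laterality),
        rim_absence_extent=rim_absence_extent(disc, cup),
    )
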
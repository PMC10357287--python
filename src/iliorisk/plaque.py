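"""Calcified-plaque classification and the plaque-on-a-curve (POC) effect.

Two concerns live here:

* **Calcification category** — plaques are graded I–IV from the fraction
  of the lumen cross-section and of the wall perimeter they occupy; a
  category of III or higher is the high-risk calcification indicator used
  by the risk score.

* **Free-lumen realignment** — a one-sided plaque narrows the lumen and
  displaces the center of the *free* lumen away from the plaque wall.
  Re-aligning the centerline to the free lumen (instead of the outer
  vessel wall) changes the measured angle of a bend the plaque sits on.
  Plaque wall positions are named relative to the bend's outward bulge:
  ``inner_wall`` plaques sit on the bulge (tip) side and push the
  free-lumen line toward the center of curvature, smoothing the measured
  angle (negative delta); ``outer_wall`` plaques sit on the wall opposite
  the bulge and sharpen it (positive delta); ``circumferential`` plaques
  ring the whole wall and leave the centerline where it was.  Because the
  displacement is the centroid shift of the free-lumen area, a plaque of
  fixed thickness displaces the line further — and perturbs the angle
  more — in a small vessel than in a large one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Sequence

import numpy as np

from .centerline_geometry import Centerline, Curve, turning_angle
from .errors import BoundaryError, InconsistencyError, InvalidInputError

#: Arc length (mm) over which the free-lumen shift ramps in/out at the
#: edges of a plaque span.
TAPER_LENGTH = 5.0
#: High-risk calcification indicator: category at or above this.
HIGH_RISK_CATEGORY = 3


class PlaquePosition(str, Enum):
    INNER_WALL = "inner_wall"  # on the bend's bulge (tip) side
    OUTER_WALL = "outer_wall"  # on the wall opposite the bulge
    CIRCUMFERENTIAL = "circumferential"  # rings the entire wall


class CalcCategory(IntEnum):
    """Calcification grade from perimeter / lumen occupation fractions."""

    I = 1
    II = 2
    III = 3
    IV = 4

    @property
    def high_risk(self) -> bool:
        return self >= HIGH_RISK_CATEGORY


@dataclass(frozen=True)
class Plaque:
    """One calcified lesion on the vessel wall.

    ``span`` is the arc-length interval (mm) it covers; ``thickness`` its
    maximal radial depth (mm); the two fractions are the proportions of
    the wall perimeter and of the lumen cross-section it occupies.
    """

    span: tuple  # (start_mm, end_mm)
    position: PlaquePosition
    perimeter_fraction: float
    lumen_fraction: float
    thickness: float

    def __post_init__(self):
        if self.span[1] <= self.span[0]:
            raise InvalidInputError(f"empty plaque span {self.span}")
        for name in ("perimeter_fraction", "lumen_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1], got {v}")
        if self.thickness <= 0:
            raise InvalidInputError("plaque thickness must be > 0")
        object.__setattr__(self, "position", PlaquePosition(self.position))

    @property
    def category(self) -> CalcCategory:
        return calcification_category(self.perimeter_fraction,
                                      self.lumen_fraction)


def calcification_category(perimeter_fraction: float,
                           lumen_fraction: float) -> CalcCategory:
    """Grade a plaque I–IV from its occupation fractions.

    I: both under half; II: ≥ half the perimeter only; III: ≥ half the
    lumen only; IV: both.  Half counts as "at least half".
    """
    for name, v in (("perimeter_fraction", perimeter_fraction),
                    ("lumen_fraction", lumen_fraction)):
        if not (np.isfinite(v) and 0.0 <= v <= 1.0):
            raise InvalidInputError(f"{name} must be in [0, 1], got {v!r}")
    peri = perimeter_fraction >= 0.5
    lum = lumen_fraction >= 0.5
    if peri and lum:
        return CalcCategory.IV
    if lum:
        return CalcCategory.III
    if peri:
        return CalcCategory.II
    return CalcCategory.I


def free_lumen_shift(diameter: float, thickness: float) -> float:
    """Displacement (mm) of the free-lumen centroid for a one-sided plaque.

    The plaque is modelled as a circular segment of depth ``thickness``
    cut from a circular lumen of the given diameter; the returned value is
    how far the centroid of the remaining (free) lumen moves away from the
    plaque wall.  Grows with thickness and, at fixed thickness, with
    1/diameter — small vessels are displaced more.
    """
    r = diameter / 2.0
    if thickness >= r:
        raise InvalidInputError(
            f"plaque thickness {thickness} mm must be below the lumen "
            f"radius {r} mm"
        )
    if thickness <= 0:
        return 0.0
    alpha = math.acos((r - thickness) / r)
    seg_area = r * r * (alpha - math.sin(alpha) * math.cos(alpha))
    if seg_area == 0:
        return 0.0
    centroid = 2.0 * r * math.sin(alpha) ** 3 / (3.0 * (alpha - math.sin(alpha) * math.cos(alpha)))
    full = math.pi * r * r
    return seg_area * centroid / (full - seg_area)


def _bulge_direction(points: np.ndarray, j: int, m: int) -> np.ndarray:
    """Unit vector pointing from the local center of curvature toward the
    bend apex (the outward bulge) at index ``j``; zero vector when the
    polyline is locally straight."""
    n = len(points)
    a, b = max(0, j - m), min(n - 1, j + m)
    v1 = points[j] - points[a]
    v2 = points[b] - points[j]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return np.zeros(3)
    u = v1 / n1 - v2 / n2  # opposite of the curvature direction
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        return np.zeros(3)
    return u / nu


def _any_perpendicular(t: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to tangent ``t``."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(t[0]) > 0.9 * np.linalg.norm(t):
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(t, ref)
    return u / np.linalg.norm(u)


def free_lumen_centerline(centerline: Centerline,
                          plaques: Sequence[Plaque],
                          taper: float = TAPER_LENGTH) -> Centerline:
    """Re-align a centerline to the free lumen given wall plaques.

    Within each plaque span, points move along the bend's bulge axis by
    the free-lumen centroid shift (``outer_wall`` plaques push the line
    toward the bulge, ``inner_wall`` away from it, ``circumferential``
    not at all), with a linear ramp of ``taper`` mm at the span edges.
    Per-point lumen diameters inside a span shrink by the plaque
    thickness.  With no plaques the input is returned unchanged.
    """
    if not plaques:
        return centerline
    s = centerline.arc_lengths()
    total = s[-1]
    occupied = {}  # wall -> list of spans, for overlap detection
    for pl in plaques:
        lo, hi = pl.span
        if lo < -1e-9 or hi > total + 1e-9:
            raise BoundaryError(
                f"plaque span {pl.span} outside vessel (length {total:.1f} mm)"
            )
        for (olo, ohi) in occupied.get(pl.position, []):
            if lo < ohi and olo < hi:
                raise InvalidInputError(
                    f"overlapping plaques on the same wall: "
                    f"({olo:.1f}, {ohi:.1f}) and ({lo:.1f}, {hi:.1f})"
                )
        occupied.setdefault(pl.position, []).append((lo, hi))

    pts = centerline.points.copy()
    dia = centerline.diameters.copy()
    step = total / (len(centerline) - 1)
    probe_m = max(1, int(round(10.0 / step)))  # bulge probe, ~10 mm

    for pl in plaques:
        lo, hi = pl.span
        inside = np.flatnonzero((s >= lo - 1e-9) & (s <= hi + 1e-9))
        if len(inside) == 0:
            continue
        for i in inside:
            if pl.thickness >= centerline.diameters[i] / 2.0:
                raise InvalidInputError(
                    f"plaque thickness {pl.thickness} mm reaches the lumen "
                    f"center at arc {s[i]:.1f} mm (diameter "
                    f"{centerline.diameters[i]:.2f} mm)"
                )
        dia[inside] = dia[inside] - pl.thickness
        if pl.position is PlaquePosition.CIRCUMFERENTIAL:
            continue  # symmetric narrowing: no net shift
        # one fixed shift axis per plaque, evaluated at the sharpest point
        mid = inside[len(inside) // 2]
        u = _bulge_direction(centerline.points, int(mid), probe_m)
        if np.allclose(u, 0.0):
            tangent = centerline.points[min(mid + 1, len(centerline) - 1)] \
                - centerline.points[max(mid - 1, 0)]
            u = _any_perpendicular(tangent)
        sign = 1.0 if pl.position is PlaquePosition.OUTER_WALL else -1.0
        for i in inside:
            d_edge = min(s[i] - lo, hi - s[i])
            ramp = 1.0 if taper <= 0 else min(1.0, max(0.0, d_edge / taper))
            mag = free_lumen_shift(float(centerline.diameters[i]),
                                   pl.thickness)
            pts[i] = pts[i] + sign * ramp * mag * u
    return Centerline(points=pts, diameters=dia,
                      areas=centerline.areas.copy(),
                      perimeters=centerline.perimeters.copy(),
                      landmarks=centerline.landmarks,
                      imputed_sections=centerline.imputed_sections)


def poc_angle_effect(centerline: Centerline, plaques: Sequence[Plaque],
                     curve: Curve, offset: float = 10.0):
    """Effect of plaque-on-a-curve on the measured bend angle.

    Recomputes the turning angle at ``curve``'s peak after free-lumen
    realignment and returns ``(adjusted_angle, delta)`` in degrees, where
    ``delta = adjusted − original``: positive for ``outer_wall`` plaques
    (sharper), negative for ``inner_wall`` (smoother), zero for
    ``circumferential``.
    """
    if not 0 <= curve.peak_index < len(centerline):
        raise InconsistencyError(
            f"curve peak {curve.peak_index} outside this centerline"
        )
    original = turning_angle(centerline, curve.peak_index, offset=offset)
    adjusted_cl = free_lumen_centerline(centerline, plaques)
    adjusted = turning_angle(adjusted_cl, curve.peak_index, offset=offset)
    return adjusted, adjusted - original
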
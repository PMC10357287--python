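"""Vessel centerline representation and tortuosity measurement.

The iliofemoral artery is represented as an ordered 3D polyline (one point
per sampled position, coordinates in mm, ordered puncture site →
aortoiliac bifurcation) with a lumen cross-section attached to every
point.  All tortuosity quantities used by the risk score are derived here:

* ``resample_smooth`` — uniform arc-length resampling plus a symmetric
  moving-average smoother, stabilising curve detection on noisy polylines;
* ``turning_angle`` — deviation-from-straight angle at a point, measured
  between chords drawn to probe points a fixed arc length away;
* ``detect_curves`` — segmentation of the turning-angle profile into
  discrete curves, each with a peak angle and an arc-length span;
* ``tortuosity_profile`` — number of curves (NOC), sum of angles (SOA),
  maximum angle, mean inter-curve distance, true/ideal length and the
  tortuosity index IFT = (true/ideal − 1) × 100;
* ``lumen_summary`` — minimal lumen diameter (MLD), minimal area and
  perimeter, mean diameter.

Angles follow the deviation convention: 0° is a straight vessel and
larger values are sharper bends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import BoundaryError, InconsistencyError, InvalidInputError

#: Default arc-length step (mm) for resampling before curve detection.
DEFAULT_SPACING = 1.0
#: Default moving-average smoothing window (mm).
DEFAULT_WINDOW = 5.0
#: Default probe offset (mm) for the turning-angle measurement.
DEFAULT_OFFSET = 10.0
#: Turning-angle noise floor (degrees): profile regions below it are
#: treated as straight.
NOISE_FLOOR_DEG = 5.0
#: Smallest peak angle (degrees) reported as a curve.
DEFAULT_MIN_ANGLE = 15.0
#: Two profile maxima closer than this arc length (mm) are one anatomic
#: bend; the larger peak is kept.
MERGE_DISTANCE = 20.0

PUNCTURE = "puncture_site"
BIFURCATION = "aortoiliac_bifurcation"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CrossSection:
    """Lumen cross-section at one centerline point (mm / mm²)."""

    diameter: float
    area: float
    perimeter: float

    def __post_init__(self):
        for name in ("diameter", "area", "perimeter"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidInputError(
                    f"cross-section {name} must be finite and > 0, got {v!r}"
                )

    @classmethod
    def circular(cls, diameter: float) -> "CrossSection":
        """Impute area and perimeter from the diameter assuming a circular
        lumen — used when a file supplies only diameters."""
        r = diameter / 2.0
        return cls(diameter=diameter, area=math.pi * r * r,
                   perimeter=math.pi * diameter)


@dataclass
class Centerline:
    """Ordered 3D vessel centerline with per-point lumen sections.

    ``points`` is an (n, 3) float array in mm; ``diameters``, ``areas`` and
    ``perimeters`` are length-n arrays.  ``landmarks`` optionally names
    indices (``puncture_site``, ``aortoiliac_bifurcation``); the analyzed
    segment runs between them when both are present.  ``imputed_sections``
    records that area/perimeter were filled in from the diameter.
    """

    points: np.ndarray
    diameters: np.ndarray
    areas: np.ndarray
    perimeters: np.ndarray
    landmarks: Optional[dict] = None
    imputed_sections: bool = False

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.perimeters = np.asarray(self.perimeters, dtype=float)
        n = len(self.points)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InvalidInputError("points must be an (n, 3) array")
        if n < 2:
            raise InvalidInputError("a centerline needs at least 2 points")
        for name in ("diameters", "areas", "perimeters"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise InvalidInputError(
                    f"{name} must have one value per point ({n}), "
                    f"got shape {arr.shape}"
                )
            if not np.all(np.isfinite(arr) & (arr > 0)):
                bad = int(np.argmin(np.isfinite(arr) & (arr > 0)))
                raise InvalidInputError(
                    f"{name}[{bad}] = {arr[bad]!r} is not a positive number"
                )
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps <= 0):
            bad = int(np.argmin(steps > 0))
            raise InvalidInputError(
                f"consecutive points {bad} and {bad + 1} coincide"
            )
        if self.landmarks:
            for name, idx in self.landmarks.items():
                if not 0 <= int(idx) < n:
                    raise InvalidInputError(
                        f"landmark {name!r} index {idx} outside 0..{n - 1}"
                    )

    @classmethod
    def from_arrays(cls, points, diameters, areas=None, perimeters=None,
                    landmarks=None) -> "Centerline":
        """Build a centerline, imputing circular area/perimeter if absent."""
        diameters = np.asarray(diameters, dtype=float)
        imputed = areas is None or perimeters is None
        if areas is None:
            areas = math.pi * (diameters / 2.0) ** 2
        if perimeters is None:
            perimeters = math.pi * diameters
        return cls(points=np.asarray(points, dtype=float),
                   diameters=diameters, areas=np.asarray(areas, dtype=float),
                   perimeters=np.asarray(perimeters, dtype=float),
                   landmarks=landmarks, imputed_sections=imputed)

    def __len__(self) -> int:
        return len(self.points)

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length (mm) at every point; starts at 0."""
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def true_length(self) -> float:
        """Polyline arc length of the analyzed segment (mm)."""
        i0, i1 = self._segment_indices()
        s = self.arc_lengths()
        return float(s[i1] - s[i0])

    @property
    def ideal_length(self) -> float:
        """Straight-line (stretched) distance between the segment
        endpoints (mm)."""
        i0, i1 = self._segment_indices()
        return float(np.linalg.norm(self.points[i1] - self.points[i0]))

    def _segment_indices(self) -> tuple[int, int]:
        lm = self.landmarks or {}
        if PUNCTURE in lm and BIFURCATION in lm:
            i0, i1 = int(lm[PUNCTURE]), int(lm[BIFURCATION])
            if i0 > i1:
                i0, i1 = i1, i0
            return i0, i1
        return 0, len(self) - 1

    def section(self, i: int) -> CrossSection:
        return CrossSection(diameter=float(self.diameters[i]),
                            area=float(self.areas[i]),
                            perimeter=float(self.perimeters[i]))

    def reversed(self) -> "Centerline":
        n = len(self)
        lm = None
        if self.landmarks:
            lm = {k: n - 1 - int(v) for k, v in self.landmarks.items()}
        return replace(self, points=self.points[::-1].copy(),
                       diameters=self.diameters[::-1].copy(),
                       areas=self.areas[::-1].copy(),
                       perimeters=self.perimeters[::-1].copy(),
                       landmarks=lm)


@dataclass(frozen=True)
class Curve:
    """One detected vessel bend."""

    peak_index: int
    turn_angle: float  # degrees, deviation from straight
    span: tuple  # (start_mm, end_mm) arc-length interval

    def __post_init__(self):
        if not 0 < self.turn_angle <= 180:
            raise InvalidInputError(
                f"turn_angle must be in (0, 180], got {self.turn_angle}"
            )
        if self.span[1] <= self.span[0]:
            raise InvalidInputError(f"empty curve span {self.span}")


@dataclass(frozen=True)
class TortuosityProfile:
    """Tortuosity summary of one vessel."""

    n_curves: int
    sum_of_angles: float  # SOA, degrees
    max_angle: float  # degrees
    mean_inter_curve_distance: Optional[float]  # mm; None when NOC < 2
    true_length: float  # mm
    ideal_length: float  # mm
    ift: float  # percent


@dataclass(frozen=True)
class LumenSummary:
    """Lumen extrema and mean over a centerline, with argmin indices."""

    mld: float  # mm
    min_area: float  # mm²
    min_perimeter: float  # mm
    mean_diameter: float  # mm
    mld_index: int = field(default=0)
    min_area_index: int = field(default=0)
    min_perimeter_index: int = field(default=0)


# ---------------------------------------------------------------------------
# operations


def _interp_point(points: np.ndarray, s: np.ndarray, target: float) -> np.ndarray:
    """Point at arc length ``target`` by linear interpolation on the polyline."""
    return np.array([np.interp(target, s, points[:, k]) for k in range(3)])


def _smooth_points(pts: np.ndarray, half: int) -> np.ndarray:
    """Symmetric moving average of half-width ``half`` samples, truncated
    symmetrically near the ends so the endpoints never move and straight
    polylines are fixed points."""
    n = len(pts)
    if half < 1 or n <= 2:
        return pts
    sm = pts.copy()
    if n > 2 * half:
        kernel = np.full(2 * half + 1, 1.0 / (2 * half + 1))
        sm[half:n - half] = np.column_stack(
            [np.convolve(pts[:, k], kernel, mode="valid") for k in range(3)]
        )
    for i in range(1, min(half, n - 1)):
        for j in {i, n - 1 - i}:
            h = min(half, j, n - 1 - j)
            if h >= 1:
                sm[j] = pts[j - h:j + h + 1].mean(axis=0)
    return sm


def resample_smooth(centerline: Centerline,
                    spacing: float = DEFAULT_SPACING,
                    window: float = DEFAULT_WINDOW) -> Centerline:
    """Resample a centerline at uniform arc-length spacing and smooth it.

    Points are placed every ``spacing`` mm along the polyline (the original
    endpoints are always kept); cross-section values are linearly
    interpolated in arc length.  The smoother is a symmetric moving
    average of half-width ``window``/2 mm whose window is truncated
    symmetrically near the ends, so the endpoints never move and straight
    polylines are fixed points.  ``window=0`` disables smoothing.
    """
    if spacing <= 0:
        raise InvalidInputError(f"spacing must be > 0, got {spacing}")
    if window < 0:
        raise InvalidInputError(f"window must be >= 0, got {window}")
    if len(centerline) < 2:  # pragma: no cover - enforced by Centerline
        raise InvalidInputError("cannot resample fewer than 2 points")

    s = centerline.arc_lengths()
    total = s[-1]
    grid = np.arange(0.0, total, spacing)
    if total - grid[-1] > 1e-9:
        grid = np.append(grid, total)
    else:
        grid[-1] = total

    pts = np.column_stack(
        [np.interp(grid, s, centerline.points[:, k]) for k in range(3)]
    )
    dia = np.interp(grid, s, centerline.diameters)
    area = np.interp(grid, s, centerline.areas)
    per = np.interp(grid, s, centerline.perimeters)

    if window > 0:
        half = int(round(window / (2.0 * spacing)))
        pts = _smooth_points(pts, half)

    lm = None
    if centerline.landmarks:
        lm = {k: int(np.argmin(np.abs(grid - s[int(v)])))
              for k, v in centerline.landmarks.items()}
    return Centerline(points=pts, diameters=dia, areas=area, perimeters=per,
                      landmarks=lm,
                      imputed_sections=centerline.imputed_sections)


def turning_angle(centerline: Centerline, index: int,
                  offset: float = DEFAULT_OFFSET) -> float:
    """Deviation-from-straight angle (degrees) at point ``index``.

    Probe points are taken exactly ``offset`` mm of arc length before and
    after the indexed point (interpolated on the polyline); the returned
    angle is the one between the chord into the point and the chord out of
    it — 0° for collinear probes, approaching 180° for a hairpin.
    """
    if offset <= 0:
        raise InvalidInputError(f"offset must be > 0, got {offset}")
    s = centerline.arc_lengths()
    if not 0 <= index < len(centerline):
        raise BoundaryError(f"index {index} outside centerline")
    s0 = s[index]
    if s0 - offset < -1e-9 or s0 + offset > s[-1] + 1e-9:
        raise BoundaryError(
            f"probe points at {s0:.1f}±{offset:.1f} mm fall outside the "
            f"vessel (length {s[-1]:.1f} mm)"
        )
    p = centerline.points[index]
    before = _interp_point(centerline.points, s, max(s0 - offset, 0.0))
    after = _interp_point(centerline.points, s, min(s0 + offset, s[-1]))
    v1 = p - before
    v2 = after - p
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    c = float(np.dot(v1, v2) / (n1 * n2))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def turning_angle_at_arc(centerline: Centerline, s0: float,
                         offset: float = DEFAULT_OFFSET) -> float:
    """Turning angle (degrees) at continuous arc position ``s0`` mm, with
    the vertex and both probe points interpolated on the polyline."""
    if offset <= 0:
        raise InvalidInputError(f"offset must be > 0, got {offset}")
    s = centerline.arc_lengths()
    if s0 - offset < -1e-9 or s0 + offset > s[-1] + 1e-9:
        raise BoundaryError(
            f"probe points at {s0:.1f}±{offset:.1f} mm fall outside the "
            f"vessel (length {s[-1]:.1f} mm)"
        )
    p = _interp_point(centerline.points, s, s0)
    before = _interp_point(centerline.points, s, max(s0 - offset, 0.0))
    after = _interp_point(centerline.points, s, min(s0 + offset, s[-1]))
    v1, v2 = p - before, after - p
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    c = float(np.dot(v1, v2) / (n1 * n2))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def refine_curve_angles(centerline: Centerline, curves: Sequence["Curve"],
                        offset: float = DEFAULT_OFFSET,
                        halfwidth: float = 2.0,
                        step: float = 0.25,
                        peak_arcs: Optional[Sequence] = None) -> list:
    """Re-measure each curve's peak angle on an *unsmoothed* polyline.

    Smoothing (and sub-sample apex placement) biases the chord-probe
    angle low; this sweeps the continuous turning angle over
    ``±halfwidth`` mm around each detected peak (grid ``step`` mm) on the
    given — typically original or resampled-but-unsmoothed — centerline
    and keeps the maximum.  ``peak_arcs`` gives each curve's peak arc
    position when the curves were detected on a different sampling of the
    same polyline.  Spans and ordering are preserved.
    """
    if not curves:
        return []
    s = centerline.arc_lengths()
    if peak_arcs is None:
        peak_arcs = [s[min(c.peak_index, len(s) - 1)] for c in curves]
    cand, owner = [], []
    for ci, s_pk in enumerate(peak_arcs):
        lo = max(offset, s_pk - halfwidth)
        hi = min(s[-1] - offset, s_pk + halfwidth)
        grid = np.arange(lo, hi + 1e-9, step) if hi >= lo else [s_pk]
        cand.extend(grid)
        owner.extend([ci] * len(grid))
    cand = np.asarray(cand, dtype=float)
    owner = np.asarray(owner)
    p = np.column_stack([np.interp(cand, s, centerline.points[:, k])
                         for k in range(3)])
    before = np.column_stack(
        [np.interp(np.maximum(cand - offset, 0.0), s,
                   centerline.points[:, k]) for k in range(3)])
    after = np.column_stack(
        [np.interp(np.minimum(cand + offset, s[-1]), s,
                   centerline.points[:, k]) for k in range(3)])
    v1, v2 = p - before, after - p
    nrm = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(np.einsum("ij,ij->i", v1, v2) / nrm, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    refined = []
    for ci, c in enumerate(curves):
        best = float(np.nanmax(ang[owner == ci]))
        refined.append(Curve(peak_index=c.peak_index, turn_angle=best,
                             span=c.span))
    return refined


def turning_angle_profile(centerline: Centerline,
                          offset: float = DEFAULT_OFFSET) -> np.ndarray:
    """Turning angle at every point (degrees); NaN where a probe would
    leave the vessel.  Vectorized companion of :func:`turning_angle` used
    by curve detection: probes are the points ``k`` samples away, where
    ``k`` is ``offset`` expressed in (uniform) sample steps."""
    s = centerline.arc_lengths()
    n = len(centerline)
    out = np.full(n, np.nan)
    if n < 3:
        return out
    step = s[-1] / (n - 1)
    k = max(1, int(round(offset / step)))
    if n <= 2 * k:
        return out
    p = centerline.points
    v1 = p[k:n - k] - p[:n - 2 * k]
    v2 = p[2 * k:] - p[k:n - k]
    dot = np.einsum("ij,ij->i", v1, v2)
    nrm = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.clip(dot / nrm, -1.0, 1.0)
    out[k:n - k] = np.degrees(np.arccos(c))
    return out


def _local_maxima(values: np.ndarray, idx: np.ndarray) -> list:
    """Indices (into the original array) of local maxima of ``values``
    restricted to the contiguous index run ``idx``; plateaus yield their
    first index; a monotone run yields its extreme end."""
    v = values[idx]
    if len(v) == 1:
        return [int(idx[0])]
    maxima = []
    for j in range(len(v)):
        left = v[j - 1] if j > 0 else -np.inf
        right = v[j + 1] if j < len(v) - 1 else -np.inf
        if v[j] > left and v[j] >= right:
            maxima.append(int(idx[j]))
    if not maxima:  # flat run
        maxima.append(int(idx[int(np.argmax(v))]))
    return maxima


def detect_curves(centerline: Centerline,
                  offset: float = DEFAULT_OFFSET,
                  min_angle: float = DEFAULT_MIN_ANGLE,
                  noise_floor: float = NOISE_FLOOR_DEG,
                  merge_distance: float = MERGE_DISTANCE) -> list:
    """Segment the turning-angle profile into discrete curves.

    A curve is a maximal contiguous region where the profile exceeds
    ``noise_floor`` degrees, containing one local maximum (its peak); two
    maxima closer than ``merge_distance`` mm of arc length are merged
    (larger peak kept) so a single anatomic bend is never double counted.
    Curves whose peak is below ``min_angle`` are discarded.  Result is
    ordered by arc length; an empty list means a straight vessel.
    """
    if offset <= 0:
        raise InvalidInputError("offset must be > 0")
    if not 0 < min_angle < 180:
        raise InvalidInputError("min_angle must be in (0, 180)")
    prof = turning_angle_profile(centerline, offset=offset)
    s = centerline.arc_lengths()
    above = np.flatnonzero(np.nan_to_num(prof, nan=-1.0) > noise_floor)
    if len(above) == 0:
        return []

    runs = np.split(above, np.flatnonzero(np.diff(above) > 1) + 1)
    curves = []
    for run in runs:
        peaks = _local_maxima(prof, run)
        # merge peaks of one anatomic bend
        peaks.sort()
        merged = [peaks[0]]
        for pk in peaks[1:]:
            if s[pk] - s[merged[-1]] < merge_distance:
                if prof[pk] > prof[merged[-1]]:
                    merged[-1] = pk
            else:
                merged.append(pk)
        # split the run between consecutive retained peaks at the minimum
        bounds = [run[0]]
        for a, b in zip(merged[:-1], merged[1:]):
            seg = np.arange(a, b + 1)
            bounds.append(seg[int(np.argmin(prof[seg]))])
        bounds.append(run[-1])
        for j, pk in enumerate(merged):
            if prof[pk] < min_angle:
                continue
            lo, hi = bounds[j], bounds[j + 1]
            if hi <= lo:
                continue
            curves.append(Curve(peak_index=int(pk),
                                turn_angle=float(prof[pk]),
                                span=(float(s[lo]), float(s[hi]))))
    curves.sort(key=lambda c: c.peak_index)
    return curves


def tortuosity_profile(centerline: Centerline,
                       curves: Sequence[Curve]) -> TortuosityProfile:
    """Summarize detected curves into the Table-style tortuosity profile.

    SOA is the sum of curve peak angles; the mean inter-curve distance is
    the mean arc-length gap between consecutive peaks (absent when fewer
    than two curves); IFT = (true length / ideal length − 1) × 100.
    """
    s = centerline.arc_lengths()
    for c in curves:
        if not 0 <= c.peak_index < len(centerline):
            raise InconsistencyError(
                f"curve peak {c.peak_index} outside this centerline"
            )
    angles = np.array([c.turn_angle for c in curves], dtype=float)
    noc = len(curves)
    soa = float(angles.sum()) if noc else 0.0
    max_angle = float(angles.max()) if noc else 0.0
    if noc >= 2:
        peaks_s = np.sort(s[[c.peak_index for c in curves]])
        micd = float(np.mean(np.diff(peaks_s)))
    else:
        micd = None
    true_len = centerline.true_length
    ideal_len = centerline.ideal_length
    ift = (true_len / ideal_len - 1.0) * 100.0
    return TortuosityProfile(n_curves=noc, sum_of_angles=soa,
                             max_angle=max_angle,
                             mean_inter_curve_distance=micd,
                             true_length=true_len, ideal_length=ideal_len,
                             ift=ift)


def lumen_summary(centerline: Centerline) -> LumenSummary:
    """Lumen extrema over all sections: MLD, minimal area/perimeter, mean
    diameter, with the indices where the minima occur."""
    d, a, p = centerline.diameters, centerline.areas, centerline.perimeters
    i_d, i_a, i_p = int(np.argmin(d)), int(np.argmin(a)), int(np.argmin(p))
    return LumenSummary(mld=float(d[i_d]), min_area=float(a[i_a]),
                        min_perimeter=float(p[i_p]),
                        mean_diameter=float(d.mean()),
                        mld_index=i_d, min_area_index=i_a,
                        min_perimeter_index=i_p)


def analyze(centerline: Centerline,
            spacing: float = DEFAULT_SPACING,
            window: float = DEFAULT_WINDOW,
            offset: float = DEFAULT_OFFSET,
            min_angle: float = DEFAULT_MIN_ANGLE):
    """Convenience pipeline: resample → detect curves → profile + lumen.

    Curves are localized on the smoothed profile (noise robustness) and
    their peak angles refined on the unsmoothed resampled polyline
    (smoothing biases the chord-probe angle low).  The lumen summary is
    taken on the *original* sections so planted or measured minima are
    reported exactly.  Returns
    ``(profile, lumen, curves, resampled_centerline)``.
    """
    raw = resample_smooth(centerline, spacing=spacing, window=0.0)
    if window > 0:
        half = int(round(window / (2.0 * spacing)))
        smoothed = replace(raw, points=_smooth_points(raw.points, half))
    else:
        smoothed = raw
    # detect with a lowered threshold (smoothing biases peaks low by up
    # to ~12%), refine, then apply the caller's min_angle to the refined
    # angles
    detect_floor = max(NOISE_FLOOR_DEG, 0.75 * min_angle)
    curves = detect_curves(smoothed, offset=offset, min_angle=detect_floor)
    # refine peak angles on the original polyline: resampling can skip a
    # bend's apex, and smoothing pulls it inward — both bias angles low
    s_raw = raw.arc_lengths()
    peak_arcs = [s_raw[c.peak_index] for c in curves]
    curves = refine_curve_angles(centerline, curves, offset=offset,
                                 peak_arcs=peak_arcs)
    curves = [c for c in curves if c.turn_angle >= min_angle]
    prof = tortuosity_profile(raw, curves)
    lum = lumen_summary(centerline)
    return prof, lum, curves, raw
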
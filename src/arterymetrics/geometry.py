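"""Planar geometry primitives for radial wall measurement.

Everything here works in pixel units in the stored (x, y) frame. The three
primitives the radial measurement builds on are:

* the luminal center of mass from vertex spatial moments of the contour,
* ray / line intersection with a closed polyline, with intersections
  reported in distance order, and
* the perpendicular measurement line through the intimal sample point.

The center of mass uses vertex moments, ``M_ij = sum over contour points of
x^i y^j``, so contours are arc-length resampled first (default 1 px
spacing) to remove vertex-density bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour import Contour

__all__ = [
    "Ray",
    "MeasurementLine",
    "resample_contour",
    "center_of_mass",
    "line_intersections",
    "ray_intersections",
    "pick_intersection",
    "measurement_line",
]

_EPS = 1e-12
#: minimal ray parameter: intersections closer than this to the origin are
#: treated as the origin itself and dropped
_T_MIN = 1e-9


@dataclass(frozen=True)
class Ray:
    """Half-line from ``origin`` at ``angle_deg`` (degrees, from +x toward +y)."""

    origin: tuple[float, float]
    angle_deg: float

    @property
    def direction(self) -> np.ndarray:
        a = np.deg2rad(self.angle_deg)
        return np.array([np.cos(a), np.sin(a)])


@dataclass(frozen=True)
class MeasurementLine:
    """Full line through ``anchor`` with unit ``direction``.

    Built perpendicular to the local intimal chord; the positive sense is
    oriented outward (away from the luminal center of mass) by
    :func:`measurement_line`.
    """

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.hypot(*d)
        if not np.isfinite(n) or n < _EPS:
            raise ValueError("direction must be a nonzero finite vector")
        object.__setattr__(self, "anchor", np.asarray(self.anchor, dtype=float))
        object.__setattr__(self, "direction", d / n)


def resample_contour(points: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample a closed polyline to uniform arc-length vertex spacing.

    Parameters
    ----------
    points : (n, 2) array
        Contour vertices, closing edge implicit.
    spacing : float
        Target spacing in pixels; at least 8 vertices are always produced.

    Returns
    -------
    (m, 2) array of resampled vertices (closing vertex not duplicated).
    """
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seglen.sum())
    if total <= 0:
        raise ValueError("degenerate contour with zero perimeter")
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    m = max(int(np.ceil(total / spacing)), 8)
    s = np.linspace(0.0, total, m, endpoint=False)
    return np.column_stack(
        [np.interp(s, cum, closed[:, 0]), np.interp(s, cum, closed[:, 1])]
    )


def center_of_mass(contour: Contour | np.ndarray, resample_spacing: float | None = 1.0) -> np.ndarray:
    """Center of mass of a contour from its vertex spatial moments.

    ``CoM = (M10/M00, M01/M00)`` with ``M_ij`` summed over the contour's
    vertex points. With ``resample_spacing`` set (the default), vertices
    are first placed at uniform arc-length spacing so the result
    approximates the continuous boundary centroid regardless of how the
    input polygon was digitized.
    """
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty contour")
    if resample_spacing is not None:
        pts = resample_contour(pts, resample_spacing)
    # M00 = vertex count, M10 = sum x, M01 = sum y
    return pts.mean(axis=0)


def line_intersections(
    anchor: np.ndarray, direction: np.ndarray, contour: Contour
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intersections of a full line with a closed polyline.

    Uses the half-open edge convention (edge parameter ``s`` in [0, 1)) so
    a crossing exactly at a shared vertex is counted once. Edges parallel
    to the line are skipped.

    Returns
    -------
    t : (k,) array
        Signed line parameters, sorted ascending.
    points : (k, 2) array
        Intersection coordinates in the same order.
    seg_idx : (k,) array of int
        Index of the contour edge each intersection lies on.
    """
    anchor = np.asarray(anchor, dtype=float)
    d = np.asarray(direction, dtype=float)
    a, e = contour.segments
    f = a - anchor
    denom = d[0] * e[:, 1] - d[1] * e[:, 0]  # cross(d, e)
    ok = np.abs(denom) > _EPS
    t = np.full(len(a), np.nan)
    s = np.full(len(a), np.nan)
    t[ok] = (f[ok, 0] * e[ok, 1] - f[ok, 1] * e[ok, 0]) / denom[ok]  # cross(f, e)/cross(d, e)
    s[ok] = (f[ok, 0] * d[1] - f[ok, 1] * d[0]) / denom[ok]  # cross(f, d)/cross(d, e)
    hit = ok & (s >= 0.0) & (s < 1.0)
    idx = np.nonzero(hit)[0]
    order = np.argsort(t[idx], kind="stable")
    idx = idx[order]
    tt = t[idx]
    pts = anchor + tt[:, None] * d
    if len(tt) > 1:
        # a crossing exactly at a vertex can register on both adjacent
        # edges through rounding; such touches count once
        keep = np.concatenate([[True], np.abs(np.diff(tt)) > 1e-7])
        tt, pts, idx = tt[keep], pts[keep], idx[keep]
    return tt, pts, idx


def ray_intersections(ray: Ray, contour: Contour) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intersections of a half-line with a closed polyline.

    Same conventions as :func:`line_intersections`, restricted to
    parameters ``t > 0`` and therefore sorted by distance from the ray
    origin. The list may be empty.
    """
    t, pts, idx = line_intersections(np.asarray(ray.origin, dtype=float), ray.direction, contour)
    keep = t > _T_MIN
    return t[keep], pts[keep], idx[keep]


def pick_intersection(points: np.ndarray, rule: str) -> np.ndarray | None:
    """Select one intersection from a distance-sorted list.

    ``rule='farthest'`` keeps the last point (used for the intima outer
    contour), ``rule='closest'`` the first (media and lumen). Returns
    ``None`` for an empty list so the caller can record a missing sample.
    """
    if rule not in ("farthest", "closest"):
        raise ValueError(f"unknown rule {rule!r}")
    if len(points) == 0:
        return None
    return np.asarray(points[-1] if rule == "farthest" else points[0], dtype=float)


def measurement_line(
    p_left: np.ndarray,
    p_mid: np.ndarray,
    p_right: np.ndarray,
    outward_from: np.ndarray | None = None,
) -> MeasurementLine:
    """Perpendicular measurement line through the central intimal point.

    The line is anchored at ``p_mid`` and directed along the unit normal of
    the chord ``p_right - p_left``. If ``outward_from`` (normally the
    luminal center of mass) is given, the sign is chosen so the direction
    points away from it; callers search both senses regardless.
    """
    p_left = np.asarray(p_left, dtype=float)
    p_right = np.asarray(p_right, dtype=float)
    chord = p_right - p_left
    if np.hypot(*chord) < _EPS:
        raise ValueError("degenerate chord: auxiliary points coincide")
    normal = np.array([-chord[1], chord[0]])
    line = MeasurementLine(np.asarray(p_mid, dtype=float), normal)
    if outward_from is not None:
        away = line.anchor - np.asarray(outward_from, dtype=float)
        if float(np.dot(line.direction, away)) < 0:
            line = MeasurementLine(line.anchor, -line.direction)
    return line
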
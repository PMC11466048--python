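"""Contour and annotation containers.

Coordinates follow the image convention: 0-based pixel centers, x to the
right, y downward. A :class:`Contour` stores one closed compartment
boundary; an :class:`ArteryAnnotation` groups the media, intima, and lumen
outer contours of a single artery. Polar angles used elsewhere in the
package are measured from the +x axis toward +y, i.e. counter-clockwise in
the (x, y) coordinate frame as stored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely.geometry

__all__ = ["Contour", "ArteryAnnotation"]


def _signed_area(points: np.ndarray) -> float:
    """Shoelace signed area; positive for counter-clockwise order in (x, y)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Contour:
    """A closed 2D polyline bounding one arterial compartment.

    The closing vertex is implicit: ``points[-1]`` connects back to
    ``points[0]``. On construction a duplicated closing vertex is dropped
    and the orientation is normalized to counter-clockwise (positive
    shoelace area in the stored frame).
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be an (n, 2) array")
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValueError("contour needs at least 3 distinct points")
        if _signed_area(pts) < 0:
            pts = pts[::-1].copy()
        object.__setattr__(self, "points", pts)

    # -- geometry -----------------------------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        """Enclosed polygon area (pixels squared)."""
        return abs(_signed_area(self.points))

    @property
    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge start points ``A`` and edge vectors ``E`` (both (n, 2)), cached."""
        cached = self.__dict__.get("_segments")
        if cached is None:
            a = self.points
            e = np.roll(a, -1, axis=0) - a
            cached = (a, e)
            object.__setattr__(self, "_segments", cached)
        return cached

    def to_shapely(self) -> shapely.geometry.Polygon:
        poly = shapely.geometry.Polygon(self.points)
        if not poly.is_valid:
            poly = poly.buffer(0)
        return poly

    def transformed(self, fn) -> "Contour":
        """Return a new contour with ``fn`` applied to the (n, 2) points."""
        return Contour(np.asarray(fn(self.points.copy()), dtype=float))

    def contains_fraction(self, other: "Contour") -> float:
        """Fraction of ``other``'s area lying inside this contour."""
        a, b = self.to_shapely(), other.to_shapely()
        if b.area == 0:
            return 0.0
        return a.intersection(b).area / b.area


@dataclass
class ArteryAnnotation:
    """One artery's compartment boundaries plus physical scale.

    ``intimas`` and ``lumens`` may hold several contours for tangentially
    cut arteries; the measurement stage selects the primary lumen-intima
    pair and treats the rest as cross-intersection obstacles. ``lumens``
    may be empty only for fully occluded arteries, which the measurement
    stage rejects.
    """

    media: Contour
    intimas: list[Contour]
    lumens: list[Contour]
    pixel_size_um: float = 0.25
    artery_id: str = "artery"
    score: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.intimas:
            raise ValueError("annotation needs at least one intima contour")
        if self.score is not None and self.score not in (0, 1, 2, 3):
            raise ValueError("score must be in {0, 1, 2, 3}")

    def transformed(self, fn) -> "ArteryAnnotation":
        return dataclasses.replace(
            self,
            media=self.media.transformed(fn),
            intimas=[c.transformed(fn) for c in self.intimas],
            lumens=[c.transformed(fn) for c in self.lumens],
        )

    @property
    def all_contours(self) -> dict[str, list[Contour]]:
        return {"media": [self.media], "intima": list(self.intimas), "lumen": list(self.lumens)}
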
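"""Radial measurement of media and intima thickness.

For every sampling angle alpha, three rays at alpha - beta, alpha, and
alpha + beta are cast from the luminal center of mass and intersected with
the intima outer contour (farthest intersection when several exist). The
measurement line L_alpha runs through the central intimal point,
perpendicular to the chord joining the two auxiliary points. Media
thickness is the distance from the intimal point to the closest media
intersection in the outward sense of L_alpha; intima thickness is the
distance to the closest lumen intersection in the inward sense.

Two exclusion mechanisms handle irregular artery appearances:

* open lumen (edge cuts): samples where both thicknesses fall below a
  minimal plausible value are flagged, then a circular moving window
  discards whole windows containing too many such samples;
* multiple lumens/intimas (tangential cuts): the lumen-intima pair with
  the largest combined area is measured, and angles whose central ray
  crosses any remaining lumen or intima contour are discarded together
  with a window of neighbors.

Flagged samples keep their raw values but are marked invalid; downstream
statistics use valid samples only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contour import ArteryAnnotation, Contour
from .geometry import (
    Ray,
    center_of_mass,
    line_intersections,
    measurement_line,
    pick_intersection,
    ray_intersections,
)

__all__ = [
    "EXCLUSION_TOKENS",
    "MeasurementConfig",
    "ThicknessProfile",
    "select_primary_lumen_intima",
    "measure_at_angle",
    "flag_open_lumen",
    "flag_cross_intersections",
    "measure_profile",
]

# exclusion tokens, in increasing order of processing stage
EXCL_NONE = "none"
EXCL_MISSING = "missing"
EXCL_OPEN = "open_lumen"
EXCL_OPEN_WINDOW = "open_lumen_window"
EXCL_CROSS = "cross_intersection"
EXCL_CROSS_WINDOW = "cross_window"
EXCLUSION_TOKENS = (EXCL_NONE, EXCL_MISSING, EXCL_OPEN, EXCL_OPEN_WINDOW, EXCL_CROSS, EXCL_CROSS_WINDOW)

#: minimum overlap fraction for "lumen contained in intima"
_CONTAIN_FRACTION = 0.95


@dataclass(frozen=True)
class MeasurementConfig:
    """Tunables of the radial measurement stage.

    beta_deg
        Offset of the two auxiliary rays (degrees).
    n_angles
        Number of equally spaced sampling angles over the full turn.
    open_lumen_threshold
        Minimal plausible thickness (pixels); samples with *both* media
        and intima thickness below it are treated as open-lumen samples.
    window_size
        Width (samples, odd) of the circular moving window used by both
        exclusion mechanisms.
    window_count_limit
        Maximum number of open-lumen samples tolerated per window before
        the whole window is discarded.
    """

    beta_deg: float = 5.0
    n_angles: int = 360
    open_lumen_threshold: float = 2.0
    window_size: int = 15
    window_count_limit: int = 3

    def __post_init__(self) -> None:
        if self.n_angles < 8:
            raise ValueError("n_angles must be >= 8")
        if not (0 < self.beta_deg < 90):
            raise ValueError("beta_deg must be in (0, 90)")
        if self.window_size % 2 != 1:
            raise ValueError("window_size must be odd")
        if self.open_lumen_threshold <= 0:
            raise ValueError("open_lumen_threshold must be positive")


@dataclass
class ThicknessProfile:
    """Per-angle media/intima thickness with validity bookkeeping.

    Thickness arrays hold NaN where a measurement is missing. The series
    is circular: the first and last angles are adjacent. ``valid`` is
    False exactly where the exclusion reason differs from ``"none"``.
    """

    angles_deg: np.ndarray
    media: np.ndarray
    intima: np.ndarray
    valid: np.ndarray
    exclusion_reason: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.angles_deg)
        for name in ("media", "intima", "valid", "exclusion_reason"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match angles")

    @property
    def n(self) -> int:
        return len(self.angles_deg)

    @property
    def wall(self) -> np.ndarray:
        """Per-angle wall thickness, media + intima."""
        return self.media + self.intima

    def copy(self) -> "ThicknessProfile":
        return ThicknessProfile(
            self.angles_deg.copy(),
            self.media.copy(),
            self.intima.copy(),
            self.valid.copy(),
            self.exclusion_reason.copy(),
            dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        wall = self.media + self.intima
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(wall > 0, self.intima / wall, np.nan)
        return pd.DataFrame(
            {
                "angle_deg": self.angles_deg,
                "media_thickness": self.media,
                "intima_thickness": self.intima,
                "ratio": ratio,
                "valid": self.valid,
                "exclusion_reason": self.exclusion_reason,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ThicknessProfile":
        return cls(
            frame["angle_deg"].to_numpy(dtype=float),
            frame["media_thickness"].to_numpy(dtype=float),
            frame["intima_thickness"].to_numpy(dtype=float),
            frame["valid"].to_numpy(dtype=bool),
            frame["exclusion_reason"].to_numpy(dtype=object),
        )


def _new_profile(cfg: MeasurementConfig) -> ThicknessProfile:
    n = cfg.n_angles
    return ThicknessProfile(
        angles_deg=np.arange(n) * (360.0 / n),
        media=np.full(n, np.nan),
        intima=np.full(n, np.nan),
        valid=np.zeros(n, dtype=bool),
        exclusion_reason=np.full(n, EXCL_MISSING, dtype=object),
    )


def select_primary_lumen_intima(
    annotation: ArteryAnnotation,
) -> tuple[Contour, Contour, list[Contour]]:
    """Pick the lumen-intima pair to measure on a multi-instance artery.

    Among all (lumen, intima) pairs where the lumen lies inside the intima
    the pair maximizing intima area + lumen area is selected. Every other
    lumen and intima contour is returned as an obstacle list for the
    cross-intersection check.
    """
    if not annotation.lumens:
        raise ValueError("occluded or missing lumen: no lumen contour to measure from")
    best = None
    for intima in annotation.intimas:
        for lumen in annotation.lumens:
            if intima.contains_fraction(lumen) < _CONTAIN_FRACTION:
                continue
            score = intima.area + lumen.area
            if best is None or score > best[0]:
                best = (score, lumen, intima)
    if best is None:
        raise ValueError("no containment-consistent lumen-intima pair found")
    _, lumen, intima = best
    others = [c for c in annotation.intimas if c is not intima]
    others += [c for c in annotation.lumens if c is not lumen]
    return lumen, intima, others


def measure_at_angle(
    com: np.ndarray,
    media: Contour,
    intima: Contour,
    lumen: Contour,
    alpha_deg: float,
    config: MeasurementConfig,
) -> tuple[float, float]:
    """Measure media and intima thickness at one angle.

    Returns ``(t_media, t_intima)`` in pixels; either may be NaN when the
    corresponding intersection does not exist (recorded as a missing
    sample, not as zero).
    """
    beta = config.beta_deg
    p_i = {}
    for off in (-beta, 0.0, beta):
        _, pts, _ = ray_intersections(Ray(tuple(com), alpha_deg + off), intima)
        p_i[off] = pick_intersection(pts, "farthest")
    if p_i[0.0] is None or p_i[-beta] is None or p_i[beta] is None:
        return np.nan, np.nan
    line = measurement_line(p_i[-beta], p_i[0.0], p_i[beta], outward_from=com)

    t_m, _, _ = line_intersections(line.anchor, line.direction, media)
    outward = t_m[t_m > 1e-9]
    t_media = float(outward[0]) if len(outward) else np.nan

    t_l, _, _ = line_intersections(line.anchor, line.direction, lumen)
    inward = t_l[t_l < -1e-9]
    t_intima = float(-inward[-1]) if len(inward) else np.nan
    return t_media, t_intima


_T_MIN = 1e-9
_EPS = 1e-12


def _batch_farthest_ray(com: np.ndarray, angles_deg: np.ndarray, contour: Contour) -> np.ndarray:
    """Farthest ray-contour intersection point for many angles at once.

    Vectorized equivalent of casting each ray and keeping the farthest
    hit; rows with no hit are NaN. Same half-open edge convention as
    :func:`arterymetrics.geometry.line_intersections`.
    """
    rad = np.deg2rad(angles_deg)
    d = np.column_stack([np.cos(rad), np.sin(rad)])  # (m, 2)
    a, e = contour.segments
    f = a - com  # (n, 2)
    num_t = f[:, 0] * e[:, 1] - f[:, 1] * e[:, 0]  # cross(f, e), (n,)
    denom = d[:, 0, None] * e[None, :, 1] - d[:, 1, None] * e[None, :, 0]  # (m, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num_t[None, :] / denom
        s = (f[None, :, 0] * d[:, 1, None] - f[None, :, 1] * d[:, 0, None]) / denom
    ok = (np.abs(denom) > _EPS) & (s >= 0.0) & (s < 1.0) & (t > _T_MIN)
    t_far = np.max(np.where(ok, t, -np.inf), axis=1)
    hit = np.isfinite(t_far) & (t_far > 0)
    pts = com + t_far[:, None] * d
    pts[~hit] = np.nan
    return pts


def _batch_line_extreme(
    anchors: np.ndarray, directions: np.ndarray, contour: Contour, sense: str
) -> np.ndarray:
    """Signed distance to the closest contour crossing per measurement line.

    ``sense='outward'`` returns the smallest positive line parameter,
    ``sense='inward'`` the magnitude of the negative parameter closest to
    the anchor. NaN where the line does not cross in that sense.
    """
    a, e = contour.segments
    f = a[None, :, :] - anchors[:, None, :]  # (m, n, 2)
    denom = directions[:, 0, None] * e[None, :, 1] - directions[:, 1, None] * e[None, :, 0]
    num_t = f[:, :, 0] * e[None, :, 1] - f[:, :, 1] * e[None, :, 0]
    num_s = f[:, :, 0] * directions[:, 1, None] - f[:, :, 1] * directions[:, 0, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num_t / denom
        s = num_s / denom
    ok = (np.abs(denom) > _EPS) & (s >= 0.0) & (s < 1.0)
    if sense == "outward":
        cand = np.where(ok & (t > _T_MIN), t, np.inf)
        best = cand.min(axis=1)
        return np.where(np.isfinite(best), best, np.nan)
    cand = np.where(ok & (t < -_T_MIN), t, -np.inf)
    best = cand.max(axis=1)
    return np.where(np.isfinite(best), -best, np.nan)


def _batch_measure(
    com: np.ndarray,
    media: Contour,
    intima: Contour,
    lumen: Contour,
    angles_deg: np.ndarray,
    cfg: MeasurementConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-angle measurement over the whole angle grid."""
    beta = cfg.beta_deg
    p_mid = _batch_farthest_ray(com, angles_deg, intima)
    p_left = _batch_farthest_ray(com, angles_deg - beta, intima)
    p_right = _batch_farthest_ray(com, angles_deg + beta, intima)
    chord = p_right - p_left
    norm = np.hypot(chord[:, 0], chord[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        normal = np.column_stack([-chord[:, 1], chord[:, 0]]) / norm[:, None]
    # orient outward (away from the luminal center of mass)
    away = p_mid - com
    flip = np.einsum("ij,ij->i", normal, away) < 0
    normal[flip] *= -1
    usable = (
        np.isfinite(p_mid).all(axis=1)
        & np.isfinite(normal).all(axis=1)
        & (norm > _EPS)
    )
    n = len(angles_deg)
    t_media = np.full(n, np.nan)
    t_intima = np.full(n, np.nan)
    if usable.any():
        anchors = p_mid[usable]
        dirs = normal[usable]
        t_media[usable] = _batch_line_extreme(anchors, dirs, media, "outward")
        t_intima[usable] = _batch_line_extreme(anchors, dirs, lumen, "inward")
    return t_media, t_intima


def _batch_ray_hits_any(com: np.ndarray, angles_deg: np.ndarray, contour: Contour) -> np.ndarray:
    """Boolean per angle: does the half-line cross the contour at all."""
    rad = np.deg2rad(angles_deg)
    d = np.column_stack([np.cos(rad), np.sin(rad)])
    a, e = contour.segments
    f = a - com
    num_t = f[:, 0] * e[:, 1] - f[:, 1] * e[:, 0]
    denom = d[:, 0, None] * e[None, :, 1] - d[:, 1, None] * e[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num_t[None, :] / denom
        s = (f[None, :, 0] * d[:, 1, None] - f[None, :, 1] * d[:, 0, None]) / denom
    ok = (np.abs(denom) > _EPS) & (s >= 0.0) & (s < 1.0) & (t > _T_MIN)
    return ok.any(axis=1)


def _circular_windows(n: int, window: int) -> np.ndarray:
    """Index matrix (n, window): circular window centered at each sample."""
    h = window // 2
    offsets = np.arange(-h, h + 1)
    return (np.arange(n)[:, None] + offsets[None, :]) % n


def flag_open_lumen(profile: ThicknessProfile, config: MeasurementConfig) -> ThicknessProfile:
    """Flag open-lumen samples and their neighborhoods.

    A sample is an open-lumen sample when both thickness values exist and
    both are below ``open_lumen_threshold``. Every circular window of
    ``window_size`` samples containing more than ``window_count_limit``
    open-lumen samples is then discarded entirely.
    """
    out = profile.copy()
    both = np.isfinite(out.media) & np.isfinite(out.intima)
    open_mask = both & (out.media < config.open_lumen_threshold) & (out.intima < config.open_lumen_threshold)
    windows = _circular_windows(out.n, config.window_size)
    counts = open_mask[windows].sum(axis=1)
    bad_windows = counts > config.window_count_limit
    window_mask = np.zeros(out.n, dtype=bool)
    if bad_windows.any():
        window_mask[np.unique(windows[bad_windows])] = True
    _apply_flags(out, open_mask, EXCL_OPEN)
    _apply_flags(out, window_mask & ~open_mask, EXCL_OPEN_WINDOW)
    return out


def flag_cross_intersections(
    profile: ThicknessProfile,
    others: list[Contour],
    com: np.ndarray,
    config: MeasurementConfig,
) -> ThicknessProfile:
    """Flag angles whose central ray crosses a non-primary lumen or intima.

    The full half-line from the center of mass is tested against every
    obstacle contour; hits flag the angle, and all samples within half a
    window of a hit (circularly) are flagged as neighbors.
    """
    out = profile.copy()
    if not others:
        return out
    hit = np.zeros(out.n, dtype=bool)
    for contour in others:
        hit |= _batch_ray_hits_any(np.asarray(com, dtype=float), out.angles_deg, contour)
    if hit.any():
        h = config.window_size // 2
        neighbor = np.zeros(out.n, dtype=bool)
        idx = np.nonzero(hit)[0]
        for off in range(-h, h + 1):
            neighbor[(idx + off) % out.n] = True
        _apply_flags(out, hit, EXCL_CROSS)
        _apply_flags(out, neighbor & ~hit, EXCL_CROSS_WINDOW)
    return out


def _apply_flags(profile: ThicknessProfile, mask: np.ndarray, token: str) -> None:
    """Set an exclusion token where ``mask`` holds, keeping raw values."""
    current = profile.exclusion_reason
    overwrite = mask & ((current == EXCL_NONE) | (current == EXCL_MISSING))
    profile.exclusion_reason[overwrite] = token
    profile.valid[mask] = False


def measure_profile(annotation: ArteryAnnotation, config: MeasurementConfig | None = None) -> ThicknessProfile:
    """Run the full radial measurement for one artery.

    Selection of the primary lumen-intima pair, per-angle measurement at
    ``n_angles`` equally spaced angles, open-lumen flagging, and
    cross-intersection flagging, in that order.
    """
    cfg = config or MeasurementConfig()
    lumen, intima, others = select_primary_lumen_intima(annotation)
    com = center_of_mass(lumen)
    profile = _new_profile(cfg)
    t_media, t_intima = _batch_measure(com, annotation.media, intima, lumen, profile.angles_deg, cfg)
    profile.media[:] = t_media
    profile.intima[:] = t_intima
    both = np.isfinite(t_media) & np.isfinite(t_intima)
    profile.valid[both] = True
    profile.exclusion_reason[both] = EXCL_NONE
    profile = flag_open_lumen(profile, cfg)
    profile = flag_cross_intersections(profile, others, com, cfg)
    profile.meta.update(
        artery_id=annotation.artery_id,
        pixel_size_um=annotation.pixel_size_um,
        com=tuple(np.asarray(com, dtype=float)),
        n_others=len(others),
    )
    return profile
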
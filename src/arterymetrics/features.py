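"""Pathomic feature extraction from conditioned thickness profiles.

Three circular series are characterized per artery: media thickness,
intima thickness, and the per-angle intima-media ratio
``R = T_intima / (T_intima + T_media)``. For each series the global
features are the average, median, and (population) variance over valid
angles, and the local features are the maximum height and maximum
topographic prominence over peaks whose width exceeds a threshold
``theta_w``. Three baseline area features are computed directly from the
annotation polygons: media band area, intima band area, and their ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .contour import ArteryAnnotation
from .measurement import MeasurementConfig, ThicknessProfile, measure_profile
from .signal import CircularSeries, condition, impute_missing

__all__ = [
    "PeakConfig",
    "Peak",
    "FEATURE_NAMES",
    "AREA_FEATURES",
    "THICKNESS_FEATURES",
    "ratio_series",
    "global_features",
    "find_peaks_circular",
    "local_features",
    "area_features",
    "extract_features",
]

SERIES_NAMES = ("media", "intima", "ratio")
_STAT_NAMES = ("average", "median", "variance", "peak_height", "peak_prominence")
THICKNESS_FEATURES = tuple(f"{s}_{stat}" for s in SERIES_NAMES for stat in _STAT_NAMES)
AREA_FEATURES = ("media_area", "intima_area", "ratio_intima_media_area")
FEATURE_NAMES = THICKNESS_FEATURES + AREA_FEATURES

#: sentinel for local features when no peak passes the width threshold:
#: zero, read as "no local excursion"
NO_PEAK = 0.0


@dataclass(frozen=True)
class PeakConfig:
    """Peak detection tunables.

    ``theta_w``: minimum peak width in samples. ``min_prominence`` is a
    numerical floor (the series is dimensionless and of order 1 after
    normalization) that keeps floating-point jitter on flat series from
    registering as peaks.
    """

    theta_w: int = 10
    min_prominence: float = 1e-6

    def __post_init__(self) -> None:
        if self.theta_w < 1:
            raise ValueError("theta_w must be >= 1")
        if self.min_prominence < 0:
            raise ValueError("min_prominence must be >= 0")


@dataclass(frozen=True)
class Peak:
    location_deg: float
    location_idx: int
    height: float
    prominence: float
    width: float


def ratio_series(profile: ThicknessProfile) -> CircularSeries:
    """Per-angle intima-media ratio ``T_i / (T_i + T_m)`` over valid angles.

    Invalid angles map to NaN. Values are bounded in [0, 1].
    """
    wall = profile.media + profile.intima
    usable = profile.valid & np.isfinite(wall)
    if usable.any() and np.any(wall[usable] <= 0):
        raise ValueError("zero wall thickness at a valid angle")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(usable, profile.intima / wall, np.nan)
    return CircularSeries(values, "ratio")


def global_features(series: CircularSeries) -> tuple[float, float, float]:
    """Average, median, and population variance over valid entries."""
    vals = series.values[np.isfinite(series.values)]
    if len(vals) == 0:
        raise ValueError("no valid entries for global features")
    return float(np.mean(vals)), float(np.median(vals)), float(np.var(vals))


def find_peaks_circular(series: CircularSeries, config: PeakConfig | None = None) -> list[Peak]:
    """Detect peaks on a circular series with a minimum-width criterion.

    The series is tiled three times and peaks are read off the central
    copy, so maxima straddling the wrap-around boundary are found once.
    Missing entries are bridged by inverse-distance imputation for the
    purpose of detection; peaks whose apex falls on a bridged (invalid)
    angle are discarded.
    """
    cfg = config or PeakConfig()
    values = series.values
    n = len(values)
    invalid = ~np.isfinite(values)
    if invalid.all():
        return []
    if invalid.any():
        if np.isfinite(values).sum() < 2:
            return []
        values = impute_missing(CircularSeries(values, series.name)).values
    ext = np.concatenate([values, values, values])
    idx, props = find_peaks(ext, width=cfg.theta_w, prominence=cfg.min_prominence)
    peaks: list[Peak] = []
    seen: set[int] = set()
    step = 360.0 / n
    for j, p in enumerate(idx):
        if not (n <= p < 2 * n):
            continue
        loc = int(p - n)
        if loc in seen or invalid[loc]:
            continue
        seen.add(loc)
        peaks.append(
            Peak(
                location_deg=loc * step,
                location_idx=loc,
                height=float(values[loc]),
                prominence=float(props["prominences"][j]),
                width=float(props["widths"][j]),
            )
        )
    return peaks


def local_features(peaks: list[Peak]) -> tuple[float, float]:
    """Maximum peak height and maximum prominence (possibly from
    different peaks); the no-peak sentinel is 0."""
    if not peaks:
        return NO_PEAK, NO_PEAK
    return max(p.height for p in peaks), max(p.prominence for p in peaks)


def area_features(annotation: ArteryAnnotation, physical_units: bool = True) -> tuple[float, float, float]:
    """Baseline compartment band areas and their ratio.

    media band = media outer polygon area minus total intima outer area;
    intima band = total intima outer area minus total lumen area;
    ratio = intima band / media band. Areas are in square microns when
    ``physical_units`` is set, else square pixels.
    """
    media_outer = annotation.media.area
    intima_outer = sum(c.area for c in annotation.intimas)
    lumen_total = sum(c.area for c in annotation.lumens)
    media_band = media_outer - intima_outer
    intima_band = intima_outer - lumen_total
    if media_band <= 0 or intima_band < 0:
        raise ValueError("degenerate compartment areas; check annotation nesting")
    scale = annotation.pixel_size_um**2 if physical_units else 1.0
    ratio = intima_band / media_band
    return media_band * scale, intima_band * scale, ratio


def _series_features(series: CircularSeries, peak_cfg: PeakConfig) -> dict[str, float]:
    avg, med, var = global_features(series)
    height, prom = local_features(find_peaks_circular(series, peak_cfg))
    name = series.name
    return {
        f"{name}_average": avg,
        f"{name}_median": med,
        f"{name}_variance": var,
        f"{name}_peak_height": height,
        f"{name}_peak_prominence": prom,
    }


def extract_features(
    annotation: ArteryAnnotation,
    measurement_config: MeasurementConfig | None = None,
    peak_config: PeakConfig | None = None,
    filter_window: int = 9,
    profile: ThicknessProfile | None = None,
) -> dict[str, float]:
    """Assemble the full per-artery feature vector.

    Runs measurement and conditioning (unless a raw ``profile`` is
    supplied, which is then conditioned here), extracts the 15
    thickness-based features and the 3 area baselines, and returns a flat
    dict including ``artery_id`` and ``score``.
    """
    peak_cfg = peak_config or PeakConfig()
    if profile is None:
        profile = measure_profile(annotation, measurement_config)
    conditioned = condition(profile, filter_window=filter_window)

    row: dict[str, float] = {"artery_id": annotation.artery_id, "score": annotation.score}
    for name in ("media", "intima"):
        vals = np.where(conditioned.valid, getattr(conditioned, name), np.nan)
        row.update(_series_features(CircularSeries(vals, name), peak_cfg))
    row.update(_series_features(ratio_series(conditioned), peak_cfg))

    media_area, intima_area, ratio_area = area_features(annotation)
    row["media_area"] = media_area
    row["intima_area"] = intima_area
    row["ratio_intima_media_area"] = ratio_area
    return row
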
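"""Circular signal conditioning for thickness profiles.

The measurement series are circular (first and last angles adjacent), so
all window operations wrap around. Conditioning applies, in order:

1. circular moving median (outlier suppression),
2. circular moving average (smoothing),
3. inverse-distance weighted imputation of missing values from the
   nearest valid neighbors on either side,
4. normalization by the median wall thickness (media + intima), making
   the series dimensionless and resolution independent.

Samples excluded by the appearance flags are treated as missing while
filtering (they do not contribute to window statistics) but are not
imputed back into validity: they keep their raw values and stay invalid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .measurement import EXCL_MISSING, EXCL_NONE, ThicknessProfile

__all__ = [
    "CircularSeries",
    "moving_median",
    "moving_average",
    "impute_missing",
    "normalize_profile",
    "condition",
]


@dataclass(frozen=True)
class CircularSeries:
    """A circular per-angle series with NaN marking missing entries."""

    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.values).sum())


def _window_matrix(values: np.ndarray, window: int) -> np.ndarray:
    """Stack circular shifts so column j holds the window around index j."""
    h = window // 2
    return np.vstack([np.roll(values, -k) for k in range(-h, h + 1)])


def _check_window(series: CircularSeries, window: int) -> None:
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be an odd positive integer")
    if series.n_valid < window:
        raise ValueError("series has fewer valid entries than the window size")


def moving_median(series: CircularSeries, window: int) -> CircularSeries:
    """Circular moving median over the valid entries of each window.

    Missing entries stay missing and do not contribute to any window.
    """
    _check_window(series, window)
    stacked = _window_matrix(series.values, window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        out = np.nanmedian(stacked, axis=0)
    out[~np.isfinite(series.values)] = np.nan
    return CircularSeries(out, series.name)


def moving_average(series: CircularSeries, window: int) -> CircularSeries:
    """Circular moving average over the valid entries of each window."""
    _check_window(series, window)
    stacked = _window_matrix(series.values, window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(stacked, axis=0)
    out[~np.isfinite(series.values)] = np.nan
    return CircularSeries(out, series.name)


def _nearest_valid(valid_idx: np.ndarray, i: int, n: int) -> tuple[int, int, int, int]:
    """Nearest valid indices left/right of ``i`` with circular distances."""
    d = (i - valid_idx) % n  # circular distance going left (backwards)
    d[d == 0] = n
    left = valid_idx[np.argmin(d)]
    d_left = int(d.min())
    d2 = (valid_idx - i) % n  # going right (forwards)
    d2[d2 == 0] = n
    right = valid_idx[np.argmin(d2)]
    d_right = int(d2.min())
    return left, d_left, right, d_right


def impute_missing(series: CircularSeries, fill_mask: np.ndarray | None = None) -> CircularSeries:
    """Fill missing entries by inverse-distance weighting of neighbors.

    A missing entry at index i is filled with
    ``(w_l * l_left + w_r * l_right) / (w_l + w_r)`` where ``l_left`` and
    ``l_right`` are the nearest valid entries circularly left and right,
    and the weights are the inverse circular index distances. With
    ``fill_mask`` given, only missing entries inside the mask are filled.
    """
    values = series.values.copy()
    missing = ~np.isfinite(values)
    if fill_mask is not None:
        missing = missing & np.asarray(fill_mask, dtype=bool)
    if not missing.any():
        return CircularSeries(values, series.name)
    valid_idx = np.nonzero(np.isfinite(series.values))[0]
    if len(valid_idx) < 2:
        raise ValueError("series too sparse to impute: fewer than 2 valid entries")
    n = series.n
    for i in np.nonzero(missing)[0]:
        left, d_left, right, d_right = _nearest_valid(valid_idx, int(i), n)
        w_left, w_right = 1.0 / d_left, 1.0 / d_right
        values[i] = (w_left * series.values[left] + w_right * series.values[right]) / (w_left + w_right)
    return CircularSeries(values, series.name)


def normalize_profile(profile: ThicknessProfile) -> ThicknessProfile:
    """Divide both thickness series by the median valid wall thickness.

    The wall thickness at an angle is media + intima; the median is taken
    over valid angles only, so the conditioned profile has median wall
    thickness exactly 1 and is invariant under uniform spatial scaling of
    the annotation.
    """
    out = profile.copy()
    wall = out.media + out.intima
    usable = out.valid & np.isfinite(wall)
    if not usable.any():
        raise ValueError("no valid samples to normalize by")
    med = float(np.median(wall[usable]))
    if med <= 0:
        raise ValueError("median wall thickness is zero")
    out.media = out.media / med
    out.intima = out.intima / med
    out.meta["normalized"] = True
    out.meta["wall_median_px"] = med
    return out


def condition(
    profile: ThicknessProfile,
    filter_window: int = 9,
    return_stages: bool = False,
) -> ThicknessProfile | tuple[ThicknessProfile, dict]:
    """Full conditioning pipeline: filter, impute, normalize.

    Moving median then moving average are applied to the valid portion of
    each series; gaps that are plainly missing (no exclusion flag) are
    then imputed and become valid; flagged samples keep their raw values
    and stay invalid. Normalization by the median wall thickness runs
    last. With ``return_stages`` the intermediate snapshots are returned
    for pipeline-order inspection.
    """
    out = profile.copy()
    reasons = out.exclusion_reason
    fillable = reasons == EXCL_MISSING
    stages: dict[str, dict[str, np.ndarray]] = {}

    conditioned = {}
    for name in ("media", "intima"):
        raw = getattr(out, name)
        work = np.where(out.valid, raw, np.nan)
        med = moving_median(CircularSeries(work, name), filter_window)
        avg = moving_average(med, filter_window)
        imp = impute_missing(avg, fill_mask=fillable)
        stages.setdefault("filtered_median", {})[name] = med.values
        stages.setdefault("filtered_average", {})[name] = avg.values
        stages.setdefault("imputed", {})[name] = imp.values
        conditioned[name] = imp.values

    for name in ("media", "intima"):
        filled = conditioned[name]
        raw = getattr(out, name)
        # flagged samples retain raw values; valid + imputed get conditioned ones
        setattr(out, name, np.where(np.isfinite(filled), filled, raw))

    newly_valid = fillable & np.isfinite(out.media) & np.isfinite(out.intima)
    out.valid = out.valid | newly_valid
    out.exclusion_reason[newly_valid] = EXCL_NONE
    out.meta["imputed_angles"] = out.angles_deg[newly_valid].tolist()

    out = normalize_profile(out)
    out.meta["filter_window"] = filter_window
    if return_stages:
        return out, stages
    return out
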
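"""Independent brute-force oracles used only by the tests.

Each oracle re-derives a quantity by a different route than the library:
pixel marching on supersampled rasters for thickness, O(n^2) pair counting
for rank correlation, per-index sorting for the circular filters, and
direct formula evaluation for imputation and agreement statistics.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import polygon as fill_polygon

from arterymetrics.contour import ArteryAnnotation
from arterymetrics.geometry import resample_contour


# ---------------------------------------------------------------------------
# raster pixel-marching thickness oracle
# ---------------------------------------------------------------------------

def _filled_mask(points: np.ndarray, shape: tuple[int, int], scale: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = fill_polygon(points[:, 1] * scale, points[:, 0] * scale, shape=shape)
    mask[rr, cc] = True
    return mask


class RasterOracle:
    """Thickness by marching along rays on supersampled filled masks."""

    def __init__(self, annotation: ArteryAnnotation, canvas: int, scale: int = 4, step: float = 0.25):
        self.scale = scale
        self.step = step
        shape = (canvas * scale, canvas * scale)
        lumen = max(annotation.lumens, key=lambda c: c.area)
        intima = max(annotation.intimas, key=lambda c: c.area)
        self.media_mask = _filled_mask(annotation.media.points, shape, scale)
        self.intima_mask = _filled_mask(intima.points, shape, scale)
        self.lumen_mask = _filled_mask(lumen.points, shape, scale)
        self.com = resample_contour(lumen.points, 1.0).mean(axis=0)
        self.r_max = float(np.hypot(canvas, canvas))

    def _inside(self, mask: np.ndarray, pts: np.ndarray) -> np.ndarray:
        ij = np.round(pts[:, ::-1] * self.scale).astype(int)  # (y, x) -> (row, col)
        ij = np.clip(ij, 0, np.array(mask.shape) - 1)
        return mask[ij[:, 0], ij[:, 1]]

    def _march_last_exit(self, origin: np.ndarray, direction: np.ndarray, mask: np.ndarray) -> np.ndarray | None:
        """Farthest inside->outside boundary crossing along a half-line."""
        t = np.arange(self.step, self.r_max, self.step)
        pts = origin + t[:, None] * direction
        status = self._inside(mask, pts)
        exits = np.nonzero(status[:-1] & ~status[1:])[0]
        if len(exits) == 0:
            return None
        k = exits[-1]
        return origin + 0.5 * (t[k] + t[k + 1]) * direction

    def _march_first_change(self, origin: np.ndarray, direction: np.ndarray, mask: np.ndarray) -> float | None:
        """Distance to the first boundary crossing along a half-line."""
        t = np.arange(self.step, self.r_max, self.step)
        pts = origin + t[:, None] * direction
        status = self._inside(mask, pts)
        changes = np.nonzero(status[:-1] != status[1:])[0]
        # also catch a change within the first step
        start_inside = self._inside(mask, origin[None, :])[0]
        if status[0] != start_inside:
            return 0.5 * (self.step + 0.0)
        if len(changes) == 0:
            return None
        k = changes[0]
        return 0.5 * (t[k] + t[k + 1])

    def measure(self, alpha_deg: float, beta_deg: float = 5.0) -> tuple[float, float]:
        p = {}
        for off in (-beta_deg, 0.0, beta_deg):
            a = np.deg2rad(alpha_deg + off)
            d = np.array([np.cos(a), np.sin(a)])
            p[off] = self._march_last_exit(self.com, d, self.intima_mask)
        if any(v is None for v in p.values()):
            return np.nan, np.nan
        chord = p[beta_deg] - p[-beta_deg]
        normal = np.array([-chord[1], chord[0]])
        normal /= np.hypot(*normal)
        if np.dot(normal, p[0.0] - self.com) < 0:
            normal = -normal
        t_media = self._march_first_change(p[0.0], normal, self.media_mask)
        t_intima = self._march_first_change(p[0.0], -normal, self.lumen_mask)
        return (
            np.nan if t_media is None else float(t_media),
            np.nan if t_intima is None else float(t_intima),
        )


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------

def kendall_tau_b_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """O(n^2) concordant/discordant pair counting with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (concordant - discordant) / denom


def _tie_term(v: np.ndarray) -> float:
    _, counts = np.unique(v, return_counts=True)
    return float(np.sum(counts * (counts - 1) / 2))


def cohens_kappa_bruteforce(a: list, b: list) -> float:
    labels = sorted(set(a) | set(b))
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    p_e = 0.0
    for lab in labels:
        p_e += (sum(x == lab for x in a) / n) * (sum(y == lab for y in b) / n)
    return (p_o - p_e) / (1 - p_e)


def moving_median_bruteforce(values: np.ndarray, window: int) -> np.ndarray:
    """Per-index circular sort-and-pick median over valid neighbors."""
    n = len(values)
    h = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        if not np.isfinite(values[i]):
            continue
        neighbors = [values[(i + k) % n] for k in range(-h, h + 1)]
        neighbors = [v for v in neighbors if np.isfinite(v)]
        out[i] = float(np.median(neighbors))
    return out


def impute_bruteforce(values: np.ndarray) -> np.ndarray:
    """Direct evaluation of inverse-distance neighbor imputation."""
    n = len(values)
    out = values.copy()
    valid = [i for i in range(n) if np.isfinite(values[i])]
    for i in range(n):
        if np.isfinite(values[i]):
            continue
        d_left = min((i - j) % n for j in valid)
        d_right = min((j - i) % n for j in valid)
        left = [j for j in valid if (i - j) % n == d_left][0]
        right = [j for j in valid if (j - i) % n == d_right][0]
        w_l, w_r = 1.0 / d_left, 1.0 / d_right
        out[i] = (w_l * values[left] + w_r * values[right]) / (w_l + w_r)
    return out
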
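"""Statistical evaluation: overlap, ordinal association, and agreement.

Dice overlap for segmentation masks, Kendall tau-b (tie corrected) for
feature-versus-grade association, ridge regression R-squared for
multivariate feature-set comparison, and Cohen's kappa with its confusion
matrix for inter-observer agreement.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge
from sklearn.preprocessing import StandardScaler

from .features import AREA_FEATURES, THICKNESS_FEATURES

__all__ = [
    "FEATURE_SUBSETS",
    "dice",
    "kendall_tau_b",
    "feature_score_associations",
    "ridge_r2",
    "cohens_kappa",
]

FEATURE_SUBSETS = {
    "area_only": list(AREA_FEATURES),
    "thickness_only": list(THICKNESS_FEATURES),
    "combined": list(THICKNESS_FEATURES) + list(AREA_FEATURES),
}


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|A∩B| / (|A| + |B|)`` of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def kendall_tau_b(feature: np.ndarray, score: np.ndarray) -> tuple[float, float]:
    """Kendall tau-b with tie correction and a two-sided normal p-value."""
    x = np.asarray(feature, dtype=float)
    y = np.asarray(score, dtype=float)
    if len(x) != len(y):
        raise ValueError("feature and score lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("no variation in one of the inputs")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def feature_score_associations(table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Per-feature tau-b against the ordinal score column."""
    names = features or FEATURE_SUBSETS["combined"]
    rows = []
    for name in names:
        tau, p = kendall_tau_b(table[name].to_numpy(), table["score"].to_numpy())
        rows.append({"feature": name, "tau": tau, "p_value": p})
    return pd.DataFrame(rows)


def ridge_r2(table: pd.DataFrame, subset: str = "combined", alpha: float = 1.0) -> float:
    """In-sample R-squared of ridge regression of score on a feature subset.

    Features are standardized before fitting; ``subset`` is one of
    ``area_only``, ``thickness_only``, ``combined``.
    """
    if subset not in FEATURE_SUBSETS:
        raise ValueError(f"unknown subset {subset!r}")
    if len(table) < 10:
        raise ValueError("need at least 10 arteries for a ridge fit")
    if table["score"].isna().any():
        raise ValueError("scores must be complete")
    cols = FEATURE_SUBSETS[subset]
    X = StandardScaler().fit_transform(table[cols].to_numpy(dtype=float))
    y = table["score"].to_numpy(dtype=float)
    model = Ridge(alpha=alpha).fit(X, y)
    return float(model.score(X, y))


def cohens_kappa(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: list | None = None
) -> tuple[float, np.ndarray]:
    """Cohen's kappa ``(p_o - p_e) / (1 - p_e)`` and the confusion matrix.

    Rows index rater A, columns rater B, in the order of ``labels``
    (default: sorted union of observed labels).
    """
    a = np.asarray(scores_a)
    b = np.asarray(scores_b)
    if len(a) != len(b):
        raise ValueError("rating lengths differ")
    if len(a) == 0:
        raise ValueError("empty ratings")
    if labels is None:
        labels = sorted(set(a.tolist()) | set(b.tolist()))
    index = {lab: k for k, lab in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)), dtype=int)
    for ai, bi in zip(a, b):
        m[index[ai], index[bi]] += 1
    n = m.sum()
    p_o = np.trace(m) / n
    p_e = float(np.dot(m.sum(axis=1), m.sum(axis=0))) / n**2
    if p_e == 1.0:
        return 1.0, m
    return float((p_o - p_e) / (1 - p_e)), m
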
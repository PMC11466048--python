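"""Annotation and result I/O.

Reads artery annotations either from GeoJSON polygon exports (QuPath
dialect: the compartment class sits in the feature's classification name)
or from single-channel multi-class label masks (PNG/TIFF, default labels
0/1/2/3 = background/media/intima/lumen). Masks are cleaned the standard
way for segmentation outputs: connected components and holes smaller than
a fraction of the class's positive pixel count are removed, and the
largest contour is taken as the media boundary while intima and lumen
multiplicity is preserved for the tangential-cut logic downstream.

Profiles and feature tables are written as plain CSV and round-trip
losslessly through the matching readers.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes
from skimage import draw as skdraw
from skimage import measure as skmeasure
from skimage.morphology import remove_small_holes, remove_small_objects

from .contour import ArteryAnnotation, Contour
from .measurement import ThicknessProfile

__all__ = [
    "DEFAULT_CLASS_LABELS",
    "read_annotation_geojson",
    "read_annotations_geojson",
    "annotation_to_geojson",
    "write_annotation_geojson",
    "read_label_mask",
    "clean_mask",
    "mask_to_annotation",
    "rasterize_annotation",
    "write_profile",
    "read_profile",
    "write_features",
    "read_features",
]

#: label value per compartment class in a label mask
DEFAULT_CLASS_LABELS = {"background": 0, "media": 1, "intima": 2, "lumen": 3}
_COMPARTMENTS = ("media", "intima", "lumen")


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------

def _classification_name(props: dict) -> str | None:
    cls = props.get("classification")
    if isinstance(cls, dict):
        cls = cls.get("name")
    if cls is None:
        cls = props.get("class")
    return cls if isinstance(cls, str) else None


def _feature_contour(feature: dict, index: int) -> Contour:
    geom = feature.get("geometry") or {}
    gtype = geom.get("type")
    try:
        if gtype == "Polygon":
            ring = geom["coordinates"][0]
        elif gtype == "MultiPolygon":
            # largest part by vertex count; QuPath rarely emits these
            ring = max(geom["coordinates"], key=lambda p: len(p[0]))[0]
        else:
            raise ValueError(f"unsupported geometry type {gtype!r}")
        return Contour(np.asarray(ring, dtype=float))
    except (KeyError, IndexError, TypeError, ValueError) as exc:
        raise ValueError(f"unparseable geometry in feature {index}: {exc}") from exc


def _group_features(
    features: list[dict], class_map: dict[str, str], group_key: str | None
) -> dict[str, dict[str, list[Contour]]]:
    groups: dict[str, dict[str, list[Contour]]] = {}
    for k, feature in enumerate(features):
        props = feature.get("properties") or {}
        name = _classification_name(props)
        cls = class_map.get(name.lower()) if name else None
        if cls is None:
            warnings.warn(f"skipping feature {k} with unknown classification {name!r}", stacklevel=3)
            continue
        gid = str(props.get(group_key, "artery")) if group_key else "artery"
        groups.setdefault(gid, {c: [] for c in _COMPARTMENTS})[cls].append(_feature_contour(feature, k))
    return groups


def read_annotations_geojson(
    path: str | Path,
    pixel_size_um: float = 0.25,
    class_map: dict[str, str] | None = None,
    group_key: str | None = None,
) -> list[ArteryAnnotation]:
    """Read one or more artery annotations from a GeoJSON file.

    ``class_map`` maps lowercased classification names onto the canonical
    compartments; the default accepts "media"/"intima"/"lumen" in any
    case. With ``group_key`` set, features are grouped into arteries by
    that property (e.g. a parent-annotation id); otherwise the file is
    treated as one artery. If ``group_key`` is None but the features all
    carry an ``artery_id`` property, that grouping is used automatically.
    """
    path = Path(path)
    data = json.loads(path.read_text())
    features = data.get("features", [])
    cmap = {c: c for c in _COMPARTMENTS}
    if class_map:
        cmap.update({k.lower(): v for k, v in class_map.items()})
    if group_key is None and features and all("artery_id" in (f.get("properties") or {}) for f in features):
        group_key = "artery_id"
    groups = _group_features(features, cmap, group_key)
    annotations = []
    for gid, comp in sorted(groups.items()):
        if not comp["media"]:
            raise ValueError(f"artery {gid!r} in {path.name} has no media contour")
        media = max(comp["media"], key=lambda c: c.area)
        score = None
        for f in features:
            props = f.get("properties") or {}
            if group_key is None or str(props.get(group_key, "artery")) == gid:
                if "score" in props and props["score"] is not None:
                    score = int(props["score"])
                    break
        annotations.append(
            ArteryAnnotation(
                media=media,
                intimas=comp["intima"],
                lumens=comp["lumen"],
                pixel_size_um=pixel_size_um,
                artery_id=gid if gid != "artery" else path.stem,
                score=score,
            )
        )
    return annotations


def read_annotation_geojson(path: str | Path, **kwargs) -> ArteryAnnotation:
    """Read a single-artery GeoJSON annotation (errors if several arteries)."""
    annotations = read_annotations_geojson(path, **kwargs)
    if len(annotations) != 1:
        raise ValueError(f"expected one artery in {path}, found {len(annotations)}")
    return annotations[0]


def annotation_to_geojson(annotation: ArteryAnnotation) -> dict:
    """Serialize an annotation as a QuPath-style FeatureCollection."""

    def feat(contour: Contour, cls: str) -> dict:
        ring = np.vstack([contour.points, contour.points[:1]]).tolist()
        props: dict = {
            "objectType": "annotation",
            "classification": {"name": cls},
            "artery_id": annotation.artery_id,
        }
        if annotation.score is not None:
            props["score"] = annotation.score
        return {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": props,
        }

    features = [feat(annotation.media, "media")]
    features += [feat(c, "intima") for c in annotation.intimas]
    features += [feat(c, "lumen") for c in annotation.lumens]
    return {"type": "FeatureCollection", "features": features}


def write_annotation_geojson(annotation: ArteryAnnotation, path: str | Path) -> None:
    Path(path).write_text(json.dumps(annotation_to_geojson(annotation)))


# ---------------------------------------------------------------------------
# label masks
# ---------------------------------------------------------------------------

def read_label_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel label mask from PNG/TIFF."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.int32)


def _clean_once(mask: np.ndarray, min_fraction: float, labels: dict[str, int]) -> np.ndarray:
    out = mask.copy()
    for cls in _COMPARTMENTS:
        value = labels[cls]
        binary = mask == value
        n = int(binary.sum())
        if n == 0:
            warnings.warn(f"class {cls!r} is empty; left unchanged", stacklevel=3)
            continue
        thr = min_fraction * n
        kept = remove_small_objects(binary, min_size=int(np.ceil(thr)))
        filled = remove_small_holes(kept, area_threshold=max(int(np.ceil(thr)) - 1, 0))
        out[binary & ~kept] = labels["background"]
        out[filled & ~kept & (out == labels["background"])] = value
        out[filled & kept] = value
    return out


def clean_mask(
    mask: np.ndarray,
    min_fraction: float = 0.05,
    labels: dict[str, int] | None = None,
    max_iter: int = 8,
) -> np.ndarray:
    """Remove small objects and holes from each compartment class.

    For each non-background class independently, connected components and
    holes with area below ``min_fraction`` of that class's positive pixel
    count are removed. The pass is iterated to a fixed point (bounded by
    ``max_iter``), which makes the operation idempotent.
    """
    if not (0 < min_fraction < 1):
        raise ValueError("min_fraction must be in (0, 1)")
    labels = labels or DEFAULT_CLASS_LABELS
    out = np.asarray(mask).copy()
    for _ in range(max_iter):
        new = _clean_once(out, min_fraction, labels)
        if np.array_equal(new, out):
            break
        out = new
    return out


def _component_contours(binary: np.ndarray) -> list[Contour]:
    """Outer contour of each connected component of a filled binary mask."""
    filled = binary_fill_holes(binary)
    labeled = skmeasure.label(filled)
    contours = []
    for region in skmeasure.regionprops(labeled):
        component = labeled == region.label
        found = skmeasure.find_contours(component.astype(float), 0.5)
        if not found:
            continue
        ring = max(found, key=len)  # outer boundary is the longest
        pts = np.column_stack([ring[:, 1], ring[:, 0]])  # (row, col) -> (x, y)
        if len(pts) >= 3:
            try:
                contours.append(Contour(pts))
            except ValueError:
                continue
    return contours


def mask_to_annotation(
    mask: np.ndarray,
    pixel_size_um: float = 0.25,
    labels: dict[str, int] | None = None,
    artery_id: str = "artery",
) -> ArteryAnnotation:
    """Extract compartment contours from a (cleaned) label mask.

    The media keeps only its largest-area contour; all intima and lumen
    contours are preserved so the measurement stage can handle multiple
    lumens from tangential cuts.
    """
    labels = labels or DEFAULT_CLASS_LABELS
    media_contours = _component_contours(mask == labels["media"])
    if not media_contours:
        raise ValueError("artery has no media")
    media = max(media_contours, key=lambda c: c.area)
    intimas = _component_contours(mask == labels["intima"])
    lumens = _component_contours(mask == labels["lumen"])
    if not intimas:
        raise ValueError("artery has no intima")
    return ArteryAnnotation(
        media=media,
        intimas=intimas,
        lumens=lumens,
        pixel_size_um=pixel_size_um,
        artery_id=artery_id,
    )


def rasterize_annotation(
    annotation: ArteryAnnotation,
    shape: tuple[int, int],
    labels: dict[str, int] | None = None,
) -> np.ndarray:
    """Render an annotation into a label mask (inner classes overwrite outer)."""
    labels = labels or DEFAULT_CLASS_LABELS
    mask = np.full(shape, labels["background"], dtype=np.int32)
    for cls, contours in (
        ("media", [annotation.media]),
        ("intima", annotation.intimas),
        ("lumen", annotation.lumens),
    ):
        for contour in contours:
            rr, cc = skdraw.polygon(contour.points[:, 1], contour.points[:, 0], shape=shape)
            mask[rr, cc] = labels[cls]
    return mask


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

def write_profile(profile: ThicknessProfile, path: str | Path) -> None:
    """Write a thickness profile as CSV, one row per angle."""
    profile.to_frame().to_csv(path, index=False)


def read_profile(path: str | Path) -> ThicknessProfile:
    return ThicknessProfile.from_frame(pd.read_csv(path))


def write_features(rows: list[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write per-artery feature vectors as CSV (header-only when empty)."""
    from .features import FEATURE_NAMES

    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        columns = ["artery_id", "score", *FEATURE_NAMES]
        frame = pd.DataFrame(rows, columns=columns if not rows else None)
    frame.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
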
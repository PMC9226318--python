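"""Annotation and mask I/O: LabelMe polygons, one-hot maps, indexed PNGs.

This is the format layer between hand (or synthetic) polygon annotations and
the per-pixel {background, sclera, cornea} label grids the rest of the
pipeline consumes.  The LabelMe dialect supported is the minimal one produced
by the annotation workflow: a top-level ``"shapes"`` list of polygon shapes
labelled ``"cornea"`` or ``"sclera"``, plus ``"imageHeight"``/``"imageWidth"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import shapely
from PIL import Image
from shapely.geometry import Polygon

BACKGROUND, SCLERA, CORNEA = 0, 1, 2
LABEL_NAMES = ("background", "sclera", "cornea")
LABEL_IDS = {"background": BACKGROUND, "sclera": SCLERA, "cornea": CORNEA}
RECOGNIZED_LABELS = ("sclera", "cornea")
# indexed-PNG palette: background black, sclera red-ish, cornea green-ish
PALETTE = [(0, 0, 0), (220, 70, 70), (70, 200, 70)]


class AnnotationParseError(ValueError):
    """Raised for structurally malformed annotation documents."""


class MaskValidityError(ValueError):
    """Raised when a one-hot map is not exactly one-hot at some pixels."""

    def __init__(self, n_invalid: int):
        self.n_invalid = n_invalid
        super().__init__(f"one-hot map invalid at {n_invalid} pixel(s)")


@dataclass(eq=False)
class EyeSegmentation:
    """Per-pixel {background, sclera, cornea} labeling of an eye image."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {self.labels.shape}")
        if self.labels.size and self.labels.max() > CORNEA:
            raise ValueError("labels must be in {0, 1, 2}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def fissure_mask(self) -> np.ndarray:
        """Palpebral fissure = union of visible sclera and cornea."""
        return self.labels > BACKGROUND

    @property
    def sclera_mask(self) -> np.ndarray:
        return self.labels == SCLERA

    @property
    def cornea_mask(self) -> np.ndarray:
        return self.labels == CORNEA

    def counts(self) -> dict:
        return {name: int((self.labels == i).sum()) for i, name in enumerate(LABEL_NAMES)}

    def one_hot(self) -> np.ndarray:
        return encode_one_hot(self)

    def flip(self, axis: str) -> "EyeSegmentation":
        if axis == "horizontal":
            return EyeSegmentation(self.labels[:, ::-1].copy())
        if axis == "vertical":
            return EyeSegmentation(self.labels[::-1, :].copy())
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")

    def equals(self, other: "EyeSegmentation") -> bool:
        return self.shape == other.shape and bool(np.array_equal(self.labels, other.labels))


def encode_one_hot(seg: EyeSegmentation) -> np.ndarray:
    """(H, W) labels -> (H, W, 3) binary map with exactly one 1 per pixel."""
    h, w = seg.shape
    out = np.zeros((h, w, 3), dtype=np.uint8)
    for i in range(3):
        out[..., i] = seg.labels == i
    return out


def decode_one_hot(one_hot: np.ndarray) -> EyeSegmentation:
    """Inverse of :func:`encode_one_hot`; validates one-hot exactness."""
    arr = np.asarray(one_hot)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) map, got shape {arr.shape}")
    sums = arr.astype(np.int64).sum(axis=2)
    n_invalid = int((sums != 1).sum())
    if n_invalid:
        raise MaskValidityError(n_invalid)
    return EyeSegmentation(np.argmax(arr, axis=2).astype(np.uint8))


def save_mask(seg: EyeSegmentation, path) -> None:
    """Write the label grid as an indexed (palette) PNG."""
    img = Image.fromarray(seg.labels, mode="P")
    img.putpalette([c for rgb in PALETTE for c in rgb])
    img.save(path, format="PNG")


def load_mask(path) -> EyeSegmentation:
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected an indexed (single-channel) PNG mask")
    return EyeSegmentation(arr)


@dataclass
class PolygonAnnotation:
    """A single labelled polygon in image coordinates."""

    label: str
    points: np.ndarray  # (N, 2) float, (x, y)
    image_height: int
    image_width: int

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(f"points must be (N, 2), got shape {self.points.shape}")
        if len(self.points) < 3:
            raise ValueError(f"polygon needs >= 3 points, got {len(self.points)}")
        if not np.isfinite(self.points).all():
            raise ValueError("polygon points must be finite")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    def validate(self) -> None:
        """Check simplicity and image-bounds invariants."""
        if not self.polygon.is_valid:
            raise ValueError(f"{self.label}: polygon is not simple")
        x, y = self.points[:, 0], self.points[:, 1]
        if x.min() < 0 or y.min() < 0 or x.max() > self.image_width or y.max() > self.image_height:
            raise ValueError(f"{self.label}: polygon exceeds image bounds")


def read_labelme(source: Union[str, Path, dict]) -> list:
    """Parse a LabelMe JSON document into :class:`PolygonAnnotation` objects.

    Shapes with unrecognized labels or non-polygon shape types are skipped
    with a warning (annotators may trace structures the pipeline does not
    model); structural problems raise :class:`AnnotationParseError` naming
    the offending shape index.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = source
    if not isinstance(doc, dict) or "shapes" not in doc:
        raise AnnotationParseError("document has no 'shapes' list")
    try:
        height = int(doc["imageHeight"])
        width = int(doc["imageWidth"])
    except (KeyError, TypeError, ValueError) as exc:
        raise AnnotationParseError("missing or invalid imageHeight/imageWidth") from exc
    annotations = []
    for i, shape in enumerate(doc["shapes"]):
        if not isinstance(shape, dict) or "label" not in shape or "points" not in shape:
            raise AnnotationParseError(f"shape {i}: missing 'label' or 'points'")
        label = shape["label"]
        if shape.get("shape_type", "polygon") != "polygon":
            warnings.warn(f"shape {i}: unsupported shape_type {shape.get('shape_type')!r}, skipped")
            continue
        if label not in RECOGNIZED_LABELS:
            warnings.warn(f"shape {i}: unrecognized label {label!r}, skipped")
            continue
        try:
            pts = np.asarray(shape["points"], dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
                raise ValueError
        except (TypeError, ValueError) as exc:
            raise AnnotationParseError(f"shape {i}: malformed points") from exc
        annotations.append(PolygonAnnotation(label, pts, height, width))
    return annotations


def write_labelme(annotations: Sequence[PolygonAnnotation], path=None) -> dict:
    """Serialize annotations to the LabelMe dialect; optionally write JSON."""
    if not annotations:
        raise ValueError("cannot write an empty annotation list (image size unknown)")
    h, w = annotations[0].image_height, annotations[0].image_width
    doc = {
        "version": "5.0.1",
        "flags": {},
        "shapes": [
            {
                "label": a.label,
                "points": [[float(x), float(y)] for x, y in a.points],
                "group_id": None,
                "shape_type": "polygon",
                "flags": {},
            }
            for a in annotations
        ],
        "imagePath": "",
        "imageData": None,
        "imageHeight": int(h),
        "imageWidth": int(w),
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    return doc


def polygon_mask(points: np.ndarray, shape: tuple) -> np.ndarray:
    """Rasterize one polygon: pixel included iff its center is inside or on
    the boundary (shapely ``covers``)."""
    h, w = shape
    poly = Polygon(np.asarray(points, dtype=float))
    minx, miny, maxx, maxy = poly.bounds
    c0, c1 = max(0, int(np.floor(minx - 1))), min(w, int(np.ceil(maxx + 1)))
    r0, r1 = max(0, int(np.floor(miny - 1))), min(h, int(np.ceil(maxy + 1)))
    out = np.zeros((h, w), dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return out
    cols = np.arange(c0, c1) + 0.5
    rows = np.arange(r0, r1) + 0.5
    cx, ry = np.meshgrid(cols, rows)
    pts = shapely.points(cx.ravel(), ry.ravel())
    covered = shapely.covers(poly, pts).reshape(ry.shape)
    out[r0:r1, c0:c1] = covered
    return out


def rasterize(annotations: Sequence[PolygonAnnotation], shape: tuple | None = None) -> EyeSegmentation:
    """Rasterize polygon annotations into a label grid.

    Sclera polygons are painted first, cornea polygons on top (the cornea
    sits atop the scleral aperture, so it wins overlaps).  Pixel inclusion is
    by the pixel-center rule.
    """
    if shape is None:
        if not annotations:
            raise ValueError("empty annotation list requires an explicit shape")
        shape = (annotations[0].image_height, annotations[0].image_width)
    for a in annotations:
        if (a.image_height, a.image_width) != tuple(shape):
            raise ValueError(
                f"annotation dimensions {(a.image_height, a.image_width)} != target {tuple(shape)}"
            )
    labels = np.zeros(shape, dtype=np.uint8)
    for name, value in (("sclera", SCLERA), ("cornea", CORNEA)):
        for a in annotations:
            if a.label == name:
                labels[polygon_mask(a.points, shape)] = value
    return EyeSegmentation(labels)
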
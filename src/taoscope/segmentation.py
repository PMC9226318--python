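"""Cornea/sclera segmentation of an eye crop (Module II support).

A classical baseline behind the interface a learned semantic segmenter
would implement: the palpebral fissure is the largest region contrasting
with the border skin tone, and the cornea is the largest sufficiently
circular dark blob inside it; the sclera is the remainder of the fissure.
The output is always a valid one-hot {background, sclera, cornea} grid.
"""

from __future__ import annotations

import warnings
from typing import List, Sequence, Union

import numpy as np
from skimage import filters, measure, morphology
from sklearn.base import BaseEstimator, TransformerMixin

from .annotation import BACKGROUND, CORNEA, SCLERA, EyeSegmentation
from .detection import EyeCrop, _border_skin_estimate, _skin_threshold


class ThresholdEyeSegmenter(BaseEstimator, TransformerMixin):
    """Otsu + morphology baseline segmenter.

    Parameters
    ----------
    circularity_min : float
        A dark component is accepted as cornea only if
        ``4 * pi * area / perimeter**2 >= circularity_min`` — rejects
        eyelash/shadow blobs while tolerating lid-clipped corneas.
    contrast_floor : float
        Below this peak skin contrast the crop is declared fissure-free:
        an all-background segmentation is returned with a warning rather
        than an exception, so batch runs continue.
    """

    def __init__(self, circularity_min: float = 0.6, closing_radius: int = 3,
                 contrast_floor: float = 0.08, border_frac: float = 0.04,
                 min_area: int = 32):
        self.circularity_min = circularity_min
        self.closing_radius = closing_radius
        self.contrast_floor = contrast_floor
        self.border_frac = border_frac
        self.min_area = min_area

    def fit(self, X=None, y=None):
        """No-op: the segmenter is rule-based and stateless."""
        self.is_fitted_ = True
        return self

    def segment(self, crop: Union[EyeCrop, np.ndarray]) -> EyeSegmentation:
        img = crop.image if isinstance(crop, EyeCrop) else np.asarray(crop)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) crop, got shape {img.shape}")
        img = np.clip(img.astype(float), 0.0, 1.0) if img.dtype.kind == "f" else img.astype(float) / 255.0
        h, w = img.shape[:2]
        labels = np.zeros((h, w), dtype=np.uint8)

        skin = _border_skin_estimate(img * 255.0, self.border_frac) / 255.0
        contrast = np.linalg.norm(img - skin, axis=2)
        if contrast.max() < self.contrast_floor:
            warnings.warn("no fissure candidate: crop is flat against its border skin tone")
            return EyeSegmentation(labels)
        bw = contrast > max(_skin_threshold(contrast), self.contrast_floor)
        bw = morphology.opening(bw, morphology.disk(1))
        bw = morphology.closing(bw, morphology.disk(self.closing_radius))
        comp = measure.label(bw, connectivity=1)
        if comp.max() == 0:
            warnings.warn("no fissure candidate above the contrast threshold")
            return EyeSegmentation(labels)
        areas = np.bincount(comp.ravel())[1:]
        if areas.max() < self.min_area:
            warnings.warn("no fissure candidate of sufficient area")
            return EyeSegmentation(labels)
        fissure = comp == (int(np.argmax(areas)) + 1)

        labels[fissure] = SCLERA
        brightness = img.mean(axis=2)
        vals = brightness[fissure]
        cornea = None
        if np.ptp(vals) > 0.05:
            bthr = filters.threshold_otsu(vals)
            dark = fissure & (brightness < bthr)
            dcomp = measure.label(dark, connectivity=1)
            if dcomp.max() > 0:
                dareas = np.bincount(dcomp.ravel())[1:]
                cand = dcomp == (int(np.argmax(dareas)) + 1)
                area = float(cand.sum())
                if area >= self.min_area:
                    perim = measure.perimeter(cand)
                    circularity = 4.0 * np.pi * area / perim**2 if perim > 0 else 0.0
                    if circularity >= self.circularity_min:
                        cornea = cand
        if cornea is not None:
            labels[cornea] = CORNEA
        return EyeSegmentation(labels)

    def transform(self, X: Sequence) -> List[EyeSegmentation]:
        return [self.segment(c) for c in X]


def segment_eye(crop, **params) -> EyeSegmentation:
    """Functional wrapper around :class:`ThresholdEyeSegmenter.segment`."""
    return ThresholdEyeSegmenter(**params).segment(crop)


def segmentation_iou(predicted: EyeSegmentation, truth: EyeSegmentation,
                     category: Union[int, str]) -> float:
    """Intersection-over-union of one category's pixel sets.

    Defined as 1.0 when both sets are empty (nothing to find, nothing
    found).
    """
    if predicted.shape != truth.shape:
        raise ValueError(f"dimension mismatch: {predicted.shape} vs {truth.shape}")
    if isinstance(category, str):
        from .annotation import LABEL_IDS
        category = LABEL_IDS[category]
    a = predicted.labels == category
    b = truth.labels == category
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(a, b).sum()) / union


def pixel_accuracy(predicted: EyeSegmentation, truth: EyeSegmentation) -> float:
    if predicted.shape != truth.shape:
        raise ValueError(f"dimension mismatch: {predicted.shape} vs {truth.shape}")
    return float((predicted.labels == truth.labels).mean())
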
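"""Per-sign scorers (Module III stand-in).

One scorer per clinical sign, all behind a uniform registry contract:
``(crop, segmentation) -> probability in [0, 1]``, deterministic.  The
baselines are handcrafted photographic features passed through a logistic
calibration — the extension point where a trained per-sign classifier
could be plugged in without touching the rest of the pipeline.

Chemosis and corneal ulcer ship as flagged "unsupported-baseline" scorers
returning a 0.5 prior: chemosis is essentially undetectable from frontal
images and corneal ulcer has no renderable phenotype here, so pretending
otherwise would manufacture unearned accuracy.  Flagged scorers are
excluded from mean-metric aggregation by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .annotation import EyeSegmentation
from .detection import EyeCrop
from .synthetic import SIGNS


class UnknownSignError(KeyError):
    def __init__(self, sign, supported):
        self.sign = sign
        super().__init__(f"unknown sign {sign!r}; supported: {sorted(supported)}")


@dataclass
class SignScore:
    sign: str
    probability: float
    features: dict = field(default_factory=dict)
    flagged: bool = False

    def __post_init__(self):
        if not (np.isfinite(self.probability) and 0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability {self.probability} not in [0, 1]")


def binarize(score: Union[SignScore, float], threshold: float = 0.5) -> bool:
    """Positive iff probability >= threshold (inclusive at the boundary)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} not in [0, 1]")
    p = score.probability if isinstance(score, SignScore) else float(score)
    return p >= threshold


# ---------------------------------------------------------------------------
# photographic features (all mirror-symmetric)
# ---------------------------------------------------------------------------

def _crop_arrays(crop) -> np.ndarray:
    img = crop.image if isinstance(crop, EyeCrop) else np.asarray(crop)
    img = img.astype(float)
    if img.max() > 1.5:
        img = img / 255.0
    return img


def _redness(img: np.ndarray, mask: np.ndarray) -> float:
    if not mask.any():
        return 0.0
    r = img[..., 0][mask]
    gb = (img[..., 1][mask] + img[..., 2][mask]) / 2.0
    return float((r - gb).mean())


def _lid_band(seg: EyeSegmentation, width_frac: float = 0.09) -> np.ndarray:
    outside = ~seg.fissure_mask
    if outside.all():
        return np.zeros(seg.shape, dtype=bool)
    edt = ndimage.distance_transform_edt(outside)
    band_width = max(3.0, width_frac * max(seg.shape))
    return outside & (edt <= band_width)


def sclera_redness(crop, seg: EyeSegmentation) -> float:
    """Mean red excess (R - (G+B)/2) over sclera pixels."""
    return _redness(_crop_arrays(crop), seg.sclera_mask)


def lid_redness(crop, seg: EyeSegmentation) -> float:
    """Mean red excess over the eyelid band around the fissure."""
    return _redness(_crop_arrays(crop), _lid_band(seg))


def lid_brightness_variance(crop, seg: EyeSegmentation) -> float:
    """Brightness variance over the lid band (edema texture proxy)."""
    band = _lid_band(seg)
    if not band.any():
        return 0.0
    return float(_crop_arrays(crop).mean(axis=2)[band].var())


def aperture_ratio(crop, seg: EyeSegmentation) -> float:
    """Fissure height / width, corrected for anisotropic crop resizing.

    When the crop records its source box, the pixel extents are mapped back
    to source-image units so the ratio is invariant to the square resize.
    """
    fissure = seg.fissure_mask
    if not fissure.any():
        return 0.0
    ys, xs = np.nonzero(fissure)
    h_px = float(ys.max() - ys.min() + 1)
    w_px = float(xs.max() - xs.min() + 1)
    sy = sx = 1.0
    if isinstance(crop, EyeCrop) and crop.box is not None:
        sh, sw = seg.shape
        sy = crop.box.height / sh
        sx = crop.box.width / sw
    return (h_px * sy) / (w_px * sx) if w_px * sx > 0 else 0.0


FEATURES: Dict[str, Callable] = {
    "sclera_redness": sclera_redness,
    "lid_redness": lid_redness,
    "lid_brightness_variance": lid_brightness_variance,
    "aperture_ratio": aperture_ratio,
}


# ---------------------------------------------------------------------------
# scorers
# ---------------------------------------------------------------------------

class LogisticFeatureScorer(BaseEstimator):
    """Logistic map of a single photographic feature.

    ``coef``/``intercept`` default to the packaged calibration constants;
    :meth:`fit` re-estimates them from labelled (crop, segmentation) pairs
    with an L2-regularized 1-D logistic regression.
    """

    flagged = False

    def __init__(self, sign: str, feature: str, coef: Optional[float] = None,
                 intercept: Optional[float] = None):
        self.sign = sign
        self.feature = feature
        self.coef = coef
        self.intercept = intercept

    def _constants(self) -> Tuple[float, float]:
        if getattr(self, "coef_", None) is not None:
            return self.coef_, self.intercept_
        if self.coef is not None and self.intercept is not None:
            return self.coef, self.intercept
        cal = load_calibration()
        entry = cal.get(self.sign)
        if entry is None:
            raise RuntimeError(f"no calibration constants for sign {self.sign!r}")
        return entry["coef"], entry["intercept"]

    def fit(self, X: Sequence[tuple], y):
        feats = np.array([[FEATURES[self.feature](crop, seg)] for crop, seg in X])
        lr = LogisticRegression(C=1e3).fit(feats, np.asarray(y, dtype=int))
        self.coef_ = float(lr.coef_[0, 0])
        self.intercept_ = float(lr.intercept_[0])
        return self

    def score_one(self, crop, seg: EyeSegmentation, **context) -> SignScore:
        f = FEATURES[self.feature](crop, seg)
        coef, intercept = self._constants()
        p = 1.0 / (1.0 + np.exp(-(coef * f + intercept)))
        return SignScore(self.sign, float(np.clip(p, 0.0, 1.0)), {self.feature: f})

    def predict_proba(self, X: Sequence[tuple]) -> np.ndarray:
        p = np.array([self.score_one(crop, seg).probability for crop, seg in X])
        return np.column_stack([1 - p, p])


class ConstantPriorScorer(BaseEstimator):
    """Flagged stand-in for signs with no functional frontal-image baseline."""

    flagged = True

    def __init__(self, sign: str, probability: float = 0.5):
        self.sign = sign
        self.probability = probability

    def fit(self, X=None, y=None):
        return self

    def score_one(self, crop, seg, **context) -> SignScore:
        return SignScore(self.sign, self.probability, {}, flagged=True)


class MotilityDelegateScorer(BaseEstimator):
    """Eye-movement-disorder score delegated to the rule engine's margin.

    The impairment margin (pixels past the rule boundary) is squashed
    through a logistic with a fixed pixel scale; requires the gaze and eye
    side as scoring context.
    """

    flagged = False

    def __init__(self, sign: str = "eye_movement_disorders", scale: float = 2.0,
                 tolerance: Optional[float] = None):
        self.sign = sign
        self.scale = scale
        self.tolerance = tolerance

    def fit(self, X=None, y=None):
        return self

    def score_one(self, crop, seg: EyeSegmentation, gaze=None, eye_side="right",
                  margin: Optional[float] = None, **context) -> SignScore:
        from .motility import assess_gaze
        if margin is None:
            if gaze is None:
                raise ValueError("eye-movement scoring requires a gaze (or a precomputed margin)")
            verdict = assess_gaze(seg, gaze, eye_side, self.tolerance)
            if verdict.impaired is None:
                return SignScore(self.sign, 0.5, {"indeterminate": 1.0})
            margin = verdict.details["impairment_margin"]
        p = 1.0 / (1.0 + np.exp(-margin / self.scale))
        return SignScore(self.sign, float(np.clip(p, 0.0, 1.0)), {"impairment_margin": margin})


# ---------------------------------------------------------------------------
# registry and calibration
# ---------------------------------------------------------------------------

_SCORER_FEATURES = {
    "eyelid_retraction": "aperture_ratio",
    "eyelid_edema": "lid_brightness_variance",
    "eyelid_congestion": "lid_redness",
    "conjunctival_congestion": "sclera_redness",
}


def build_registry() -> Dict[str, BaseEstimator]:
    """Default scorer registry: one scorer per supported sign."""
    registry: Dict[str, BaseEstimator] = {
        sign: LogisticFeatureScorer(sign, feature)
        for sign, feature in _SCORER_FEATURES.items()
    }
    registry["chemosis"] = ConstantPriorScorer("chemosis")
    registry["corneal_ulcer"] = ConstantPriorScorer("corneal_ulcer")
    registry["eye_movement_disorders"] = MotilityDelegateScorer()
    return registry


def score_sign(crop, seg: EyeSegmentation, sign: str,
               registry: Optional[Mapping[str, BaseEstimator]] = None,
               **context) -> SignScore:
    """Score one sign on one crop through the registry."""
    registry = build_registry() if registry is None else registry
    if sign not in registry:
        raise UnknownSignError(sign, registry.keys())
    return registry[sign].score_one(crop, seg, **context)


_calibration_cache: Optional[dict] = None


def load_calibration() -> dict:
    """Packaged logistic calibration constants (see :func:`fit_calibration`)."""
    global _calibration_cache
    if _calibration_cache is None:
        with resources.files("taoscope.data").joinpath("calibration.json").open() as fh:
            _calibration_cache = json.load(fh)
    return _calibration_cache


def fit_calibration(seed: int = 20220610, n_per_sign: int = 160,
                    image_size: int = 160) -> dict:
    """Fit the default logistic constants on a seeded synthetic set.

    For each feature-based sign, renders ``n_per_sign`` eyes with the sign
    label balanced 50/50 and all other phenotype dimensions sampled as in
    the cohort simulator, then fits the 1-D logistic map.  The result ships
    as package data so default scoring is reproducible without refitting.
    """
    from .synthetic import GAZE_BY_NAME, sample_patient

    out = {}
    primary = GAZE_BY_NAME["primary"]
    for k, (sign, feature) in enumerate(sorted(_SCORER_FEATURES.items())):
        rng = np.random.default_rng([seed, k])
        pairs, labels = [], []
        for i in range(n_per_sign):
            label = i % 2
            prev = {s: 0.5 for s in SIGNS}
            prev[sign] = float(label)
            prev["eye_movement_disorders"] = 0.0
            from .synthetic import render_eye
            sampled, phenotypes = sample_patient(rng, prev, image_size)
            eye = render_eye(phenotypes["right"], primary, image_size,
                             seed=int(rng.integers(2**31)))
            pairs.append((eye.image, eye.segmentation))
            labels.append(label)
        scorer = LogisticFeatureScorer(sign, feature).fit(pairs, labels)
        out[sign] = {"feature": feature, "coef": scorer.coef_,
                     "intercept": scorer.intercept_,
                     "seed": seed, "n": n_per_sign}
    return out
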
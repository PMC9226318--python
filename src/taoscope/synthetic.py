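"""Parametric synthetic eye/face renderer and cohort simulator.

No clinical photographs ship with this package.  Instead, every downstream
module is exercised against a parametric model of what a frontal periocular
photograph contains:

* an almond-shaped palpebral fissure drawn as two parabolic arcs between an
  inner and an outer canthus, with height = ``aperture_ratio`` x width;
* a white sclera filling the fissure, optionally tinted red
  (``redness`` = conjunctival congestion phenotype);
* a dark circular cornea whose center is displaced from the fissure center
  along the gaze direction by ``motility`` x the maximal excursion, where
  the maximal excursion is *defined* as the displacement that makes the
  cornea exactly tangent to the corresponding gaze rule line (the vertical
  line through the gaze-side canthus for lateral gaze, the intercanthal
  line for vertical gaze) — so full motility is tangency by construction;
* a skin-toned surround with an optional reddened lid band
  (``lid_redness`` = eyelid congestion phenotype) and additive Gaussian
  pixel noise.

The cohort simulator samples the seven per-patient sign labels at the
configured prevalences, maps labels to rendering phenotypes, renders the
planned views (anteroposterior face, nine-gaze faces, per-eye lateral
stand-ins), and writes images, indexed-PNG masks, LabelMe JSON and a
manifest (patients.csv + images.csv).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from shapely.geometry import MultiPolygon, Point as ShapelyPoint, Polygon

from .annotation import (
    CORNEA,
    SCLERA,
    EyeSegmentation,
    PolygonAnnotation,
    rasterize,
    save_mask,
    write_labelme,
)
from .geometry import Point2D


class PhenotypeError(ValueError):
    """Raised when an eye phenotype violates its invariants."""


# ---------------------------------------------------------------------------
# gaze directions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GazeDirection:
    """One of the nine cardinal gaze positions.

    Components are in the image frame: ``horizontal`` +1 means the cornea
    moves toward image right, ``vertical`` +1 means superior (toward the top
    of the image, i.e. decreasing row index).
    """

    name: str
    horizontal: int
    vertical: int

    @property
    def is_primary(self) -> bool:
        return self.horizontal == 0 and self.vertical == 0

    @property
    def is_oblique(self) -> bool:
        return self.horizontal != 0 and self.vertical != 0


_GAZE_SPECS = [
    ("superior-right", 1, 1),
    ("superior", 0, 1),
    ("superior-left", -1, 1),
    ("right", 1, 0),
    ("primary", 0, 0),
    ("left", -1, 0),
    ("inferior-right", 1, -1),
    ("inferior", 0, -1),
    ("inferior-left", -1, -1),
]
NINE_GAZES = tuple(GazeDirection(n, h, v) for n, h, v in _GAZE_SPECS)
GAZE_BY_NAME = {g.name: g for g in NINE_GAZES}
_GAZE_BY_COMPONENTS = {(g.horizontal, g.vertical): g for g in NINE_GAZES}
ECCENTRIC_GAZES = tuple(g for g in NINE_GAZES if not g.is_primary)


def gaze(name: str) -> GazeDirection:
    try:
        return GAZE_BY_NAME[name]
    except KeyError:
        raise ValueError(f"unknown gaze {name!r}; valid: {sorted(GAZE_BY_NAME)}") from None


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EyePhenotype:
    """Rendering parameters of one eye.

    ``motility`` maps gaze names to excursion fractions in [0, 1] (1 = full
    excursion = tangent to the rule line); gazes absent from the mapping
    default to 1.  ``aperture_ratio`` is fissure height / width (the
    photographic proxy for eyelid retraction), ``redness`` the scleral
    red-channel bias in [0, 1] (conjunctival congestion), ``lid_redness``
    the same for the eyelid band (eyelid congestion).  ``canthi`` are the
    (left, right) canthus points in eye-tile coordinates.
    """

    canthi: Tuple[Point2D, Point2D]
    corneal_radius: float
    aperture_ratio: float = 0.36
    redness: float = 0.10
    lid_redness: float = 0.05
    motility: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def default(cls, image_size: int = 160, **overrides) -> "EyePhenotype":
        """A realistic frontal-eye default for a square tile of ``image_size``.

        Canthi sit at 8% and 92% of the width on the vertical mid-line
        (aligned to a pixel-center row so the intercanthal chord passes
        through pixel centers); the corneal radius is ~17% of the
        intercanthal width, matching the ~11.5 mm corneal diameter vs
        ~30 mm fissure width of an adult eye.
        """
        w = float(image_size)
        y = round(w / 2.0) - 0.5
        canthi = (Point2D(0.08 * w, y), Point2D(0.92 * w, y))
        width = canthi[1].x - canthi[0].x
        params = dict(canthi=canthi, corneal_radius=0.17 * width)
        params.update(overrides)
        return cls(**params)

    def motility_for(self, g: GazeDirection) -> float:
        return float(self.motility.get(g.name, 1.0))

    def validate(self) -> None:
        a, b = self.canthi
        width = math.hypot(b.x - a.x, b.y - a.y)
        if width <= 0 or b.x <= a.x:
            raise PhenotypeError("canthi must be distinct with left.x < right.x")
        if not 0 < self.aperture_ratio <= 1:
            raise PhenotypeError(f"aperture_ratio {self.aperture_ratio} not in (0, 1]")
        for name, val in (("redness", self.redness), ("lid_redness", self.lid_redness)):
            if not 0 <= val <= 1:
                raise PhenotypeError(f"{name} {val} not in [0, 1]")
        for gname, m in self.motility.items():
            if gname not in GAZE_BY_NAME:
                raise PhenotypeError(f"unknown gaze {gname!r} in motility map")
            if not 0 <= m <= 1:
                raise PhenotypeError(f"motility[{gname!r}] = {m} not in [0, 1]")
        if not 0 < self.corneal_radius < width / 2:
            raise PhenotypeError(
                f"corneal_radius {self.corneal_radius} must be in (0, half fissure width "
                f"{width / 2:.1f})"
            )


# ---------------------------------------------------------------------------
# eye rendering
# ---------------------------------------------------------------------------

SKIN_COLOR = np.array([224.0, 172.0, 148.0])
SCLERA_BASE = 242.0
CORNEA_COLOR = np.array([70.0, 46.0, 38.0])
DEFAULT_NOISE_SIGMA = 5.0 / 255.0


def _fissure_polygon(canthi: Tuple[Point2D, Point2D], aperture_ratio: float, n: int = 64) -> np.ndarray:
    """Almond outline: two parabolic arcs between the canthi."""
    a, b = canthi
    t = np.linspace(0.0, 1.0, n + 1)
    xs = a.x + t * (b.x - a.x)
    ys = a.y + t * (b.y - a.y)
    width = math.hypot(b.x - a.x, b.y - a.y)
    half_h = aperture_ratio * width / 2.0
    bump = half_h * 4.0 * t * (1.0 - t)
    upper = np.column_stack([xs, ys - bump])          # smaller y = toward image top
    lower = np.column_stack([xs, ys + bump])[::-1][1:-1]
    return np.vstack([upper, lower])


def max_excursions(phenotype: EyePhenotype, g: GazeDirection) -> Tuple[float, float]:
    """Per-axis maximal excursions ``(dx_max, dy_max)`` for a gaze.

    ``dx_max`` moves the corneal center from the fissure center until the
    circle is tangent to the vertical line through the gaze-side canthus;
    ``dy_max`` until it is tangent to the intercanthal line.  Axes without a
    gaze component return 0.
    """
    a, b = phenotype.canthi
    r = phenotype.corneal_radius
    mid_x, mid_y = (a.x + b.x) / 2.0, (a.y + b.y) / 2.0
    dx_max = dy_max = 0.0
    if g.horizontal != 0:
        x_gs = b.x if g.horizontal > 0 else a.x
        dx_max = abs(x_gs - mid_x) - r
        if dx_max <= 0:
            raise PhenotypeError("cornea too large for a lateral excursion")
    if g.vertical != 0:
        # vertical displacement whose perpendicular distance to the
        # intercanthal line equals r (the chord may be slightly tilted)
        length = math.hypot(b.x - a.x, b.y - a.y)
        n_y = abs(b.x - a.x) / length
        if n_y <= 0:
            raise PhenotypeError("vertical canthal chord: vertical excursion undefined")
        dy_max = r / n_y
    return dx_max, dy_max


def corneal_center(phenotype: EyePhenotype, g: GazeDirection) -> Point2D:
    """Ground-truth corneal center for a phenotype and gaze."""
    a, b = phenotype.canthi
    m = phenotype.motility_for(g)
    dx_max, dy_max = max_excursions(phenotype, g)
    cx = (a.x + b.x) / 2.0 + g.horizontal * m * dx_max
    cy = (a.y + b.y) / 2.0 - g.vertical * m * dy_max  # y grows downward
    return Point2D(cx, cy)


@dataclass
class RenderedEye:
    image: Optional[np.ndarray]          # (S, S, 3) uint8, None when masks only
    segmentation: EyeSegmentation
    annotations: list
    phenotype: EyePhenotype
    gaze: GazeDirection
    cornea_center: Point2D               # ground-truth circle center


def render_eye(
    phenotype: EyePhenotype,
    g: GazeDirection,
    image_size: int = 160,
    seed: int = 0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    with_image: bool = True,
) -> RenderedEye:
    """Render one eye tile: image, label mask and polygon annotation.

    The sclera annotation polygon is the full fissure outline and the cornea
    polygon is the *visible* cornea (circle clipped by the fissure), matching
    what an annotator can trace on a photograph; rasterization precedence
    (cornea over sclera) then yields the label grid.
    """
    if image_size < 64:
        raise ValueError(f"image_size must be >= 64, got {image_size}")
    phenotype.validate()
    fissure_pts = _fissure_polygon(phenotype.canthi, phenotype.aperture_ratio)
    fissure_poly = Polygon(fissure_pts)
    center = corneal_center(phenotype, g)
    circle = ShapelyPoint(center.x, center.y).buffer(phenotype.corneal_radius, quad_segs=16)
    visible = circle.intersection(fissure_poly)
    if isinstance(visible, MultiPolygon):
        visible = max(visible.geoms, key=lambda p: p.area)
    if visible.is_empty or visible.area < 1.0:
        raise PhenotypeError("cornea not visible inside the fissure")
    shape = (image_size, image_size)
    annotations = [
        PolygonAnnotation("sclera", fissure_pts, image_size, image_size),
        PolygonAnnotation("cornea", np.asarray(visible.exterior.coords)[:-1], image_size, image_size),
    ]
    seg = rasterize(annotations, shape)
    image = _paint_eye(seg, phenotype, seed, noise_sigma) if with_image else None
    return RenderedEye(image, seg, annotations, phenotype, g, center)


def _paint_eye(seg: EyeSegmentation, phenotype: EyePhenotype, seed, noise_sigma: float) -> np.ndarray:
    h, w = seg.shape
    img = np.empty((h, w, 3), dtype=float)
    img[:] = SKIN_COLOR
    band_width = max(3.0, 0.09 * max(h, w))
    outside = ~seg.fissure_mask
    edt = ndimage.distance_transform_edt(outside)
    band = outside & (edt <= band_width)
    img[band] += phenotype.lid_redness * np.array([28.0, -60.0, -60.0])
    s = SCLERA_BASE
    img[seg.sclera_mask] = [s, s - 130.0 * phenotype.redness, s - 130.0 * phenotype.redness]
    img[seg.cornea_mask] = CORNEA_COLOR
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, noise_sigma * 255.0, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# flip augmentation
# ---------------------------------------------------------------------------

def flip_gaze(g: GazeDirection, axis: str) -> GazeDirection:
    """Remap a gaze label under a horizontal or vertical image flip."""
    if axis == "horizontal":
        return _GAZE_BY_COMPONENTS[(-g.horizontal, g.vertical)]
    if axis == "vertical":
        return _GAZE_BY_COMPONENTS[(g.horizontal, -g.vertical)]
    raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def flip_augment(image: np.ndarray, mask, g: GazeDirection, axis: str):
    """Flip an image/mask pair and remap the gaze-position label.

    A horizontal flip swaps the left/right gaze families, a vertical flip
    the superior/inferior families; the primary position is a fixed point of
    both.  Applying the same flip twice restores the original bytes and
    label exactly.
    """
    ax = {"horizontal": 1, "vertical": 0}.get(axis)
    if ax is None:
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    flipped_image = np.flip(np.asarray(image), axis=ax).copy()
    if isinstance(mask, EyeSegmentation):
        flipped_mask = mask.flip(axis)
    else:
        flipped_mask = np.flip(np.asarray(mask), axis=ax).copy()
    return flipped_image, flipped_mask, flip_gaze(g, axis)


# ---------------------------------------------------------------------------
# face rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderedFace:
    image: Optional[np.ndarray]
    boxes: Dict[str, tuple]                    # eye side -> (x0, y0, x1, y1) half-open
    masks: Dict[str, EyeSegmentation]          # eye side -> canvas-sized label grid
    eyes: Dict[str, RenderedEye]
    origins: Dict[str, tuple]                  # eye side -> tile (x, y) origin


def render_face(
    left_phenotype: EyePhenotype,
    right_phenotype: EyePhenotype,
    g: GazeDirection,
    canvas_size: Tuple[int, int] = (320, 640),
    eye_size: int = 160,
    seed: int = 0,
    jitter: int = 6,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    with_image: bool = True,
    max_retries: int = 10,
) -> RenderedFace:
    """Composite two rendered eyes onto a skin-toned face canvas.

    The anatomical right eye sits on the image left (frontal photograph).
    Tiles are placed symmetrically about the vertical midline and jittered;
    ground-truth boxes are the half-open extents of each eye's fissure mask
    in canvas coordinates.
    """
    h, w = canvas_size
    gap = max(8, eye_size // 4)
    if w < 2 * eye_size + gap or h < eye_size:
        raise ValueError(f"canvas {canvas_size} too small for two {eye_size} px eyes")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_right, s_left, s_canvas, s_jitter = ss.spawn(4)
    rng = np.random.default_rng(s_jitter)
    y0 = h // 2 - eye_size // 2
    base = {
        "right": (w // 2 - gap // 2 - eye_size, y0),
        "left": (w // 2 + gap // 2, y0),
    }
    origins = None
    for _ in range(max_retries):
        trial = {}
        for side in ("right", "left"):
            bx, by = base[side]
            jx = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            jy = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            x = int(np.clip(bx + jx, 0, w - eye_size))
            y = int(np.clip(by + jy, 0, h - eye_size))
            trial[side] = (x, y)
        if trial["right"][0] + eye_size <= trial["left"][0]:
            origins = trial
            break
    if origins is None:
        raise RuntimeError(f"eye tiles overlap after {max_retries} jitter retries")

    eyes = {
        "right": render_eye(right_phenotype, g, eye_size, s_right, noise_sigma, with_image),
        "left": render_eye(left_phenotype, g, eye_size, s_left, noise_sigma, with_image),
    }
    image = None
    if with_image:
        image = np.empty((h, w, 3), dtype=float)
        image[:] = SKIN_COLOR
        if noise_sigma > 0:
            image += np.random.default_rng(s_canvas).normal(0.0, noise_sigma * 255.0, image.shape)
        image = np.clip(image, 0, 255).astype(np.uint8)
    boxes, masks = {}, {}
    for side, (x, y) in origins.items():
        eye = eyes[side]
        if with_image:
            image[y : y + eye_size, x : x + eye_size] = eye.image
        canvas_labels = np.zeros((h, w), dtype=np.uint8)
        canvas_labels[y : y + eye_size, x : x + eye_size] = eye.segmentation.labels
        masks[side] = EyeSegmentation(canvas_labels)
        ys, xs = np.nonzero(canvas_labels)
        boxes[side] = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
    return RenderedFace(image, boxes, masks, eyes, origins)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

SIGNS = (
    "eyelid_retraction",
    "eyelid_congestion",
    "eyelid_edema",
    "conjunctival_congestion",
    "chemosis",
    "corneal_ulcer",
    "eye_movement_disorders",
)

# per-sign cohort prevalences (yes / (yes + no) over 1,560 patients)
DEFAULT_PREVALENCES = {
    "eyelid_retraction": 479 / 1560,
    "eyelid_congestion": 236 / 1560,
    "eyelid_edema": 870 / 1560,
    "conjunctival_congestion": 977 / 1560,
    "chemosis": 1084 / 1560,
    "corneal_ulcer": 116 / 1560,
    "eye_movement_disorders": 1209 / 1560,
}

DEFAULT_VIEW_PLAN = {"anteroposterior": 1, "nine_gaze": 9, "lateral": 2}

_AGE_BANDS = ["10-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80-89"]
_AGE_PROBS = np.array([17, 289, 384, 365, 309, 159, 35, 2], dtype=float)
_AGE_PROBS /= _AGE_PROBS.sum()
_MALE_FRACTION = 563 / 1560

# label threshold tying the continuous motility parameter to the binary
# movement-disorder label: impaired iff motility < 0.7 in the tested gaze
MOTILITY_IMPAIRED_THRESHOLD = 0.7


def sample_patient(
    rng: np.random.Generator,
    prevalences: Mapping[str, float],
    image_size: int = 160,
) -> Tuple[Dict[str, int], Dict[str, EyePhenotype]]:
    """Sample one patient's sign labels and the matching eye phenotypes.

    Signs are sampled independently at the given prevalences.  Label-to-
    phenotype mapping: eyelid retraction widens the fissure aperture,
    conjunctival congestion raises scleral redness, eyelid congestion
    reddens the lid band.  A movement-disorder patient gets 1-4 impaired
    (eye, gaze) slots with motility ~ U(0.2, 0.65); every unimpaired gaze is
    rendered at full excursion (motility 1), which is what the gaze rule
    defines as normal duction.
    """
    labels = {s: int(rng.random() < prevalences.get(s, 0.0)) for s in SIGNS}
    phenotypes = {}
    impaired_slots: set = set()
    if labels["eye_movement_disorders"]:
        n_slots = int(rng.integers(1, 5))
        all_slots = [(side, g.name) for side in ("right", "left") for g in ECCENTRIC_GAZES]
        idx = rng.choice(len(all_slots), size=n_slots, replace=False)
        impaired_slots = {all_slots[i] for i in idx}
    for side in ("right", "left"):
        aperture = (
            float(rng.normal(0.50, 0.03))
            if labels["eyelid_retraction"]
            else float(rng.normal(0.36, 0.03))
        )
        aperture = float(np.clip(aperture, 0.25, 0.62))
        redness = (
            float(rng.uniform(0.55, 0.90))
            if labels["conjunctival_congestion"]
            else float(rng.uniform(0.0, 0.20))
        )
        lid_redness = (
            float(rng.uniform(0.50, 0.90))
            if labels["eyelid_congestion"]
            else float(rng.uniform(0.0, 0.15))
        )
        base = EyePhenotype.default(image_size)
        width = base.canthi[1].x - base.canthi[0].x
        radius = float(rng.uniform(0.16, 0.195)) * width
        motility = {
            g.name: float(rng.uniform(0.2, 0.65))
            for g in ECCENTRIC_GAZES
            if (side, g.name) in impaired_slots
        }
        phenotypes[side] = replace(
            base,
            corneal_radius=radius,
            aperture_ratio=aperture,
            redness=redness,
            lid_redness=lid_redness,
            motility=motility,
        )
    return labels, phenotypes


def patient_motility_truth(phenotypes: Mapping[str, EyePhenotype]) -> int:
    """Ground-truth patient movement label implied by the phenotypes."""
    for phen in phenotypes.values():
        for m in phen.motility.values():
            if m < MOTILITY_IMPAIRED_THRESHOLD:
                return 1
    return 0


@dataclass
class CohortManifest:
    """Per-patient sign labels plus per-image view/gaze metadata.

    The manifest CSVs are the single source of truth for labels; image and
    mask files carry none.  Paths in ``images`` are relative to ``root``.
    """

    patients: pd.DataFrame
    images: pd.DataFrame
    root: Optional[Path] = None

    def counts(self, sign: str) -> Tuple[int, int]:
        if sign not in self.patients.columns:
            raise KeyError(f"unknown sign {sign!r}")
        yes = int(self.patients[sign].sum())
        return yes, len(self.patients) - yes

    def prevalence(self, sign: str) -> float:
        yes, no = self.counts(sign)
        return yes / (yes + no)

    def validate(self, view_plan: Optional[Mapping[str, int]] = None) -> None:
        known = set(self.patients["patient_id"])
        unknown = set(self.images["patient_id"]) - known
        if unknown:
            raise ValueError(f"image rows reference unknown patients: {sorted(unknown)[:5]}")
        nine = self.images["view_type"] == "nine_gaze"
        if (self.images.loc[nine, "gaze"] == "").any():
            raise ValueError("nine-gaze rows must carry a gaze label")
        if (self.images.loc[~nine, "gaze"] != "").any():
            raise ValueError("gaze labels are only valid on nine-gaze rows")
        if view_plan:
            per_view = (
                self.images.drop_duplicates("image_path").groupby("view_type").size().to_dict()
            )
            n = len(self.patients)
            for view, count in view_plan.items():
                expected = count * n
                if per_view.get(view, 0) != expected:
                    raise ValueError(
                        f"view {view!r}: {per_view.get(view, 0)} images != plan {expected}"
                    )

    def save(self, root) -> None:
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(root / "patients.csv", index=False)
        self.images.to_csv(root / "images.csv", index=False)
        self.root = root

    @classmethod
    def load(cls, root) -> "CohortManifest":
        root = Path(root)
        patients = pd.read_csv(root / "patients.csv")
        images = pd.read_csv(root / "images.csv", keep_default_na=False)
        return cls(patients, images, root)


def simulate_cohort(
    n_patients: int,
    out_dir,
    prevalences: Optional[Mapping[str, float]] = None,
    view_plan: Optional[Mapping[str, int]] = None,
    seed: int = 0,
    image_size: int = 160,
    canvas_size: Tuple[int, int] = (320, 640),
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    with_images: bool = True,
) -> CohortManifest:
    """Render a full synthetic cohort to disk and return its manifest.

    Anteroposterior and nine-gaze views are frontal two-eye face images;
    lateral views are rendered as single-eye stand-ins (a true 90-degree
    profile is outside the renderer's scope but the manifest rows exist so
    the evaluation harness sees the full view plan).  All randomness flows
    from ``seed`` through per-patient substreams, so the same seed yields a
    byte-identical manifest.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    prevalences = dict(DEFAULT_PREVALENCES if prevalences is None else prevalences)
    for sign, p in prevalences.items():
        if not 0 <= p <= 1:
            raise ValueError(f"prevalence[{sign!r}] = {p} not in [0, 1]")
    view_plan = dict(DEFAULT_VIEW_PLAN if view_plan is None else view_plan)
    if view_plan.get("nine_gaze", 0) not in (0, 9):
        raise ValueError("view_plan['nine_gaze'] must be 0 or 9 (one image per gaze)")
    if view_plan.get("lateral", 0) not in (0, 1, 2):
        raise ValueError("view_plan['lateral'] must be 0, 1 or 2 (per-eye profiles)")

    out_dir = Path(out_dir)
    for sub in ("images", "masks", "annotations"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)

    patient_rows, image_rows = [], []
    streams = np.random.SeedSequence(seed).spawn(n_patients)
    for i, stream in enumerate(streams):
        pid = f"p{i:04d}"
        rng = np.random.default_rng(stream)
        labels, phenotypes = sample_patient(rng, prevalences, image_size)
        sex = "male" if rng.random() < _MALE_FRACTION else "female"
        age_band = _AGE_BANDS[int(rng.choice(len(_AGE_BANDS), p=_AGE_PROBS))]
        patient_rows.append({"patient_id": pid, "sex": sex, "age_band": age_band, **labels})

        view_items = []
        for _ in range(view_plan.get("anteroposterior", 0)):
            view_items.append(("anteroposterior", GAZE_BY_NAME["primary"]))
        if view_plan.get("nine_gaze", 0):
            view_items.extend(("nine_gaze", g) for g in NINE_GAZES)
        face_seeds = stream.spawn(len(view_items) + 2)

        for k, (view, g) in enumerate(view_items):
            stem = f"{pid}_{view}_{g.name}"
            face = render_face(
                phenotypes["left"], phenotypes["right"], g,
                canvas_size=canvas_size, eye_size=image_size,
                seed=face_seeds[k], noise_sigma=noise_sigma, with_image=with_images,
            )
            img_path = f"images/{stem}.png"
            if with_images:
                Image.fromarray(face.image).save(out_dir / img_path)
            for side in ("right", "left"):
                mask_path = f"masks/{stem}_{side}.png"
                ann_path = f"annotations/{stem}_{side}.json"
                save_mask(face.eyes[side].segmentation, out_dir / mask_path)
                write_labelme(face.eyes[side].annotations, out_dir / ann_path)
                x0, y0, x1, y1 = face.boxes[side]
                image_rows.append({
                    "patient_id": pid, "image_path": img_path, "view_type": view,
                    "gaze": g.name if view == "nine_gaze" else "",
                    "eye_side": side, "mask_path": mask_path,
                    "annotation_path": ann_path,
                    "tile_x": face.origins[side][0], "tile_y": face.origins[side][1],
                    "box_x0": x0, "box_y0": y0, "box_x1": x1, "box_y1": y1,
                })

        lateral_sides = ("right", "left")[: view_plan.get("lateral", 0)]
        for j, side in enumerate(lateral_sides):
            stem = f"{pid}_lateral_{side}"
            eye = render_eye(
                phenotypes[side], GAZE_BY_NAME["primary"], image_size,
                seed=face_seeds[len(view_items) + j], noise_sigma=noise_sigma,
                with_image=with_images,
            )
            img_path = f"images/{stem}.png"
            if with_images:
                Image.fromarray(eye.image).save(out_dir / img_path)
            mask_path = f"masks/{stem}.png"
            ann_path = f"annotations/{stem}.json"
            save_mask(eye.segmentation, out_dir / mask_path)
            write_labelme(eye.annotations, out_dir / ann_path)
            ys, xs = np.nonzero(eye.segmentation.labels)
            image_rows.append({
                "patient_id": pid, "image_path": img_path, "view_type": "lateral",
                "gaze": "", "eye_side": side, "mask_path": mask_path,
                "annotation_path": ann_path, "tile_x": 0, "tile_y": 0,
                "box_x0": int(xs.min()), "box_y0": int(ys.min()),
                "box_x1": int(xs.max()) + 1, "box_y1": int(ys.max()) + 1,
            })

    manifest = CohortManifest(pd.DataFrame(patient_rows), pd.DataFrame(image_rows))
    manifest.save(out_dir)
    return manifest


def generate_motility_exams(
    n_patients: int,
    prevalence: float = DEFAULT_PREVALENCES["eye_movement_disorders"],
    seed: int = 0,
    image_size: int = 160,
):
    """Yield (patient_id, movement_label, exams) without touching disk.

    ``exams`` is a list of ``(eye_side, gaze, EyeSegmentation)`` over the
    eight eccentric gazes and both eyes, rendered as ground-truth masks —
    the input contract of the motility module's patient-level diagnosis.
    Used for parameter-recovery experiments at cohort scale.
    """
    prevalences = dict(DEFAULT_PREVALENCES)
    prevalences["eye_movement_disorders"] = prevalence
    streams = np.random.SeedSequence(seed).spawn(n_patients)
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        labels, phenotypes = sample_patient(rng, prevalences, image_size)
        exams = []
        for side in ("right", "left"):
            for g in ECCENTRIC_GAZES:
                eye = render_eye(phenotypes[side], g, image_size, seed=0, with_image=False)
                exams.append((side, g, eye.segmentation))
        yield f"p{i:04d}", labels["eye_movement_disorders"], exams
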
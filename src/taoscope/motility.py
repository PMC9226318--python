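"""Nine-gaze ocular-motility rule engine (Module II).

Turns a per-gaze cornea/sclera segmentation into an eye-movement-disorder
verdict using the photographic gaze rules:

* **Lateral gaze** — construct the vertical line through the gaze-side
  canthus vertex.  The eye is *impaired* iff the corneal circle is
  *separated* from that line (it failed to reach the canthus); tangent or
  intersecting means normal duction.
* **Vertical gaze** — construct the line through the inner and outer
  canthus.  The eye is *impaired* iff the corneal circle *intersects* the
  intercanthal line (it failed to clear it); tangent or separated means
  normal.
* **Oblique gaze** — both component rules are evaluated and the verdicts
  combined by OR (the conservative screening choice; the clinical rules are
  stated only for pure lateral and vertical gaze).

A patient is impaired iff any determinate per-eye, per-gaze verdict is
impaired; verdicts with no visible cornea are indeterminate and excluded
from the OR but counted, so a closed eye can never silently read as normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator

from .annotation import EyeSegmentation
from .geometry import (
    INTERSECTING,
    SEPARATED,
    TANGENT,
    CanthusLandmarks,
    CircleLineRelation,
    CornealCircle,
    DegenerateGeometryError,
    EmptyFissureError,
    LineSegment2D,
    Point2D,
    circle_line_relation,
    corneal_boundary_points,
    default_tolerance,
    extract_canthi,
    fit_circle_center_fixed_radius,
    fit_cornea_from_mask,
    fit_corneal_circle,
)
from .synthetic import GazeDirection

RULE_LATERAL = "lateral"
RULE_VERTICAL = "vertical"
RULE_OBLIQUE = "oblique-combined"

# impaired flag as a pure function of (rule, relation) — total by construction
RULE_TABLE = {
    (RULE_LATERAL, SEPARATED): True,
    (RULE_LATERAL, TANGENT): False,
    (RULE_LATERAL, INTERSECTING): False,
    (RULE_VERTICAL, SEPARATED): False,
    (RULE_VERTICAL, TANGENT): False,
    (RULE_VERTICAL, INTERSECTING): True,
}


@dataclass
class MotilityVerdict:
    """Per-eye, per-gaze rule outcome.

    ``impaired`` is None for indeterminate verdicts (no visible cornea).
    ``details`` carries the component clearances and the impairment margin
    (how many pixels past the decision boundary the verdict sits; positive
    = impaired side).
    """

    eye_side: str
    gaze: GazeDirection
    relation: Optional[CircleLineRelation]
    rule_applied: str
    impaired: Optional[bool]
    details: dict = field(default_factory=dict)


@dataclass
class PatientMotilityReport:
    verdicts: List[MotilityVerdict]
    patient_impaired: bool
    n_indeterminate: int

    @property
    def impairment_margin(self) -> float:
        """Max per-verdict margin; positive iff the patient reads impaired."""
        margins = [v.details["impairment_margin"] for v in self.verdicts
                   if v.impaired is not None]
        return max(margins) if margins else float("-inf")


def _verdict(eye_side, g, relation, rule, details) -> MotilityVerdict:
    return MotilityVerdict(eye_side, g, relation, rule,
                           RULE_TABLE[(rule, relation.relation)], details)


def assess_lateral_gaze(
    circle: CornealCircle,
    canthi: CanthusLandmarks,
    g: GazeDirection,
    tolerance: Optional[float] = None,
) -> MotilityVerdict:
    """Apply the lateral (canthus-vertex) rule.

    The rule line is vertical through the gaze-side canthus: the temporal
    canthus for temporal gaze and the nasal canthus for nasal gaze,
    resolved purely by image-frame direction (the gaze-side canthus is the
    one the cornea travels toward).
    """
    if g.horizontal == 0 or g.vertical != 0:
        raise ValueError(f"lateral rule requires a pure horizontal gaze, got {g.name!r}")
    if tolerance is None:
        tolerance = default_tolerance(circle.radius)
    line = canthi.lateral_line(g.horizontal)
    rel = circle_line_relation(circle, line, tolerance)
    side_name = "temporal" if (
        (g.horizontal > 0) == (canthi.eye_side == "left")
    ) else "nasal"
    details = {
        "lateral_clearance": rel.signed_clearance,
        "gaze_side_canthus": side_name,
        "impairment_margin": rel.signed_clearance - tolerance,
    }
    return _verdict(canthi.eye_side, g, rel, RULE_LATERAL, details)


def assess_vertical_gaze(
    circle: CornealCircle,
    canthi: CanthusLandmarks,
    g: GazeDirection,
    tolerance: Optional[float] = None,
) -> MotilityVerdict:
    """Apply the vertical (intercanthal-line) rule."""
    if g.vertical == 0 or g.horizontal != 0:
        raise ValueError(f"vertical rule requires a pure vertical gaze, got {g.name!r}")
    if tolerance is None:
        tolerance = default_tolerance(circle.radius)
    rel = circle_line_relation(circle, canthi.intercanthal_line(), tolerance)
    details = {
        "vertical_clearance": rel.signed_clearance,
        "impairment_margin": -rel.signed_clearance - tolerance,
    }
    return _verdict(canthi.eye_side, g, rel, RULE_VERTICAL, details)


def _indeterminate(eye_side, g, reason) -> MotilityVerdict:
    rule = RULE_OBLIQUE if (g.horizontal and g.vertical) else (
        RULE_LATERAL if g.horizontal else RULE_VERTICAL)
    return MotilityVerdict(eye_side, g, None, rule, None, {"reason": reason})


def assess_gaze(
    seg: EyeSegmentation,
    g: GazeDirection,
    eye_side: str = "right",
    tolerance: Optional[float] = None,
    radius: Optional[float] = None,
) -> MotilityVerdict:
    """Fit the corneal circle and canthi from a segmentation and apply the
    rule for one eccentric gaze.

    Oblique gazes evaluate both component rules and OR the impairments.
    Missing cornea (or an unusable fissure) yields an indeterminate
    verdict rather than an exception.  When ``radius`` is given (e.g. the
    per-eye estimate pooled across gazes by :func:`diagnose_patient`), the
    circle fit fixes that radius and estimates only the center, which
    stabilizes the extrapolated clearance in extreme lateral gaze where
    the leading corneal edge is hidden under the canthus.
    """
    if g.is_primary:
        raise ValueError("gaze rules apply to the eight eccentric positions only")
    try:
        canthi = extract_canthi(seg, eye_side)
        pts = corneal_boundary_points(seg.labels)
        circle = fit_corneal_circle(pts)
        if radius is not None:
            circle = fit_circle_center_fixed_radius(pts, radius, circle.center)
    except EmptyFissureError as exc:
        return _indeterminate(eye_side, g, str(exc))
    except DegenerateGeometryError as exc:
        return _indeterminate(eye_side, g, str(exc))
    if tolerance is None:
        tolerance = default_tolerance(circle.radius)

    if g.is_oblique:
        lat = assess_lateral_gaze(circle, canthi, GazeDirection("lat", g.horizontal, 0), tolerance)
        ver = assess_vertical_gaze(circle, canthi, GazeDirection("ver", 0, g.vertical), tolerance)
        details = {**lat.details, **ver.details,
                   "impairment_margin": max(lat.details["impairment_margin"],
                                            ver.details["impairment_margin"])}
        impairing = lat if lat.impaired else (ver if ver.impaired else lat)
        v = MotilityVerdict(eye_side, g, impairing.relation, RULE_OBLIQUE,
                            bool(lat.impaired or ver.impaired), details)
    elif g.horizontal != 0:
        v = assess_lateral_gaze(circle, canthi, g, tolerance)
        v = MotilityVerdict(eye_side, g, v.relation, v.rule_applied, v.impaired, v.details)
    else:
        v = assess_vertical_gaze(circle, canthi, g, tolerance)
        v = MotilityVerdict(eye_side, g, v.relation, v.rule_applied, v.impaired, v.details)
    v.details["radius"] = circle.radius
    v.details["tolerance"] = tolerance
    return v


Exam = Tuple[str, GazeDirection, EyeSegmentation]


def _pooled_radius(exams: list) -> dict:
    """Median free-fit corneal radius per eye side (the cornea is rigid:
    one radius per eye across all gazes)."""
    radii: dict = {}
    for side, _, seg in exams:
        try:
            radii.setdefault(side, []).append(fit_cornea_from_mask(seg.labels).radius)
        except DegenerateGeometryError:
            continue
    return {side: float(np.median(r)) for side, r in radii.items() if r}


def diagnose_patient(exams: Iterable[Exam], tolerance: Optional[float] = None) -> PatientMotilityReport:
    """OR the determinate per-gaze verdicts into a patient-level call.

    The corneal radius is pooled per eye (median over that eye's gazes)
    before the per-gaze assessment, so poorly conditioned lateral arcs
    inherit a stable radius.  Raises if no exam yields a determinate
    verdict (a patient whose cornea is never visible cannot be assessed).
    """
    exams = list(exams)
    pooled = _pooled_radius(exams)
    verdicts = [assess_gaze(seg, g, side, tolerance, radius=pooled.get(side))
                for side, g, seg in exams]
    if not verdicts:
        raise ValueError("diagnose_patient needs at least one assessable gaze")
    determinate = [v for v in verdicts if v.impaired is not None]
    if not determinate:
        raise ValueError("all verdicts indeterminate: no visible cornea in any gaze")
    return PatientMotilityReport(
        verdicts=verdicts,
        patient_impaired=any(v.impaired for v in determinate),
        n_indeterminate=len(verdicts) - len(determinate),
    )


class MotilityRuleEngine(BaseEstimator):
    """Estimator facade over the rule engine.

    ``predict`` maps a list of patients (each a list of
    ``(eye_side, gaze, segmentation)`` exams) to binary impaired calls;
    ``decision_function`` returns the continuous impairment margin in
    pixels, usable as a ranking score.
    """

    def __init__(self, tolerance: Optional[float] = None):
        self.tolerance = tolerance

    def fit(self, X=None, y=None):
        """No-op: the engine is rule-based and stateless."""
        self.is_fitted_ = True
        return self

    def diagnose(self, exams: Iterable[Exam]) -> PatientMotilityReport:
        return diagnose_patient(exams, self.tolerance)

    def predict(self, X: Sequence[Iterable[Exam]]) -> np.ndarray:
        return np.array([self.diagnose(exams).patient_impaired for exams in X], dtype=bool)

    def decision_function(self, X: Sequence[Iterable[Exam]]) -> np.ndarray:
        return np.array([self.diagnose(exams).impairment_margin for exams in X], dtype=float)


# ---------------------------------------------------------------------------
# brute-force pixel oracle
# ---------------------------------------------------------------------------

def _pixel_relation(cornea_mask: np.ndarray, line: LineSegment2D, tolerance: float) -> CircleLineRelation:
    """Relation of a rasterized cornea region to a line by pixel-side counting.

    Signed distances of all cornea pixel centers to the line are oriented
    so the cornea centroid is on the positive side; the minimum plays the
    role of the analytic signed clearance.  Half a pixel is subtracted
    because a pixel's cell extends ~0.5 px beyond its center toward the
    line — without the inset correction the pixel estimate of a region's
    clearance is systematically half a pixel too large.
    """
    ys, xs = np.nonzero(cornea_mask)
    if len(xs) == 0:
        raise EmptyFissureError("no cornea pixels")
    px, py = xs + 0.5, ys + 0.5
    dx, dy = line.b.x - line.a.x, line.b.y - line.a.y
    norm = np.hypot(dx, dy)
    s = (dx * (py - line.a.y) - dy * (px - line.a.x)) / norm
    if s.mean() < 0:
        s = -s
    return CircleLineRelation.from_clearance(float(s.min()) - 0.5, tolerance)


def pixel_oracle_verdict(
    seg: EyeSegmentation,
    g: GazeDirection,
    eye_side: str = "right",
    tolerance: Optional[float] = None,
    cornea_mask: Optional[np.ndarray] = None,
) -> MotilityVerdict:
    """Brute-force counterpart of :func:`assess_gaze`.

    Uses no circle fit: the clearance is measured directly by counting
    cornea pixels on either side of the rule lines.  By default the
    segmentation's (lid-clipped) cornea pixels are used; pass
    ``cornea_mask`` to count a different rasterized region — e.g. a
    synthetic generator's unclipped corneal disk, which is the fair
    independent reference when the leading corneal edge hides under a lid
    (in extreme adducted/elevated gaze the visible pixels cannot reach the
    canthus even though the cornea does).  The default tolerance is
    derived from the equivalent-area radius of the counted region.
    """
    if g.is_primary:
        raise ValueError("gaze rules apply to the eight eccentric positions only")
    cornea = seg.cornea_mask if cornea_mask is None else np.asarray(cornea_mask) > 0
    if not cornea.any():
        return _indeterminate(eye_side, g, "no cornea pixels")
    try:
        canthi = extract_canthi(seg, eye_side)
    except DegenerateGeometryError as exc:
        return _indeterminate(eye_side, g, str(exc))
    if tolerance is None:
        tolerance = default_tolerance(float(np.sqrt(cornea.sum() / np.pi)))

    relations = {}
    if g.horizontal != 0:
        relations[RULE_LATERAL] = _pixel_relation(cornea, canthi.lateral_line(g.horizontal), tolerance)
    if g.vertical != 0:
        relations[RULE_VERTICAL] = _pixel_relation(cornea, canthi.intercanthal_line(), tolerance)
    flags = {rule: RULE_TABLE[(rule, rel.relation)] for rule, rel in relations.items()}
    impaired = any(flags.values())
    rule = RULE_OBLIQUE if len(relations) == 2 else next(iter(relations))
    shown = next((relations[r] for r, f in flags.items() if f), next(iter(relations.values())))
    return MotilityVerdict(eye_side, g, shown, rule, impaired,
                           {"pixel_clearances": {r: rel.signed_clearance for r, rel in relations.items()}})
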
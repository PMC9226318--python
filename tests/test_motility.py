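"""Nine-gaze motility rule engine: rule tables, dispatch, aggregation."""

from dataclasses import replace

import numpy as np
import pytest

from taoscope.annotation import EyeSegmentation
from taoscope.geometry import CornealCircle, Point2D, extract_canthi
from taoscope.motility import (
    RULE_TABLE,
    MotilityRuleEngine,
    assess_gaze,
    assess_lateral_gaze,
    assess_vertical_gaze,
    diagnose_patient,
    pixel_oracle_verdict,
)
from taoscope.synthetic import (
    ECCENTRIC_GAZES,
    EyePhenotype,
    flip_augment,
    flip_gaze,
    gaze,
    render_eye,
)


@pytest.fixture(scope="module")
def canthi(default_eye):
    return extract_canthi(default_eye.segmentation, "right")


class TestRuleTables:
    def test_total_over_all_relation_rule_pairs(self):
        relations = ("separated", "tangent", "intersecting")
        assert set(RULE_TABLE) == {(r, rel) for r in ("lateral", "vertical")
                                   for rel in relations}
        # lateral: impaired iff separated; vertical: impaired iff intersecting
        assert RULE_TABLE[("lateral", "separated")] is True
        assert RULE_TABLE[("lateral", "tangent")] is False
        assert RULE_TABLE[("lateral", "intersecting")] is False
        assert RULE_TABLE[("vertical", "separated")] is False
        assert RULE_TABLE[("vertical", "tangent")] is False
        assert RULE_TABLE[("vertical", "intersecting")] is True


class TestLateralRule:
    def test_far_from_canthus_line_is_impaired(self, canthi):
        r = 10.0
        circle = CornealCircle(Point2D(canthi.right.x - 6 * r, canthi.right.y), r)
        v = assess_lateral_gaze(circle, canthi, gaze("right"), tolerance=1.0)
        assert v.relation.relation == "separated"
        assert v.impaired is True

    def test_tangent_to_canthus_line_is_normal(self, canthi):
        x_line = canthi.right.x + 1  # outer edge of the canthus pixel
        circle = CornealCircle(Point2D(x_line - 12.0, canthi.right.y), 12.0)
        v = assess_lateral_gaze(circle, canthi, gaze("right"), tolerance=1.0)
        assert v.relation.relation == "tangent"
        assert v.impaired is False

    def test_crossing_the_line_is_normal(self, canthi):
        x_line = canthi.right.x + 1
        circle = CornealCircle(Point2D(x_line - 10.0, canthi.right.y), 12.0)
        v = assess_lateral_gaze(circle, canthi, gaze("right"), tolerance=1.0)
        assert v.relation.relation == "intersecting"
        assert v.impaired is False

    def test_requires_pure_horizontal_gaze(self, canthi):
        circle = CornealCircle(Point2D(50, 50), 10)
        with pytest.raises(ValueError):
            assess_lateral_gaze(circle, canthi, gaze("superior"), 1.0)

    def test_increasing_tolerance_never_creates_impairment(self, canthi):
        circle = CornealCircle(Point2D(canthi.right.x - 30.0, canthi.right.y), 20.0)
        flags = [assess_lateral_gaze(circle, canthi, gaze("right"), t).impaired
                 for t in (0.5, 2.0, 8.0, 20.0)]
        for a, b in zip(flags, flags[1:]):
            assert not (a is False and b is True)


class TestVerticalRule:
    def test_clear_of_intercanthal_line_is_normal(self, canthi):
        circle = CornealCircle(Point2D(80, canthi.left.y - 40.0), 12.0)
        v = assess_vertical_gaze(circle, canthi, gaze("superior"), tolerance=1.0)
        assert v.relation.relation == "separated"
        assert v.impaired is False

    def test_straddling_the_line_is_impaired(self, canthi):
        circle = CornealCircle(Point2D(80, canthi.left.y + 0.5), 12.0)
        v = assess_vertical_gaze(circle, canthi, gaze("superior"), tolerance=1.0)
        assert v.relation.relation == "intersecting"
        assert v.impaired is True

    def test_tangent_within_tolerance_is_normal(self, canthi):
        circle = CornealCircle(Point2D(80, canthi.left.y + 0.5 - 12.3), 12.0)
        v = assess_vertical_gaze(circle, canthi, gaze("inferior"), tolerance=1.0)
        assert v.relation.relation == "tangent"
        assert v.impaired is False


class TestAssessGaze:
    def test_full_motility_lateral_is_normal(self, default_phenotype):
        p = replace(default_phenotype, motility={"right": 1.0})
        eye = render_eye(p, gaze("right"), 160, seed=0, with_image=False)
        assert assess_gaze(eye.segmentation, gaze("right"), "right").impaired is False

    def test_low_motility_upgaze_is_impaired(self, default_phenotype):
        p = replace(default_phenotype, motility={"superior": 0.2})
        eye = render_eye(p, gaze("superior"), 160, seed=0, with_image=False)
        assert assess_gaze(eye.segmentation, gaze("superior"), "right").impaired is True

    def test_low_motility_oblique_combines_rules(self, default_phenotype):
        g = gaze("superior-left")
        p = replace(default_phenotype, motility={g.name: 0.2})
        eye = render_eye(p, g, 160, seed=0, with_image=False)
        v = assess_gaze(eye.segmentation, g, "right")
        assert v.rule_applied == "oblique-combined"
        assert v.impaired is True
        # both component clearances recorded
        assert "lateral_clearance" in v.details and "vertical_clearance" in v.details

    def test_primary_gaze_rejected(self, default_eye):
        with pytest.raises(ValueError):
            assess_gaze(default_eye.segmentation, gaze("primary"), "right")

    def test_missing_cornea_is_indeterminate(self, default_eye):
        labels = default_eye.segmentation.labels.copy()
        labels[labels == 2] = 1  # cornea fully hidden
        v = assess_gaze(EyeSegmentation(labels), gaze("left"), "right")
        assert v.impaired is None and v.relation is None

    def test_horizontal_mirror_equivariance(self, default_phenotype):
        """Flipping the mask and remapping the gaze label preserves the
        impaired flag (for the mirrored eye side)."""
        for name, m in (("left", 1.0), ("left", 0.4), ("superior-right", 0.5)):
            g = gaze(name)
            p = replace(default_phenotype, motility={name: m})
            eye = render_eye(p, g, 160, seed=1, with_image=False)
            v = assess_gaze(eye.segmentation, g, "right")
            _, f_seg, f_g = flip_augment(np.zeros((2, 2, 3)), eye.segmentation, g,
                                         "horizontal")
            v_f = assess_gaze(f_seg, f_g, "left")
            assert v_f.impaired == v.impaired


class TestDiagnosePatient:
    def _exams(self, phenotype, motility):
        p = replace(phenotype, motility=motility)
        return [(side, g, render_eye(p, g, 160, seed=0, with_image=False).segmentation)
                for side in ("right", "left") for g in ECCENTRIC_GAZES]

    def test_all_normal_verdicts(self, default_phenotype):
        report = diagnose_patient(self._exams(default_phenotype, {}))
        assert report.patient_impaired is False
        assert len(report.verdicts) == 16
        assert report.n_indeterminate == 0

    def test_single_impairment_flags_patient(self, default_phenotype):
        report = diagnose_patient(self._exams(default_phenotype, {"left": 0.3}))
        assert report.patient_impaired is True

    def test_indeterminate_counted_not_silently_normal(self, default_phenotype):
        exams = self._exams(default_phenotype, {})
        side, g, seg = exams[0]
        labels = seg.labels.copy()
        labels[labels == 2] = 1
        exams[0] = (side, g, EyeSegmentation(labels))
        report = diagnose_patient(exams)
        assert report.n_indeterminate == 1
        blank = EyeSegmentation(np.zeros((64, 64), np.uint8))
        with pytest.raises(ValueError):
            diagnose_patient([("right", gaze("left"), blank)])

    def test_engine_predict_matches_diagnose(self, default_phenotype):
        engine = MotilityRuleEngine().fit()
        patients = [self._exams(default_phenotype, {}),
                    self._exams(default_phenotype, {"superior": 0.25})]
        pred = engine.predict(patients)
        assert pred.tolist() == [False, True]
        margins = engine.decision_function(patients)
        assert margins[0] < 0 < margins[1]


class TestPixelOracle:
    @pytest.mark.parametrize("name,m,expected", [
        ("left", 0.3, True),
        ("superior", 0.3, True),
        ("superior", 1.0, False),
    ])
    def test_oracle_matches_engine_away_from_boundary(self, default_phenotype,
                                                      name, m, expected):
        g = gaze(name)
        p = replace(default_phenotype, motility={name: m})
        eye = render_eye(p, g, 160, seed=0, with_image=False)
        v = assess_gaze(eye.segmentation, g, "right")
        o = pixel_oracle_verdict(eye.segmentation, g, "right",
                                 tolerance=v.details["tolerance"])
        assert v.impaired is expected
        assert o.impaired is expected
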
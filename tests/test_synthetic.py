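"""Synthetic renderer and cohort simulator: geometric construction,
label-phenotype coupling, manifests and flip augmentation."""

from dataclasses import replace

import numpy as np
import pytest

from taoscope.annotation import EyeSegmentation
from taoscope.geometry import default_tolerance, fit_cornea_from_mask
from taoscope.motility import assess_gaze
from taoscope.synthetic import (
    DEFAULT_VIEW_PLAN,
    ECCENTRIC_GAZES,
    NINE_GAZES,
    CohortManifest,
    EyePhenotype,
    PhenotypeError,
    corneal_center,
    flip_augment,
    flip_gaze,
    gaze,
    max_excursions,
    render_eye,
    render_face,
    sample_patient,
    simulate_cohort,
)


class TestGazeDirections:
    def test_exactly_nine_positions(self):
        assert len(NINE_GAZES) == 9
        assert len({(g.horizontal, g.vertical) for g in NINE_GAZES}) == 9
        assert gaze("primary").is_primary

    def test_unknown_gaze_rejected(self):
        with pytest.raises(ValueError, match="unknown gaze"):
            gaze("up-and-left")


class TestRenderEye:
    def test_mask_partitions_every_pixel(self, default_eye):
        oh = default_eye.segmentation.one_hot()
        assert (oh.sum(axis=2) == 1).all()

    def test_full_excursion_is_tangent_to_lateral_line(self, default_phenotype):
        """motility 1.0 toward a lateral gaze puts the corneal circle
        tangent to the vertical line through the gaze-side canthus."""
        p = replace(default_phenotype, motility={"left": 1.0})
        center = corneal_center(p, gaze("left"))
        x_line = p.canthi[0].x
        clearance = abs(center.x - x_line) - p.corneal_radius
        assert abs(clearance) <= 1e-9

    def test_full_excursion_clears_intercanthal_line(self, default_phenotype):
        p = replace(default_phenotype, motility={"superior": 1.0})
        center = corneal_center(p, gaze("superior"))
        clearance = abs(center.y - p.canthi[0].y) - p.corneal_radius
        assert clearance >= -default_tolerance(p.corneal_radius)

    def test_low_motility_upgaze_intersects(self, default_phenotype):
        """motility 0.3 superior: analytic clearance (m-1)*r is deeply
        negative, and the fitted circle on the rendered mask agrees."""
        p = replace(default_phenotype, motility={"superior": 0.3})
        g = gaze("superior")
        _, dy_max = max_excursions(p, g)
        predicted = 0.3 * dy_max - p.corneal_radius
        assert predicted < -default_tolerance(p.corneal_radius)
        eye = render_eye(p, g, 160, seed=0, with_image=False)
        v = assess_gaze(eye.segmentation, g, "right")
        assert v.relation.relation == "intersecting"
        assert v.relation.signed_clearance == pytest.approx(predicted, abs=1.0)

    def test_radius_recovery_within_two_percent(self):
        """Best-fit circle on the rasterized cornea recovers the generator
        radius within 2% across corneal sizes."""
        for frac in (0.10, 0.14, 0.17, 0.195):
            base = EyePhenotype.default(224)
            width = base.canthi[1].x - base.canthi[0].x
            p = replace(base, corneal_radius=frac * width)
            eye = render_eye(p, gaze("primary"), 224, seed=0, with_image=False)
            fit = fit_cornea_from_mask(eye.segmentation.labels)
            assert fit.radius == pytest.approx(p.corneal_radius, rel=0.02)

    def test_invalid_phenotype_rejected(self, default_phenotype):
        with pytest.raises(PhenotypeError):
            replace(default_phenotype, redness=1.5).validate()
        with pytest.raises(PhenotypeError):
            replace(default_phenotype, corneal_radius=500.0).validate()
        with pytest.raises(PhenotypeError):
            replace(default_phenotype, motility={"left": -0.1}).validate()

    def test_annotation_matches_mask(self, default_eye):
        from taoscope.annotation import rasterize

        again = rasterize(default_eye.annotations, default_eye.segmentation.shape)
        assert again.equals(default_eye.segmentation)


class TestRenderFace:
    def test_boxes_contain_their_fissures(self, default_phenotype):
        face = render_face(default_phenotype, default_phenotype, gaze("primary"), seed=4)
        for side in ("right", "left"):
            x0, y0, x1, y1 = face.boxes[side]
            ys, xs = np.nonzero(face.masks[side].labels)
            assert xs.min() >= x0 and xs.max() < x1
            assert ys.min() >= y0 and ys.max() < y1
        # the two eye regions never overlap
        r, l = face.boxes["right"], face.boxes["left"]
        assert r[2] <= l[0]

    def test_zero_jitter_boxes_mirror_about_midline(self, default_phenotype):
        face = render_face(default_phenotype, default_phenotype, gaze("primary"),
                           seed=0, jitter=0)
        w = face.image.shape[1]
        r, l = face.boxes["right"], face.boxes["left"]
        assert abs(l[0] - (w - r[2])) <= 1
        assert abs(l[2] - (w - r[0])) <= 1

    @pytest.mark.parametrize("seed", range(10))
    def test_boxes_equal_mask_extents_exactly(self, default_phenotype, seed):
        face = render_face(default_phenotype, default_phenotype, gaze("left"),
                           seed=seed, with_image=False)
        for side in ("right", "left"):
            ys, xs = np.nonzero(face.masks[side].labels)
            assert face.boxes[side] == (xs.min(), ys.min(), xs.max() + 1, ys.max() + 1)


class TestFlipAugment:
    @pytest.mark.parametrize("name,axis,expected", [
        ("left", "horizontal", "right"),
        ("superior-left", "horizontal", "superior-right"),
        ("primary", "vertical", "primary"),
        ("superior", "vertical", "inferior"),
        ("inferior-right", "vertical", "superior-right"),
    ])
    def test_gaze_label_remapping(self, name, axis, expected):
        assert flip_gaze(gaze(name), axis).name == expected

    def test_double_flip_is_identity(self, default_eye):
        img, seg, g = default_eye.image, default_eye.segmentation, gaze("left")
        f_img, f_seg, f_g = flip_augment(img, seg, g, "horizontal")
        b_img, b_seg, b_g = flip_augment(f_img, f_seg, f_g, "horizontal")
        assert np.array_equal(b_img, img)
        assert b_seg.equals(seg)
        assert b_g == g

    def test_flip_moves_pixels(self, default_eye):
        f_img, _, _ = flip_augment(default_eye.image, default_eye.segmentation,
                                   gaze("left"), "horizontal")
        assert np.array_equal(f_img, default_eye.image[:, ::-1])


class TestSimulateCohort:
    def test_manifest_structure_and_determinism(self, tmp_path):
        plan = dict(DEFAULT_VIEW_PLAN)
        m1 = simulate_cohort(4, tmp_path / "a", seed=5, view_plan=plan)
        m1.validate(plan)
        per_patient = m1.images.drop_duplicates("image_path").groupby("patient_id").size()
        assert (per_patient == sum(plan.values())).all()
        simulate_cohort(4, tmp_path / "b", seed=5, view_plan=plan)
        assert (tmp_path / "a" / "patients.csv").read_bytes() == \
               (tmp_path / "b" / "patients.csv").read_bytes()
        assert (tmp_path / "a" / "images.csv").read_bytes() == \
               (tmp_path / "b" / "images.csv").read_bytes()

    def test_zero_prevalence_boundary(self, tmp_path):
        prev = {s: 0.0 for s in ("eyelid_retraction", "eyelid_congestion", "eyelid_edema",
                                 "conjunctival_congestion", "chemosis", "corneal_ulcer",
                                 "eye_movement_disorders")}
        m = simulate_cohort(3, tmp_path / "c", prevalences=prev, seed=1,
                            view_plan={"anteroposterior": 1, "nine_gaze": 0, "lateral": 0})
        for sign in prev:
            assert m.counts(sign) == (0, 3)

    def test_manifest_csv_roundtrip(self, tmp_path):
        m = simulate_cohort(3, tmp_path / "d", seed=2,
                            view_plan={"anteroposterior": 1, "nine_gaze": 0, "lateral": 2})
        loaded = CohortManifest.load(tmp_path / "d")
        assert loaded.patients.equals(m.patients)
        assert len(loaded.images) == len(m.images)
        loaded.validate()

    def test_movement_labels_map_to_motility(self):
        rng = np.random.default_rng(9)
        prev = {"eye_movement_disorders": 1.0}
        for _ in range(5):
            labels, phen = sample_patient(rng, prev)
            ms = [m for p in phen.values() for m in p.motility.values()]
            assert labels["eye_movement_disorders"] == 1
            assert ms and all(m < 0.7 for m in ms)
        prev = {"eye_movement_disorders": 0.0}
        labels, phen = sample_patient(rng, prev)
        assert all(not p.motility for p in phen.values())
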
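import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon, box

from autowbrt.aperture import aperture_from_mask, polygon_to_mask
from autowbrt.field_builder import (
    FieldRequest,
    VertebralLandmarks,
    build_scalp_sparing_field,
    build_traditional_field,
    caudal_extent_v,
    compute_vertebral_landmarks,
    mirror_for_opposed_beam,
    set_inferior_border,
)
from autowbrt.projection import ImagePlaneGrid, project_contour_bev, project_points
from autowbrt.voxels import contour_to_mask


class TestLandmarks:
    def test_centroid_oracle_on_analytic_vertebrae(self, case, landmarks):
        # [DERIVED] C1-C3 are z-cylinders at (x, y) = (0, -12) with known
        # centre heights; voxelized centroids must match within a voxel.
        spec = case.spec
        for name in ("C1", "C2", "C3"):
            cx, cy, cz = landmarks.centroids_mm[name]
            assert abs(cx - 0.0) < 2.6
            assert abs(cy + 12.0) < 2.6
            assert abs(cz - spec.vertebra_center_z(name)) < 2.6

    def test_caudal_extent_is_centroid_midpoint(self, landmarks):
        c = landmarks.centroids_mm
        assert np.isclose(landmarks.caudal_extent_mm["C1"],
                          (c["C1"][2] + c["C2"][2]) / 2)
        assert np.isclose(landmarks.caudal_extent_mm["C2"],
                          (c["C2"][2] + c["C3"][2]) / 2)

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="decrease"):
            VertebralLandmarks(
                centroids_mm={"C1": (0, 0, -100), "C2": (0, 0, -90)},
                caudal_extent_mm={},
            )

    def test_missing_structures_raise(self, case):
        from autowbrt.core import StructureSet

        ss = StructureSet(structures={"C1": case.structures["C1"]})
        with pytest.raises(KeyError, match="C2"):
            compute_vertebral_landmarks(ss)


class TestInferiorBorder:
    GRID = ImagePlaneGrid(pixel_spacing_mm=2.0, width=60, height=80)
    BODY = box(-40, -70, 40, 70)

    def _ap(self, v_lo):
        return aperture_from_mask(polygon_to_mask(box(-30, v_lo, 30, 60), self.GRID))

    def test_crop_up_and_extend_down(self):
        ap = self._ap(-20.0)
        down = set_inferior_border(ap, -50.0, self.BODY)
        assert abs(down.inferior_border_v() + 50.0) <= 1.0
        up = set_inferior_border(ap, 10.0, self.BODY)
        assert abs(up.inferior_border_v() - 10.0) <= 1.0

    def test_extension_clipped_to_body(self):
        ap = self._ap(-20.0)
        narrow_body = Polygon([(-10, -70), (10, -70), (40, 0), (-40, 0),
                               (-40, 70), (40, 70)]).convex_hull
        out = set_inferior_border(ap, -60.0, narrow_body)
        u = self.GRID.u_coords()
        bottom = out.mask.pixels[np.where(out.mask.pixels.any(axis=1))[0][-1]]
        # body half-width at the bottom open row (v = -59):
        # 10 + 30 * (70 - 59) / 70 = 14.71 mm
        assert u[bottom].min() >= -14.71 and u[bottom].max() <= 14.71

    def test_below_body_rejected(self):
        with pytest.raises(ValueError, match="below"):
            set_inferior_border(self._ap(-20.0), -80.0, self.BODY)


class TestBuildFields:
    def test_traditional_field_snaps_border_and_flashes(
        self, case, beam_left, body_left, landmarks, reference_left
    ):
        req = FieldRequest(extent="C1")
        fld = build_traditional_field(
            reference_left.mask, body_left, landmarks, req, beam_left,
            "left-lateral",
        )
        v_target = caudal_extent_v(landmarks, "C1", beam_left)
        assert abs(fld.inferior_border_v() - v_target) <= 1.01
        assert fld.flash_applied and fld.flash_mm == 10.0
        # flash: the cranial-most open pixel lies ~10 mm above the body
        v_open = fld.grid.v_coords()[fld.mask.pixels.any(axis=1)]
        assert abs(v_open.max() - (body_left.bounds[3] + 10.0)) <= 1.01

    def test_scalp_sparing_is_subset_and_covers_brain(
        self, case, beam_left, body_left, landmarks, reference_left
    ):
        req_t = FieldRequest(extent="C1")
        trad = build_traditional_field(
            reference_left.mask, body_left, landmarks, req_t, beam_left,
            "left-lateral",
        )
        req_s = FieldRequest(technique="scalp_sparing", extent="C1")
        sparing = build_scalp_sparing_field(
            trad, case.structures["brain"], beam_left, landmarks, req_s
        )
        assert not (sparing.mask.pixels & ~trad.mask.pixels).any()
        assert sparing.mask.pixels.sum() < trad.mask.pixels.sum()
        # brain projection itself stays covered
        brain = project_contour_bev(case.structures["brain"], beam_left)
        bpx = polygon_to_mask(brain, case.bev_grid).pixels
        covered = (sparing.mask.pixels & bpx).sum() / bpx.sum()
        assert covered > 0.99

    def test_extent_mismatch_rejected(self, case, beam_left, body_left,
                                      landmarks, reference_left):
        trad = build_traditional_field(
            reference_left.mask, body_left, landmarks, FieldRequest(extent="C1"),
            beam_left, "left-lateral",
        )
        with pytest.raises(ValueError, match="extent"):
            build_scalp_sparing_field(
                trad, case.structures["brain"], beam_left, landmarks,
                FieldRequest(technique="scalp_sparing", extent="C2"),
            )


class TestMirror:
    def test_mirror_is_involution_and_flips_moments(self, reference_left):
        # [DERIVED] polygon-moment oracle: reflection about u = 0 negates the
        # area centroid's u and preserves area.
        m = mirror_for_opposed_beam(reference_left)
        mm = mirror_for_opposed_beam(m)
        assert (mm.mask.pixels == reference_left.mask.pixels).all()
        assert m.beam_side == "right-lateral"
        a0 = reference_left.polygon
        a1 = m.polygon
        assert abs(a0.area - a1.area) / a0.area < 0.01
        assert abs(a0.centroid.x + a1.centroid.x) < 0.6
        assert abs(a0.centroid.y - a1.centroid.y) < 0.6
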
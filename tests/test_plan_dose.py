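import numpy as np
import pytest

from autowbrt.aperture import aperture_from_mask, polygon_to_mask
from autowbrt.core import CTVolume
from autowbrt.field_builder import FieldRequest
from autowbrt.plan_dose import (
    DoseGrid,
    build_plan,
    compute_toy_dose,
    dvh_metric,
    dvh_report,
)
from autowbrt import pipeline
from autowbrt.projection import ImagePlaneGrid
from shapely.geometry import box


@pytest.fixture(scope="module")
def fields(case, tiny_model):
    req = FieldRequest(extent=case.clinical_extent)
    return pipeline.build_fields_for_case(case, tiny_model, req)


@pytest.fixture(scope="module")
def plan(case, fields):
    return build_plan(case, fields)


class TestBuildPlan:
    def test_two_equal_weight_lateral_beams(self, plan):
        gantries = sorted(b.gantry_deg for b in plan.beams)
        assert gantries == [90.0, 270.0]
        assert all(b.weight == 0.5 for b in plan.beams)
        assert plan.prescription_gy == 30.0 and plan.n_fractions == 10

    def test_mlc_fitted_per_beam(self, plan):
        for b in plan.beams:
            assert b.leaf_positions_mm is not None
            assert b.leaf_positions_mm.shape == (b.mlc.n_pairs, 2)
            x1, x2, y1, y2 = b.jaws_mm
            assert x1 < x2 and y1 < y2

    def test_requires_both_sides(self, case, fields):
        with pytest.raises(ValueError, match="side"):
            build_plan(case, {"left-lateral": fields["left-lateral"]})
        with pytest.raises(ValueError, match="positive"):
            build_plan(case, fields, prescription_gy=0)


class TestToyDose:
    def test_normalized_to_100_at_isocenter(self, case, plan):
        dose = compute_toy_dose(plan, case.ct)
        idx = tuple(int(round(i))
                    for i in case.ct.point_to_index(plan.normalization_point_mm))
        assert np.isclose(dose.dose[idx], 100.0)
        assert dose.dose.min() >= 0 and np.isfinite(dose.dose).all()

    def test_attenuation_oracle_on_uniform_water_slab(self):
        # [DERIVED] lateral-opposed beams through uniform water with a full
        # open field: dose(x) ~ exp(-mu(WED_l)) + exp(-mu(WED_r)), symmetric
        # about the midplane and normalized to 100 at the centre.
        n = 50
        ct = CTVolume(hu=np.zeros((6, 20, n)), spacing_mm=(4.0, 4.0, 4.0),
                      origin_mm=(-(n - 1) * 2.0, -38.0, -10.0))
        grid = ImagePlaneGrid(pixel_spacing_mm=2.0, width=80, height=40)
        ap = aperture_from_mask(polygon_to_mask(box(-60, -35, 60, 35), grid))
        from autowbrt.core import BeamDefinition, PlanSpec

        beams = [
            BeamDefinition(gantry_deg=g, isocenter_mm=(0, 0, 0),
                           jaws_mm=(-60, 60, -35, 35), weight=0.5, name=nm)
            for g, nm in ((270.0, "right-lateral"), (90.0, "left-lateral"))
        ]
        plan = PlanSpec(beams=beams, normalization_point_mm=(0, 0, 0),
                        apertures={"right-lateral": ap, "left-lateral": ap})
        dose = compute_toy_dose(plan, ct, mu_eff_per_mm=0.005)
        mid = dose.dose[3, 10, :]
        # symmetry about the midplane
        assert np.allclose(mid, mid[::-1], rtol=1e-6)
        # analytic profile shape (normalization cancels in the ratio)
        x = ct.voxel_centers()[0]
        L = float(n * 4.0)  # slab thickness along x
        depth_l = (x[-1] + 2.0) - x  # from the +x entry face
        expect = 0.5 * (np.exp(-0.005 * depth_l)
                        + np.exp(-0.005 * (L - depth_l)))
        assert np.allclose(mid / mid[25], expect / expect[25], rtol=1e-9)

    def test_norm_point_outside_fields_rejected(self, case, plan):
        shifted = type(plan)(
            beams=plan.beams, prescription_gy=plan.prescription_gy,
            n_fractions=plan.n_fractions,
            normalization_point_mm=(0.0, 0.0, 10000.0),
            apertures=plan.apertures,
        )
        with pytest.raises(ValueError):
            compute_toy_dose(shifted, case.ct)


class TestDVH:
    def _dose(self):
        vals = np.arange(1000, dtype=float).reshape(10, 10, 10) / 10.0
        ct = CTVolume(hu=np.zeros((10, 10, 10)), spacing_mm=(1, 1, 1),
                      origin_mm=(0, 0, 0))
        return DoseGrid(dose=vals, ct=ct)

    def test_percentile_sorting_oracle(self):
        # [DERIVED] Dx% uses the lower-interpolation (100-x) percentile:
        # sorted ascending, index floor((100-x)/100 * (n-1)).
        dose = self._dose()
        mask = np.ones((10, 10, 10), dtype=bool)
        flat = np.sort(dose.dose.ravel())
        for x in (99, 95, 50, 1):
            m = dvh_metric(dose, mask, f"D{x}%", prescription_gy=100.0)
            k = int(np.floor((100 - x) / 100.0 * (flat.size - 1)))
            assert np.isclose(m.value_gy, flat[k]), x

    def test_mean_and_scaling(self):
        dose = self._dose()
        mask = dose.dose >= 99.0
        m = dvh_metric(dose, mask, "mean", prescription_gy=30.0)
        assert np.isclose(m.value_gy, dose.dose[mask].mean() * 0.30)

    def test_bad_inputs(self):
        dose = self._dose()
        with pytest.raises(ValueError, match="empty"):
            dvh_metric(dose, np.zeros((10, 10, 10), bool), "D95%", 30.0)
        with pytest.raises(ValueError, match="metric"):
            dvh_metric(dose, np.ones((10, 10, 10), bool), "V20Gy", 30.0)
        with pytest.raises(ValueError):
            dvh_metric(dose, np.ones((10, 10, 10), bool), "D0%", 30.0)

    def test_report_covers_standard_structures(self, case, plan):
        dose = compute_toy_dose(plan, case.ct)
        masks = {n: pipeline.structure_mask(case, n)
                 for n in ("brain", "lens_l", "lens_r")}
        rep = dvh_report(dose, masks, 30.0)
        names = {(m.structure, m.metric) for m in rep}
        assert names == {("brain", "D99%"), ("brain", "D95%"), ("brain", "D1%"),
                         ("lens_l", "mean"), ("lens_r", "mean")}
        brain = {m.metric: m.value_gy for m in rep if m.structure == "brain"}
        assert brain["D99%"] <= brain["D95%"] <= brain["D1%"]
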
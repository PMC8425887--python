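import numpy as np
import pydicom
import pytest

from autowbrt import rt_io
from autowbrt.core import CTVolume
from autowbrt.plan_dose import build_plan
from autowbrt.field_builder import FieldRequest
from autowbrt import pipeline


@pytest.fixture(scope="module")
def small_ct():
    rng = np.random.default_rng(3)
    hu = rng.uniform(-1000, 1500, size=(5, 8, 9)).round()
    return CTVolume(hu=hu, spacing_mm=(2.0, 2.5, 3.0), origin_mm=(-8, -9, -6))


class TestCTSeries:
    def test_roundtrip_preserves_hu_and_geometry(self, tmp_path, small_ct):
        rt_io.write_ct_series(small_ct, tmp_path / "ct")
        back = rt_io.read_ct_series(tmp_path / "ct")
        assert np.allclose(back.hu, small_ct.hu, atol=0.501)
        assert back.spacing_mm == small_ct.spacing_mm
        assert back.origin_mm == small_ct.origin_mm

    def test_rescale_arithmetic(self, tmp_path, small_ct):
        # [DERIVED] stored = (hu - intercept) / slope; reading applies
        # stored * slope + intercept.
        rt_io.write_ct_series(small_ct, tmp_path / "ct", slope=2.0, intercept=-2048.0)
        f = sorted((tmp_path / "ct").glob("*.dcm"))[0]
        ds = pydicom.dcmread(f)
        assert float(ds.RescaleSlope) == 2.0
        stored = ds.pixel_array.astype(float)
        assert np.allclose(stored * 2.0 - 2048.0, small_ct.hu[0], atol=1.01)

    def test_mixed_series_rejected(self, tmp_path, small_ct):
        rt_io.write_ct_series(small_ct, tmp_path / "ct")
        rt_io.write_ct_series(small_ct, tmp_path / "ct2")
        (tmp_path / "ct" / "other.dcm").write_bytes(
            (sorted((tmp_path / "ct2").glob("*.dcm"))[0]).read_bytes()
        )
        with pytest.raises(ValueError, match="mixed"):
            rt_io.read_ct_series(tmp_path / "ct")

    def test_nonuniform_spacing_named_in_error(self, tmp_path, small_ct):
        rt_io.write_ct_series(small_ct, tmp_path / "ct")
        f = sorted((tmp_path / "ct").glob("*.dcm"))[-1]
        ds = pydicom.dcmread(f)
        ds.ImagePositionPatient[2] = float(ds.ImagePositionPatient[2]) + 1.7
        ds.save_as(f, enforce_file_format=True)
        with pytest.raises(ValueError, match="gap"):
            rt_io.read_ct_series(tmp_path / "ct")


class TestStructAndPlan:
    def test_structure_roundtrip(self, tmp_path, case):
        rt_io.write_structure_set(case.structures, tmp_path / "ss.dcm")
        back = rt_io.read_structure_set(tmp_path / "ss.dcm")
        assert back.names() == case.structures.names()
        for name in ("brain", "C1"):
            a, b = case.structures[name], back[name]
            assert sorted(a.rings) == pytest.approx(sorted(b.rings), abs=1e-4)
            ra = a.rings[a.slice_positions[0]][0]
            rb = b.rings[b.slice_positions[0]][0]
            assert np.allclose(ra, rb, atol=1e-3)

    def test_plan_roundtrip(self, tmp_path, case, tiny_model):
        fields = pipeline.build_fields_for_case(
            case, tiny_model, FieldRequest(extent=case.clinical_extent)
        )
        plan = build_plan(case, fields)
        rt_io.write_plan(plan, tmp_path / "plan.dcm")
        beams = rt_io.read_plan_beams(tmp_path / "plan.dcm")
        assert sorted(b.gantry_deg for b in beams) == [90.0, 270.0]
        for orig, back in zip(plan.beams, beams):
            assert back.weight == orig.weight
            assert np.allclose(back.jaws_mm, orig.jaws_mm, atol=1e-3)
            assert np.allclose(back.leaf_positions_mm, orig.leaf_positions_mm,
                               atol=1e-3)
            assert not back.jaw_only
            assert np.allclose(back.isocenter_mm, orig.isocenter_mm, atol=1e-3)

    def test_travel_limit_enforced_on_write(self, tmp_path, case, tiny_model):
        from autowbrt.core import MLCModel

        fields = pipeline.build_fields_for_case(
            case, tiny_model, FieldRequest(extent=case.clinical_extent)
        )
        plan = build_plan(case, fields, mlc=MLCModel())
        plan.beams[0].mlc = MLCModel(travel_limit_mm=10.0)
        with pytest.raises(ValueError, match="travel"):
            rt_io.write_plan(plan, tmp_path / "plan.dcm")


class TestImagesAndApertures:
    def test_drr_png_roundtrip_within_window_quantization(self, tmp_path, drr_left):
        rt_io.write_image(drr_left, tmp_path / "drr.png")
        arr, grid = rt_io.read_image(tmp_path / "drr.png")
        lo, hi = drr_left.pixels.min(), drr_left.pixels.max()
        assert np.allclose(arr, drr_left.pixels, atol=(hi - lo) / 65535 + 1e-9)
        assert grid.shape == drr_left.grid.shape

    def test_mask_png_roundtrip_exact(self, tmp_path, reference_left):
        rt_io.write_image(reference_left.mask, tmp_path / "m.png")
        back = rt_io.read_image(tmp_path / "m.png")
        assert (back.pixels == reference_left.mask.pixels).all()

    def test_aperture_json_roundtrip(self, tmp_path, reference_left):
        rt_io.write_aperture_json(reference_left, tmp_path / "ap.json")
        back = rt_io.read_aperture_json(tmp_path / "ap.json")
        assert back.extent == reference_left.extent
        assert back.beam_side == reference_left.beam_side
        assert (back.mask.pixels == reference_left.mask.pixels).all()


class TestBundles:
    def test_bundle_roundtrip(self, tmp_path, case):
        p = tmp_path / "case.npz"
        rt_io.save_case_bundle(case, p)
        back = rt_io.load_case_bundle(p)
        assert back.case_id == case.case_id
        assert np.allclose(back.ct.hu, case.ct.hu, atol=1e-3)  # float32 storage
        assert back.spec == case.spec
        assert back.clinical_extent == case.clinical_extent
        assert back.structures.names() == case.structures.names()
        for key, ap in case.reference_apertures.items():
            assert (back.reference_apertures[key].mask.pixels == ap.mask.pixels).all()

    def test_write_case_tree(self, tmp_path, case):
        rt_io.write_case(case, tmp_path / "case")
        assert (tmp_path / "case" / "rtstruct.dcm").exists()
        assert len(list((tmp_path / "case" / "ct").glob("*.dcm"))) == case.ct.shape[0]
        assert (tmp_path / "case" / "case.json").exists()
        back = rt_io.read_ct_series(tmp_path / "case" / "ct")
        assert np.allclose(back.hu, case.ct.hu, atol=0.501)
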
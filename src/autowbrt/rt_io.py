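"""Radiotherapy file formats: DICOM CT series, RT-STRUCT, minimal RT-PLAN,
16-bit PNG images with JSON sidecars, and JSON aperture polygons.

The RT-PLAN support is a documented minimal dialect — static beams, one
control point, ASYMX/ASYMY jaws and an MLCX device — sufficient for the
lateral-opposed plans this package produces.  All writers and readers are
exact inverses up to the stated quantization (16-bit HU storage, float
DICOM decimal strings).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pydicom
from PIL import Image
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .aperture import ApertureMask, FieldAperture, polygon_to_mask
from .core import BeamDefinition, Contour3D, CTVolume, MLCModel, PlanSpec, StructureSet
from .projection import DRRImage, ImagePlaneGrid
from shapely.geometry import Polygon

__all__ = [
    "write_ct_series",
    "read_ct_series",
    "write_structure_set",
    "read_structure_set",
    "write_plan",
    "read_plan_beams",
    "write_image",
    "read_image",
    "write_aperture_json",
    "read_aperture_json",
    "write_case",
    "save_case_bundle",
    "load_case_bundle",
]

_CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
_RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"
_RTPLAN_SOP = "1.2.840.10008.5.1.4.1.1.481.5"

_SLICE_TOL_MM = 1e-3


def _frame_uid(label: str | None) -> str:
    """Return a valid DICOM UID for a frame-of-reference label.

    Labels that already are well-formed UIDs pass through; other strings
    (e.g. human-readable case ids) map deterministically to a valid UID;
    empty/None yields a fresh random UID.
    """
    if not label:
        return generate_uid()
    import re

    if re.fullmatch(r"[0-9]+(\.[0-9]+)*", label) and len(label) <= 64:
        return label
    return generate_uid(entropy_srcs=[label])


def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


# --------------------------------------------------------------------- CT


def write_ct_series(
    ct: CTVolume,
    out_dir,
    frame_of_reference: str | None = None,
    slope: float = 1.0,
    intercept: float = -1024.0,
) -> str:
    """Write one DICOM CT instance per slice; returns the FrameOfReference UID."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    for_uid = _frame_uid(frame_of_reference)
    dx, dy, dz = ct.spacing_mm
    stored = np.round((ct.hu - intercept) / slope).astype(np.int16)
    for k in range(ct.shape[0]):
        sop_uid = generate_uid()
        ds = Dataset()
        ds.file_meta = _file_meta(_CT_SOP, sop_uid)
        ds.SOPClassUID = _CT_SOP
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "CT"
        ds.PatientName = "Phantom^Synthetic"
        ds.PatientID = "PHANTOM"
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = for_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [
            float(ct.origin_mm[0]),
            float(ct.origin_mm[1]),
            float(ct.origin_mm[2] + k * dz),
        ]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [float(dy), float(dx)]  # (row, col) spacing
        ds.SliceThickness = float(dz)
        ds.Rows, ds.Columns = ct.shape[1], ct.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.PixelData = stored[k].tobytes()
        ds.save_as(out / f"ct_{k:04d}.dcm", enforce_file_format=True)
    return for_uid


def read_ct_series(path) -> CTVolume:
    """Load a single-series directory of CT instances, sorted by position."""
    files = sorted(Path(path).glob("*.dcm"))
    slices = [pydicom.dcmread(f) for f in files]
    slices = [s for s in slices if getattr(s, "Modality", "") == "CT"]
    if not slices:
        raise ValueError(f"no CT instances found in {path}")
    series = {s.SeriesInstanceUID for s in slices}
    if len(series) != 1:
        raise ValueError(f"mixed CT series in {path}: {sorted(series)}")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(zs) > 1:
        gaps = np.diff(zs)
        if np.ptp(gaps) > _SLICE_TOL_MM:
            worst = int(np.argmax(np.abs(gaps - np.median(gaps))))
            raise ValueError(
                f"nonuniform slice spacing: gap {gaps[worst]:.4f} mm between "
                f"slices at z={zs[worst]:.3f} and z={zs[worst + 1]:.3f} "
                f"(median {np.median(gaps):.4f} mm)"
            )
        dz = float(np.mean(gaps))
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    hu = np.stack(
        [
            s.pixel_array.astype(float) * float(s.RescaleSlope)
            + float(s.RescaleIntercept)
            for s in slices
        ]
    )
    first = slices[0]
    dy, dx = (float(v) for v in first.PixelSpacing)
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    return CTVolume(hu=hu, spacing_mm=(dx, dy, dz), origin_mm=origin)


# ------------------------------------------------------------- RT-STRUCT


def write_structure_set(
    structures: StructureSet, path, frame_of_reference: str | None = None
) -> None:
    sop_uid = generate_uid()
    ds = Dataset()
    ds.file_meta = _file_meta(_RTSTRUCT_SOP, sop_uid)
    ds.SOPClassUID = _RTSTRUCT_SOP
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTSTRUCT"
    ds.PatientName = "Phantom^Synthetic"
    ds.PatientID = "PHANTOM"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.StructureSetLabel = "autowbrt"
    for_uid = _frame_uid(frame_of_reference or structures.frame_of_reference)
    ds.FrameOfReferenceUID = for_uid

    roi_seq, contour_seq = [], []
    for num, name in enumerate(structures.names(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = for_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        items = []
        contour = structures[name]
        for z in contour.slice_positions:
            for ring in contour.rings[z]:
                item = Dataset()
                item.ContourGeometricType = "CLOSED_PLANAR"
                item.NumberOfContourPoints = len(ring)
                data = np.column_stack([ring, np.full(len(ring), z)]).ravel()
                item.ContourData = [f"{v:.4f}" for v in data]
                items.append(item)
        rc.ContourSequence = items
        contour_seq.append(rc)
    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.save_as(path, enforce_file_format=True)


def read_structure_set(path) -> StructureSet:
    ds = pydicom.dcmread(path)
    if "FrameOfReferenceUID" not in ds:
        warnings.warn("RT-STRUCT lacks a frame-of-reference UID; best-effort load")
        for_uid = ""
    else:
        for_uid = str(ds.FrameOfReferenceUID)
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    structures: dict[str, Contour3D] = {}
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        rings: dict[float, list[np.ndarray]] = {}
        for item in getattr(rc, "ContourSequence", []):
            pts = np.asarray([float(v) for v in item.ContourData]).reshape(-1, 3)
            z = float(np.round(pts[:, 2].mean(), 4))
            rings.setdefault(z, []).append(pts[:, :2])
        structures[name] = Contour3D(rings=rings, name=name)
    return StructureSet(structures=structures, frame_of_reference=for_uid)


# ---------------------------------------------------------------- RT-PLAN


def write_plan(plan: PlanSpec, path) -> None:
    """Minimal static RT-PLAN (one control point per beam)."""
    for beam in plan.beams:
        if beam.mlc is not None and beam.leaf_positions_mm is not None:
            if np.any(np.abs(beam.leaf_positions_mm) > beam.mlc.travel_limit_mm):
                raise ValueError(
                    f"beam {beam.name!r}: leaf position beyond travel limit "
                    f"{beam.mlc.travel_limit_mm} mm"
                )
    sop_uid = generate_uid()
    ds = Dataset()
    ds.file_meta = _file_meta(_RTPLAN_SOP, sop_uid)
    ds.SOPClassUID = _RTPLAN_SOP
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTPLAN"
    ds.PatientName = "Phantom^Synthetic"
    ds.PatientID = "PHANTOM"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.RTPlanLabel = "autowbrt-wbrt"
    ds.RTPlanGeometry = "PATIENT"

    rx = Dataset()
    rx.TargetPrescriptionDose = float(plan.prescription_gy)
    ds.DoseReferenceSequence = [rx]

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = int(plan.n_fractions)
    fg.NumberOfBeams = len(plan.beams)
    refs = []
    beams = []
    for i, beam in enumerate(plan.beams, start=1):
        b = Dataset()
        b.BeamNumber = i
        b.BeamName = beam.name or f"beam{i}"
        b.BeamType = "STATIC"
        b.RadiationType = "PHOTON"
        b.TreatmentMachineName = beam.machine_label
        b.SourceAxisDistance = float(beam.sad_mm)
        b.NumberOfControlPoints = 1
        devices = []
        for dev_type, n in (("ASYMX", 1), ("ASYMY", 1)):
            d = Dataset()
            d.RTBeamLimitingDeviceType = dev_type
            d.NumberOfLeafJawPairs = n
            devices.append(d)
        if beam.mlc is not None and beam.leaf_positions_mm is not None:
            d = Dataset()
            d.RTBeamLimitingDeviceType = "MLCX"
            d.NumberOfLeafJawPairs = beam.mlc.n_pairs
            d.LeafPositionBoundaries = [f"{v:.4f}" for v in beam.mlc.row_edges()]
            devices.append(d)
        b.BeamLimitingDeviceSequence = devices

        cp = Dataset()
        cp.ControlPointIndex = 0
        cp.GantryAngle = float(beam.gantry_deg)
        # NominalBeamEnergy is numeric (MV); the label is e.g. "6MV".
        energy_mv = "".join(ch for ch in beam.energy_label if ch.isdigit() or ch == ".")
        cp.NominalBeamEnergy = float(energy_mv) if energy_mv else 0.0
        cp.IsocenterPosition = [float(v) for v in beam.isocenter_mm]
        cp.CumulativeMetersetWeight = 0.0
        positions = []
        x1, x2, y1, y2 = beam.jaws_mm
        for dev_type, vals in (("ASYMX", [x1, x2]), ("ASYMY", [y1, y2])):
            p = Dataset()
            p.RTBeamLimitingDeviceType = dev_type
            p.LeafJawPositions = [f"{v:.4f}" for v in vals]
            positions.append(p)
        if beam.mlc is not None and beam.leaf_positions_mm is not None:
            p = Dataset()
            p.RTBeamLimitingDeviceType = "MLCX"
            lp = beam.leaf_positions_mm
            p.LeafJawPositions = [f"{v:.4f}" for v in np.concatenate([lp[:, 0], lp[:, 1]])]
            positions.append(p)
        cp.BeamLimitingDevicePositionSequence = positions
        b.ControlPointSequence = [cp]
        beams.append(b)

        ref = Dataset()
        ref.ReferencedBeamNumber = i
        ref.BeamMeterset = float(beam.weight)
        refs.append(ref)
    fg.ReferencedBeamSequence = refs
    ds.FractionGroupSequence = [fg]
    ds.BeamSequence = beams
    ds.save_as(path, enforce_file_format=True)


def read_plan_beams(path) -> list[BeamDefinition]:
    """Parse the minimal RT-PLAN dialect back into beam definitions."""
    ds = pydicom.dcmread(path)
    weights = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for ref in getattr(fg, "ReferencedBeamSequence", []):
            weights[int(ref.ReferencedBeamNumber)] = float(ref.BeamMeterset)
    out = []
    for b in ds.BeamSequence:
        cp = b.ControlPointSequence[0]
        jaws = {}
        mlc_positions = None
        for p in cp.BeamLimitingDevicePositionSequence:
            vals = [float(v) for v in p.LeafJawPositions]
            if p.RTBeamLimitingDeviceType in ("ASYMX", "X"):
                jaws["x"] = vals
            elif p.RTBeamLimitingDeviceType in ("ASYMY", "Y"):
                jaws["y"] = vals
            elif p.RTBeamLimitingDeviceType == "MLCX":
                half = len(vals) // 2
                mlc_positions = np.column_stack([vals[:half], vals[half:]])
        if "x" not in jaws or "y" not in jaws:
            raise ValueError(f"beam {b.BeamName!r}: jaw positions missing")
        mlc = None
        jaw_only = True
        if mlc_positions is not None:
            n_pairs = len(mlc_positions)
            width = None
            for dev in getattr(b, "BeamLimitingDeviceSequence", []):
                if dev.RTBeamLimitingDeviceType == "MLCX":
                    bounds = [float(v) for v in dev.LeafPositionBoundaries]
                    width = float(np.mean(np.diff(bounds)))
            mlc = MLCModel(n_pairs=n_pairs, leaf_width_mm=width or 5.0)
            jaw_only = False
        out.append(
            BeamDefinition(
                gantry_deg=float(cp.GantryAngle),
                isocenter_mm=tuple(float(v) for v in cp.IsocenterPosition),
                jaws_mm=(jaws["x"][0], jaws["x"][1], jaws["y"][0], jaws["y"][1]),
                mlc=mlc,
                leaf_positions_mm=mlc_positions,
                weight=weights.get(int(b.BeamNumber), 1.0),
                sad_mm=float(getattr(b, "SourceAxisDistance", 1000.0)),
                machine_label=str(getattr(b, "TreatmentMachineName", "")),
                name=str(getattr(b, "BeamName", "")),
                jaw_only=jaw_only,
            )
        )
    return out


# ------------------------------------------------------------ PNG + JSON


def _grid_sidecar(grid: ImagePlaneGrid) -> dict:
    r0, c0 = grid.uv_to_pixel(0.0, 0.0)
    return {
        "pixel_spacing_mm": grid.pixel_spacing_mm,
        "width": grid.width,
        "height": grid.height,
        "isocenter_pixel_rowcol": [float(r0), float(c0)],
        "bev_axes": "u = patient anterior (+columns), v = patient superior (-rows); "
        "common convention for both lateral beams",
    }


def write_image(img: DRRImage | ApertureMask, path) -> None:
    """16-bit grayscale PNG plus a JSON sidecar with the BEV geometry.

    DRRs are min-max windowed to the full 16-bit range; masks map to
    {0, 65535}.  A constant DRR degenerates the window; it is written as
    zeros with a ``zero_range`` flag in the sidecar.
    """
    path = Path(path)
    side = {"kind": None, **_grid_sidecar(img.grid)}
    if isinstance(img, ApertureMask):
        arr = np.where(img.pixels, 65535, 0).astype(np.uint16)
        side["kind"] = "mask"
    else:
        px = img.pixels
        lo, hi = float(px.min()), float(px.max())
        side.update(kind="drr", window=[lo, hi], zero_range=bool(hi <= lo))
        if hi <= lo:
            arr = np.zeros(px.shape, dtype=np.uint16)
        else:
            arr = np.round((px - lo) / (hi - lo) * 65535).astype(np.uint16)
    Image.fromarray(arr).save(path)
    path.with_suffix(".json").write_text(json.dumps(side, indent=2))


def read_image(path):
    """Read a PNG+sidecar pair back to an ApertureMask or a windowed array."""
    path = Path(path)
    side = json.loads(path.with_suffix(".json").read_text())
    arr = np.asarray(Image.open(path), dtype=np.uint16)
    grid = ImagePlaneGrid(
        pixel_spacing_mm=side["pixel_spacing_mm"],
        width=side["width"],
        height=side["height"],
    )
    if side["kind"] == "mask":
        return ApertureMask(arr > 32767, grid)
    lo, hi = side["window"]
    if side.get("zero_range"):
        return np.full(arr.shape, lo), grid
    return arr.astype(float) / 65535.0 * (hi - lo) + lo, grid


def write_aperture_json(aperture: FieldAperture, path) -> None:
    doc = {
        "vertices_uv_mm": np.asarray(aperture.polygon.exterior.coords).tolist(),
        "technique": aperture.technique,
        "extent": aperture.extent,
        "flash_applied": aperture.flash_applied,
        "flash_mm": aperture.flash_mm,
        "beam_side": aperture.beam_side,
        "grid": _grid_sidecar(aperture.grid),
        "meta": {k: v for k, v in aperture.meta.items() if _jsonable(v)},
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_aperture_json(path) -> FieldAperture:
    doc = json.loads(Path(path).read_text())
    grid = ImagePlaneGrid(
        pixel_spacing_mm=doc["grid"]["pixel_spacing_mm"],
        width=doc["grid"]["width"],
        height=doc["grid"]["height"],
    )
    poly = Polygon(doc["vertices_uv_mm"])
    return FieldAperture(
        polygon=poly,
        mask=polygon_to_mask(poly, grid),
        technique=doc["technique"],
        extent=doc["extent"],
        flash_applied=doc["flash_applied"],
        flash_mm=doc["flash_mm"],
        beam_side=doc.get("beam_side", ""),
        meta=doc.get("meta", {}),
    )


# ---------------------------------------------------------- case bundles


def write_case(case, out_dir) -> None:
    """Full on-disk case: DICOM CT series + RT-STRUCT + aperture JSONs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for_uid = write_ct_series(case.ct, out / "ct")
    write_structure_set(case.structures, out / "rtstruct.dcm", frame_of_reference=for_uid)
    for (side, extent), ap in case.reference_apertures.items():
        write_aperture_json(ap, out / f"aperture_{side}_{extent}.json")
    (out / "case.json").write_text(
        json.dumps(
            {
                "case_id": case.case_id,
                "isocenter_mm": list(case.isocenter_mm),
                "clinical_extent": case.clinical_extent,
            },
            indent=2,
        )
    )


def save_case_bundle(case, path) -> None:
    """Compact single-file bundle (npz: HU array + JSON header) for fast I/O."""
    from dataclasses import asdict

    header = {
        "case_id": case.case_id,
        "spacing_mm": list(case.ct.spacing_mm),
        "origin_mm": list(case.ct.origin_mm),
        "isocenter_mm": list(case.isocenter_mm),
        "clinical_extent": case.clinical_extent,
        "spec": asdict(case.spec),
        "bev_grid": {
            "pixel_spacing_mm": case.bev_grid.pixel_spacing_mm,
            "width": case.bev_grid.width,
            "height": case.bev_grid.height,
        },
        "structures": {
            name: {
                str(z): [r.tolist() for r in rings]
                for z, rings in case.structures[name].rings.items()
            }
            for name in case.structures.names()
        },
        "reference_apertures": {
            f"{side}|{extent}": {
                "vertices_uv_mm": np.asarray(ap.polygon.exterior.coords).tolist(),
                "extent": ap.extent,
                "beam_side": ap.beam_side,
            }
            for (side, extent), ap in case.reference_apertures.items()
        },
    }
    np.savez_compressed(
        path, hu=case.ct.hu.astype(np.float32), header=np.array(json.dumps(header))
    )


def load_case_bundle(path):
    """Load a bundle back into a PhantomCase."""
    from .phantom import PhantomCase, PhantomSpec

    with np.load(path, allow_pickle=False) as f:
        header = json.loads(str(f["header"]))
        hu = f["hu"].astype(float)
    ct = CTVolume(
        hu=hu,
        spacing_mm=tuple(header["spacing_mm"]),
        origin_mm=tuple(header["origin_mm"]),
    )
    structures = StructureSet(
        structures={
            name: Contour3D(
                rings={
                    float(z): [np.asarray(r) for r in rings]
                    for z, rings in body.items()
                },
                name=name,
            )
            for name, body in header["structures"].items()
        },
        frame_of_reference=header["case_id"],
    )
    grid = ImagePlaneGrid(**header["bev_grid"])
    spec_kw = dict(header["spec"])
    for key in ("head_radii_mm", "voxel_spacing_mm", "grid_shape", "brain_center"):
        spec_kw[key] = tuple(spec_kw[key])
    apertures = {}
    for key, doc in header["reference_apertures"].items():
        side, extent = key.split("|")
        poly = Polygon(doc["vertices_uv_mm"])
        apertures[(side, extent)] = FieldAperture(
            polygon=poly,
            mask=polygon_to_mask(poly, grid),
            technique="traditional",
            extent=extent,
            beam_side=side,
        )
    return PhantomCase(
        case_id=header["case_id"],
        ct=ct,
        structures=structures,
        reference_apertures=apertures,
        spec=PhantomSpec(**spec_kw),
        isocenter_mm=tuple(header["isocenter_mm"]),
        bev_grid=grid,
        clinical_extent=header["clinical_extent"],
    )
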
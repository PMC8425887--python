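"""Parameterized synthetic head-and-neck phantoms.

Each phantom is a CSG assembly of ellipsoids and cylinders — a scalp/skull
shell around an ellipsoidal brain, orbital globes with lenses, a neck
cylinder with C1-C3 vertebral bodies, brainstem and spinal cord — voxelized
to Hounsfield units, contoured into a structure set, and paired with
geometrically constructed "clinical-style" reference apertures for the
laterally opposed whole-brain fields.  Realistic CT texture is a non-goal:
the anatomy is exactly analytic so every downstream stage has a geometric
oracle.

HU assignments default to air -1000, soft tissue 40, bone 1000, plus
optional Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely import affinity
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .aperture import FieldAperture, polygon_to_mask, mask_to_polygon, ApertureMask
from .core import Contour3D, CTVolume, StructureSet
from .projection import BeamGeometry, ImagePlaneGrid, project_contour_bev, project_point
from .voxels import mask_to_contour

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "generate_cohort",
    "make_reference_aperture",
    "SIDES",
    "EXTENTS",
]

SIDES = ("left-lateral", "right-lateral")
EXTENTS = ("C1", "C2")

AIR_HU = -1000.0
SOFT_TISSUE_HU = 40.0
BONE_HU = 1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Anatomy and grid parameters of one synthetic head phantom.

    ``head_radii_mm`` are the outer body semi-axes (left-right,
    anterior-posterior, superior-inferior); everything else is derived
    from them in fixed proportion unless separately parameterized.
    """

    seed: int = 0
    head_radii_mm: tuple[float, float, float] = (70.0, 90.0, 100.0)
    skull_thickness_mm: float = 6.0
    scalp_thickness_mm: float = 5.0
    neck_length_mm: float = 130.0
    vertebra_height_mm: float = 25.0
    vertebra_gap_mm: float = 5.0
    eye_radius_mm: float = 12.0
    lens_radius_mm: float = 4.0
    hu_noise_sd: float = 20.0
    voxel_spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    grid_shape: tuple[int, int, int] = (80, 92, 132)  # (nx, ny, nz)
    soft_tissue_hu: float = SOFT_TISSUE_HU
    bone_hu: float = BONE_HU

    def validate(self) -> None:
        a, b, c = self.head_radii_mm
        if min(a, b, c) <= 0:
            raise ValueError("head radii must be positive")
        if not (self.lens_radius_mm < self.eye_radius_mm < min(a, b, c)):
            raise ValueError("need lens_radius < eye_radius < min(head_radii)")
        for name in (
            "skull_thickness_mm",
            "scalp_thickness_mm",
            "neck_length_mm",
            "vertebra_height_mm",
            "vertebra_gap_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hu_noise_sd < 0:
            raise ValueError("hu_noise_sd must be nonnegative")
        inner = self.skull_inner_radii()
        if min(inner) <= 12:
            raise ValueError("skull inner cavity too small for a brain")
        # Grid extent checks (grid is centred on the head in x/y; z spans
        # the neck bottom to above the vertex, with 12 mm clearance).
        nx, ny, nz = self.grid_shape
        dx, dy, dz = self.voxel_spacing_mm
        if (nx - 1) * dx / 2 < a + 12:
            raise ValueError(
                f"grid too small: left-right half-extent {(nx - 1) * dx / 2:.1f} mm "
                f"< head semi-axis {a:.1f} + 12 mm clearance"
            )
        if (ny - 1) * dy / 2 < b + 12:
            raise ValueError(
                f"grid too small: anterior-posterior half-extent "
                f"{(ny - 1) * dy / 2:.1f} mm < head semi-axis {b:.1f} + 12 mm"
            )
        needed_z = (c + 12) - (self.neck_bottom_z() - 12)
        if (nz - 1) * dz < needed_z:
            raise ValueError(
                f"grid too small: superior-inferior extent {(nz - 1) * dz:.1f} mm "
                f"< required {needed_z:.1f} mm (vertex to below C3/neck bottom)"
            )

    # Derived geometry (head centre is the patient-coordinate origin).
    def skull_outer_radii(self) -> tuple[float, float, float]:
        t = self.scalp_thickness_mm
        a, b, c = self.head_radii_mm
        return (a - t, b - t, c - t)

    def skull_inner_radii(self) -> tuple[float, float, float]:
        t = self.skull_thickness_mm
        return tuple(r - t for r in self.skull_outer_radii())

    def brain_radii(self) -> tuple[float, float, float]:
        ia, ib, ic = self.skull_inner_radii()
        return (ia - 2.0, ib - 9.0, ic - 9.0)

    brain_center: tuple[float, float, float] = (0.0, 2.0, 8.0)

    def neck_top_z(self) -> float:
        return -0.6 * self.head_radii_mm[2]

    def neck_bottom_z(self) -> float:
        return self.neck_top_z() - self.neck_length_mm

    def neck_radius(self) -> float:
        return 0.68 * self.head_radii_mm[0]

    def vertebra_center_z(self, name: str) -> float:
        c1 = -(self.head_radii_mm[2] + 5.0)
        pitch = self.vertebra_height_mm + self.vertebra_gap_mm
        return c1 - pitch * {"C1": 0, "C2": 1, "C3": 2}[name]

    def eye_centers(self) -> dict[str, tuple[float, float, float]]:
        a, b, c = self.head_radii_mm
        y = -b + self.eye_radius_mm + 2.0
        z = -0.45 * c
        return {"eye_l": (0.43 * a, y, z), "eye_r": (-0.43 * a, y, z)}


def _grid_axes(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_spacing_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    z0 = spec.neck_bottom_z() - 12.0
    z = z0 + np.arange(nz) * dz
    return x, y, z


def _ellipsoid(xx, yy, zz, center, radii) -> np.ndarray:
    cx, cy, cz = center
    rx, ry, rz = radii
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2 <= 1.0


def _zcylinder(xx, yy, zz, cx, cy, radius, z_lo, z_hi) -> np.ndarray:
    return ((xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2) & (zz >= z_lo) & (zz <= z_hi)


@dataclass
class PhantomCase:
    """One synthetic patient: CT, structures and reference apertures."""

    case_id: str
    ct: CTVolume
    structures: StructureSet
    reference_apertures: dict[tuple[str, str], FieldAperture]
    spec: PhantomSpec
    isocenter_mm: tuple[float, float, float]
    bev_grid: ImagePlaneGrid
    clinical_extent: str = "C1"
    masks: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def beam(self, side: str) -> BeamGeometry:
        gantry = {"left-lateral": 90.0, "right-lateral": 270.0}[side]
        return BeamGeometry(gantry_deg=gantry, isocenter_mm=self.isocenter_mm)


def _structure_masks(spec: PhantomSpec):
    x, y, z = _grid_axes(spec)
    xx = x[None, None, :]
    yy = y[None, :, None]
    zz = z[:, None, None]
    a, b, c = spec.head_radii_mm

    head = _ellipsoid(xx, yy, zz, (0, 0, 0), (a, b, c))
    neck = _zcylinder(xx, yy, zz, 0.0, 5.0, spec.neck_radius(),
                      spec.neck_bottom_z(), spec.neck_top_z())
    eyes = {}
    for name, ctr in spec.eye_centers().items():
        eyes[name] = _ellipsoid(xx, yy, zz, ctr, (spec.eye_radius_mm,) * 3)
    eye_bumps = np.zeros_like(head)
    for name, ctr in spec.eye_centers().items():
        eye_bumps |= _ellipsoid(xx, yy, zz, ctr, (spec.eye_radius_mm + 3.0,) * 3)
    body = head | neck | eye_bumps

    outer = _ellipsoid(xx, yy, zz, (0, 0, 0), spec.skull_outer_radii())
    inner = _ellipsoid(xx, yy, zz, (0, 0, 0), spec.skull_inner_radii())
    skull = outer & ~inner
    # Foramen magnum / cervical canal carve-out so brainstem meets cord.
    canal = _zcylinder(xx, yy, zz, 0.0, 10.0, 12.0, z[0], -0.7 * c)
    skull &= ~canal

    # Orbital rims: a thin bone shell around each globe, as the orbit is
    # the cue that makes the eye position visible on a lateral DRR.
    orbit = np.zeros_like(head)
    for name, ctr in spec.eye_centers().items():
        orbit |= _ellipsoid(
            xx, yy, zz, ctr, (spec.eye_radius_mm + 3.0,) * 3
        ) & ~_ellipsoid(xx, yy, zz, ctr, (spec.eye_radius_mm,) * 3)
    orbit &= body

    brain = _ellipsoid(xx, yy, zz, spec.brain_center, spec.brain_radii())
    lenses = {}
    for ename, ctr in spec.eye_centers().items():
        off = spec.eye_radius_mm - spec.lens_radius_mm - 1.0
        lctr = (ctr[0], ctr[1] - off, ctr[2])
        lenses["lens" + ename[3:]] = _ellipsoid(
            xx, yy, zz, lctr, (spec.lens_radius_mm,) * 3
        )
    brainstem = _zcylinder(xx, yy, zz, 0.0, 10.0, 8.0, -(c - 5.0), -0.2 * c)
    cord = _zcylinder(xx, yy, zz, 0.0, 10.0, 4.0,
                      spec.neck_bottom_z() + 5.0, -(c - 5.0))
    vertebrae = {}
    h2 = spec.vertebra_height_mm / 2.0
    for name in ("C1", "C2", "C3"):
        zc = spec.vertebra_center_z(name)
        vertebrae[name] = _zcylinder(xx, yy, zz, 0.0, -12.0, 0.2 * a, zc - h2, zc + h2)

    masks = {
        "body": body,
        "brain": brain,
        "brainstem": brainstem & body,
        "spinal_cord": cord & body,
        **{k: v & body for k, v in eyes.items()},
        **{k: v & body for k, v in lenses.items()},
        **vertebrae,
    }
    bone = skull | orbit | vertebrae["C1"] | vertebrae["C2"] | vertebrae["C3"]
    return masks, bone, (x, y, z)


def generate_phantom(
    spec: PhantomSpec,
    case_id: str | None = None,
    bev_grid: ImagePlaneGrid | None = None,
    clinical_extent: str = "C1",
) -> PhantomCase:
    """Build one phantom case: CT, structure set and reference apertures.

    Deterministic for a fixed spec (the HU noise stream is seeded from
    ``spec.seed``).
    """
    spec.validate()
    masks, bone, (x, y, z) = _structure_masks(spec)
    hu = np.full(masks["body"].shape, AIR_HU)
    hu[masks["body"]] = spec.soft_tissue_hu
    hu[bone & masks["body"]] = spec.bone_hu
    if spec.hu_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.hu_noise_sd, size=hu.shape)
    dx, dy, dz = spec.voxel_spacing_mm
    ct = CTVolume(hu=hu, spacing_mm=(dx, dy, dz), origin_mm=(x[0], y[0], z[0]))

    structures = StructureSet(
        structures={
            name: mask_to_contour(m, x, y, z, name=name) for name, m in masks.items()
        },
        frame_of_reference=f"phantom-{spec.seed}",
    )
    # Marked isocenter: the brain centroid.
    bz, by, bx = [float(v) for v in np.argwhere(masks["brain"]).mean(axis=0)]
    iso = (x[0] + bx * dx, y[0] + by * dy, z[0] + bz * dz)

    if bev_grid is None:
        bev_grid = ImagePlaneGrid()
    case = PhantomCase(
        case_id=case_id or f"phantom-{spec.seed:06d}",
        ct=ct,
        structures=structures,
        reference_apertures={},
        spec=spec,
        isocenter_mm=iso,
        bev_grid=bev_grid,
        clinical_extent=clinical_extent,
        masks=masks,
    )
    for side in SIDES:
        cache: dict = {}
        for extent in EXTENTS:
            case.reference_apertures[(side, extent)] = make_reference_aperture(
                case, extent, side, _cache=cache
            )
    return case


def make_reference_aperture(
    case: PhantomCase,
    extent: str,
    side: str,
    eye_shield_margin_mm: float = 3.0,
    brain_margin_mm: float = 5.0,
    spine_margin_mm: float = 10.0,
    _cache: dict | None = None,
) -> FieldAperture:
    """Geometric oracle for a clinical-style traditional field aperture.

    Projects body/brain/eyes/vertebrae to the BEV, keeps everything above
    the brain's inferior level plus an anterior-inferior wedge covering
    the vertebral column down to the requested caudal extent, and shields
    the eyes with a margin-dilated block.  Pre-flash (clipped to the body
    projection), as used for segmentation training labels.
    """
    if extent not in EXTENTS:
        raise ValueError(f"unknown extent {extent!r}")
    if extent == "C2" and "C3" not in case.structures:
        raise KeyError("extent C2 requires structure 'C3'")
    for req in ("C1", "C2", "body", "brain"):
        if req not in case.structures:
            raise KeyError(f"missing structure {req!r}")

    beam = case.beam(side)
    c = _cache if _cache is not None else {}
    if "body" not in c:
        c["body"] = project_contour_bev(case.structures["body"], beam)
        c["brain"] = project_contour_bev(case.structures["brain"], beam)
        c["eyes"] = unary_union(
            [
                project_contour_bev(case.structures[n], beam)
                for n in ("eye_l", "eye_r")
                if n in case.structures
            ]
        )
        c["spine"] = unary_union(
            [
                project_contour_bev(case.structures[n], beam).buffer(spine_margin_mm)
                for n in ("C1", "C2", "C3")
                if n in case.structures
            ]
        )
    body_poly: Polygon = c["body"]
    brain_poly: Polygon = c["brain"]

    from .field_builder import compute_vertebral_landmarks  # local: avoid cycle

    if "landmarks" not in c:
        c["landmarks"] = compute_vertebral_landmarks(case.structures, case.ct)
    lm = c["landmarks"]
    z_extent = lm.caudal_extent_mm[extent]
    cx, cy, _ = lm.centroids_mm["C1"]
    _, v_e = project_point((cx, cy, z_extent), beam)

    brain_part = brain_poly.buffer(brain_margin_mm)
    v_j = brain_poly.bounds[1]
    u1 = brain_part.bounds[2] + 1.0
    u2 = c["spine"].bounds[2]
    u_back = body_poly.bounds[0] - 5.0
    u_top = body_poly.bounds[3] + 20.0

    upper = box(u_back, v_j, body_poly.bounds[2] + 5.0, u_top)
    wedge = Polygon([(u_back, v_j), (u1, v_j), (u2, v_e), (u_back, v_e)])
    keep = unary_union([upper, wedge, brain_part])
    ap = body_poly.intersection(keep)
    ap = ap.intersection(box(u_back - 5, v_e, body_poly.bounds[2] + 5.0, u_top))
    # The eye shield extends to the anterior field edge: nothing may stay
    # open anterior of the eyes at their level, or a single-level MLC
    # could not deliver the aperture (leaves close from the sides only).
    shield = c["eyes"].buffer(eye_shield_margin_mm)
    shield = unary_union(
        [
            g.union(affinity.translate(g, xoff=200.0)).convex_hull
            for g in getattr(shield, "geoms", [shield])
        ]
    )
    ap = ap.difference(shield)
    if ap.is_empty:
        raise ValueError("reference aperture construction produced an empty field")
    if ap.geom_type == "MultiPolygon":
        ap = max(ap.geoms, key=lambda g: g.area)
    ap = Polygon(ap.exterior)  # drop any holes (none expected)

    mask = polygon_to_mask(ap, case.bev_grid)
    return FieldAperture(
        polygon=ap,
        mask=mask,
        technique="traditional",
        extent=extent,
        flash_applied=False,
        flash_mm=0.0,
        beam_side=side,
        meta={"source": "geometric-oracle", "caudal_extent_z_mm": float(z_extent)},
    )


def generate_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    variability: dict[str, float] | None = None,
    seed: int = 0,
    c2_fraction: float = 0.2,
    bev_grid: ImagePlaneGrid | None = None,
    max_retries: int = 20,
) -> list[PhantomCase]:
    """Generate ``n`` phantoms with independently jittered anatomy.

    ``variability`` maps spec field names to relative standard deviations;
    draws are clamped at two standard deviations so jittered anatomy stays
    inside the fixed grid.  Each case is assigned a "clinical" caudal
    extent (C2 with probability ``c2_fraction``), emulating a cohort in
    which most patients were treated to C1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base_spec = base_spec or PhantomSpec()
    if variability is None:
        variability = {
            "head_radii_mm": 0.05,
            "skull_thickness_mm": 0.10,
            "neck_length_mm": 0.04,
            "vertebra_height_mm": 0.08,
            "vertebra_gap_mm": 0.15,
            "eye_radius_mm": 0.08,
        }
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        extent = "C2" if rng.random() < c2_fraction else "C1"
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = None
        for _ in range(max_retries):
            candidate = _jitter_spec(base_spec, variability, rng, case_seed)
            try:
                candidate.validate()
            except ValueError:
                continue
            spec = candidate
            break
        if spec is None:
            raise RuntimeError(
                f"could not draw a valid phantom spec for case {i} "
                f"after {max_retries} retries"
            )
        cases.append(
            generate_phantom(
                spec,
                case_id=f"case{i:03d}",
                bev_grid=bev_grid,
                clinical_extent=extent,
            )
        )
    return cases


def _jitter_spec(base: PhantomSpec, variability, rng, case_seed: int) -> PhantomSpec:
    def draw(value: float, rel_sd: float) -> float:
        if rel_sd == 0:
            return value
        return value * (1.0 + np.clip(rng.normal(0.0, rel_sd), -2 * rel_sd, 2 * rel_sd))

    kw: dict = {"seed": case_seed}
    for name, rel in variability.items():
        val = getattr(base, name)
        if isinstance(val, tuple):
            kw[name] = tuple(draw(v, rel) for v in val)
        else:
            kw[name] = draw(val, rel)
    return replace(base, **kw)
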
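"""Assemble the four patient-specific whole-brain field options.

Traditional fields take the segmentation model's predicted mask, clip it
to the projected body contour, snap the inferior border to the requested
caudal extent (C1 or C2, from vertebral-centroid midpoints) and add skin
flash.  Scalp-sparing fields replace the superior/posterior edge with the
projection of the 5 mm-expanded brain contour while keeping the
traditional anterior/inferior edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .aperture import (
    ApertureMask,
    FieldAperture,
    add_skin_flash,
    aperture_from_mask,
    clip_to_body,
    polygon_to_mask,
)
from .core import Contour3D, CTVolume, StructureSet
from .projection import (
    BeamGeometry,
    expand_contour_3d,
    project_contour_bev,
    project_point,
)
from .voxels import contour_to_mask

__all__ = [
    "VertebralLandmarks",
    "FieldRequest",
    "compute_vertebral_landmarks",
    "set_inferior_border",
    "build_traditional_field",
    "build_scalp_sparing_field",
    "mirror_for_opposed_beam",
]


@dataclass(frozen=True)
class VertebralLandmarks:
    """Vertebral-body centroids and derived caudal field extents (mm).

    The caudal extent of Ck is the midpoint of the superior-inferior
    centroid coordinates of Ck and Ck+1.
    """

    centroids_mm: dict[str, tuple[float, float, float]]
    caudal_extent_mm: dict[str, float]

    def __post_init__(self) -> None:
        zs = [self.centroids_mm[n][2] for n in ("C1", "C2", "C3") if n in self.centroids_mm]
        if any(lower >= upper for lower, upper in zip(zs[1:], zs)):
            raise ValueError("vertebral centroids must strictly decrease C1 > C2 > C3")


@dataclass(frozen=True)
class FieldRequest:
    """A physician's field-option choice plus its two margins."""

    technique: str = "traditional"
    extent: str = "C1"
    flash_mm: float = 10.0
    brain_margin_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.technique not in ("traditional", "scalp_sparing"):
            raise ValueError(f"unknown technique {self.technique!r}")
        if self.extent not in ("C1", "C2"):
            raise ValueError(f"unknown extent {self.extent!r}")
        if self.flash_mm < 0 or self.brain_margin_mm < 0:
            raise ValueError("margins must be nonnegative")


def compute_vertebral_landmarks(
    structures: StructureSet, ct: CTVolume | None = None
) -> VertebralLandmarks:
    """Centroids of the voxelized C1-C3 labels and midpoint caudal extents."""
    structures.require("C1", "C2")
    names = [n for n in ("C1", "C2", "C3") if n in structures]
    centroids: dict[str, tuple[float, float, float]] = {}
    for n in names:
        contour = structures[n]
        if ct is not None:
            mask = contour_to_mask(contour, ct)
            if not mask.any():
                raise ValueError(f"structure {n!r} voxelized to an empty mask")
            x, y, z = ct.voxel_centers()
            idx = np.argwhere(mask)
            centroids[n] = (
                float(x[0] + idx[:, 2].mean() * ct.spacing_mm[0]),
                float(y[0] + idx[:, 1].mean() * ct.spacing_mm[1]),
                float(z[0] + idx[:, 0].mean() * ct.spacing_mm[2]),
            )
        else:
            # Area-weighted centroid of the per-slice rings.
            tot_a = 0.0
            acc = np.zeros(3)
            for zpos, rings in contour.rings.items():
                for ring in rings:
                    p = Polygon(ring)
                    acc += p.area * np.array([p.centroid.x, p.centroid.y, zpos])
                    tot_a += p.area
            if tot_a == 0:
                raise ValueError(f"structure {n!r} has no area")
            centroids[n] = tuple(acc / tot_a)
    extents: dict[str, float] = {}
    if "C2" in centroids:
        extents["C1"] = (centroids["C1"][2] + centroids["C2"][2]) / 2.0
    if "C3" in centroids:
        extents["C2"] = (centroids["C2"][2] + centroids["C3"][2]) / 2.0
    return VertebralLandmarks(centroids_mm=centroids, caudal_extent_mm=extents)


def caudal_extent_v(
    landmarks: VertebralLandmarks, extent: str, beam: BeamGeometry
) -> float:
    """BEV v-coordinate of a caudal extent, divergence-aware.

    The patient-space extent level is projected at the vertebral column's
    depth (the C1 centroid's x/y), not copied as a raw coordinate.
    """
    if extent not in landmarks.caudal_extent_mm:
        raise KeyError(
            f"caudal extent {extent!r} unavailable (need structure "
            f"{'C3' if extent == 'C2' else 'C2'})"
        )
    cx, cy, _ = landmarks.centroids_mm["C1"]
    _, v = project_point((cx, cy, landmarks.caudal_extent_mm[extent]), beam)
    return v


def set_inferior_border(
    aperture: FieldAperture, target_v: float, body_projection: Polygon
) -> FieldAperture:
    """Move an aperture's inferior border to ``target_v``.

    Below the current border the bottom-row cross-section is extruded
    down and clipped to the body projection (dilated by the flash margin
    if flash was already applied); above it the aperture is cropped.
    """
    grid = aperture.grid
    v = grid.v_coords()
    px = aperture.mask.pixels.copy()
    rows = np.where(px.any(axis=1))[0]
    if len(rows) == 0:
        raise ValueError("cannot set the border of an empty aperture")
    if target_v < body_projection.bounds[1] - grid.pixel_spacing_mm:
        raise ValueError("target border lies below the body projection")
    bottom = rows[-1]
    target_row = int(np.argmin(np.abs(v - target_v)))
    if target_row > bottom:  # extend down
        cols = px[bottom]
        body = body_projection
        if aperture.flash_applied and aperture.flash_mm > 0:
            body = body.buffer(aperture.flash_mm)
        body_px = polygon_to_mask(body, grid).pixels
        for r in range(bottom + 1, target_row + 1):
            px[r] = cols & body_px[r]
    elif target_row < bottom:  # crop
        px[target_row + 1 :] = False
    out = aperture_from_mask(
        ApertureMask(px, grid, flags=list(aperture.mask.flags)),
        technique=aperture.technique,
        extent=aperture.extent,
    )
    out.flash_applied = aperture.flash_applied
    out.flash_mm = aperture.flash_mm
    out.beam_side = aperture.beam_side
    out.meta = dict(aperture.meta)
    return out


def build_traditional_field(
    pred: ApertureMask,
    body_projection: Polygon,
    landmarks: VertebralLandmarks,
    request: FieldRequest,
    beam: BeamGeometry,
    beam_side: str = "",
) -> FieldAperture:
    """Predicted mask -> clinical traditional field.

    Pipeline: clip to the projected body, snap the inferior border to the
    requested caudal extent, then add skin flash on the
    anterior/posterior/cranial sides.
    """
    if pred.is_empty():
        raise ValueError("predicted mask is empty")
    clipped = clip_to_body(pred, body_projection)
    ap = aperture_from_mask(clipped, technique="traditional", extent=request.extent)
    ap.beam_side = beam_side
    v_target = caudal_extent_v(landmarks, request.extent, beam)
    ap = set_inferior_border(ap, v_target, body_projection)
    out = add_skin_flash(ap.mask, body_projection, request.flash_mm)
    out.technique = "traditional"
    out.extent = request.extent
    out.beam_side = beam_side
    out.meta.update(
        {"caudal_extent_v_mm": float(v_target), "request": request.__dict__.copy()}
    )
    return out


def build_scalp_sparing_field(
    traditional: FieldAperture,
    brain: Contour3D,
    beam: BeamGeometry,
    landmarks: VertebralLandmarks,
    request: FieldRequest,
) -> FieldAperture:
    """Conform the superior/posterior edge to the expanded-brain projection.

    ``B`` is the BEV projection of the brain expanded by
    ``request.brain_margin_mm``; the output is
    ``traditional ∩ (B ∪ N)`` where ``N`` (the neck bridge) is the part
    of the traditional field below the inferior extent of B's posterior
    half, carrying the field down the vertebral column.
    """
    if traditional.extent != request.extent:
        raise ValueError("traditional field and request disagree on caudal extent")
    expanded = expand_contour_3d(brain, request.brain_margin_mm)
    B = project_contour_bev(expanded, beam)
    if not B.intersects(traditional.polygon):
        raise ValueError("expanded-brain projection is disjoint from the field")
    grid = traditional.grid

    # Inferior extent of B's posterior half.
    u_mid = 0.5 * (B.bounds[0] + B.bounds[2])
    bpts = np.asarray(B.exterior.coords)
    post = bpts[bpts[:, 0] <= u_mid]
    v_cut = float(post[:, 1].min())

    B_px = polygon_to_mask(B, grid).pixels
    vv = grid.v_coords()[:, None]
    neck = traditional.mask.pixels & (vv <= v_cut)
    out_px = traditional.mask.pixels & (B_px | neck)
    out = aperture_from_mask(
        ApertureMask(out_px, grid), technique="scalp_sparing", extent=request.extent
    )
    out.flash_applied = traditional.flash_applied
    out.flash_mm = traditional.flash_mm
    out.beam_side = traditional.beam_side
    out.meta = dict(traditional.meta)
    out.meta["scalp_sparing_v_cut_mm"] = v_cut
    return out


def mirror_for_opposed_beam(aperture: FieldAperture) -> FieldAperture:
    """Reflect an aperture about u = 0 (for the opposed beam's native frame)."""
    px = aperture.mask.pixels[:, ::-1].copy()
    grid = aperture.grid
    # Pixel-centre u-coordinates are symmetric about 0, so reflection is
    # exact on the raster.
    out = aperture_from_mask(
        ApertureMask(px, grid, flags=list(aperture.mask.flags)),
        technique=aperture.technique,
        extent=aperture.extent,
    )
    out.flash_applied = aperture.flash_applied
    out.flash_mm = aperture.flash_mm
    out.beam_side = {
        "left-lateral": "right-lateral",
        "right-lateral": "left-lateral",
        "": "",
    }[aperture.beam_side]
    out.meta = dict(aperture.meta)
    return out
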
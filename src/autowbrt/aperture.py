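"""Aperture mask algebra in the beams-eye view.

Rasterize MLC/jaw-defined beams to masks, fit MLC leaves to apertures,
clip predicted masks to the projected body contour (pre-processing), and
add skin flash outside the body on the anterior/posterior/cranial sides
(post-processing).  Masks are rasterizations of the aperture polygon at
the DRR pixel grid; pixel-centre membership is the rasterization rule
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon
from skimage import measure

from .core import BeamDefinition, MLCModel
from .projection import ImagePlaneGrid

__all__ = [
    "ApertureMask",
    "FieldAperture",
    "polygon_to_mask",
    "mask_to_polygon",
    "mlc_to_mask",
    "mask_to_mlc",
    "clip_to_body",
    "add_skin_flash",
]


@dataclass
class ApertureMask:
    """Binary field mask aligned with an image-plane grid."""

    pixels: np.ndarray
    grid: ImagePlaneGrid
    flags: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.shape != self.grid.shape:
            raise ValueError("mask shape does not match its grid")

    @property
    def area_mm2(self) -> float:
        return float(self.pixels.sum()) * self.grid.pixel_spacing_mm**2

    def is_empty(self) -> bool:
        return not self.pixels.any()


@dataclass
class FieldAperture:
    """A treatment-field aperture: polygon (BEV mm) plus raster mask."""

    polygon: Polygon
    mask: ApertureMask
    technique: str = "traditional"  # or "scalp_sparing"
    extent: str = "C1"  # or "C2"
    flash_applied: bool = False
    flash_mm: float = 0.0
    beam_side: str = ""  # "left-lateral" / "right-lateral"
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.technique not in ("traditional", "scalp_sparing"):
            raise ValueError(f"unknown technique {self.technique!r}")
        if self.extent not in ("C1", "C2"):
            raise ValueError(f"unknown extent {self.extent!r}")
        if self.flash_mm < 0:
            raise ValueError("flash_mm must be nonnegative")

    @property
    def grid(self) -> ImagePlaneGrid:
        return self.mask.grid

    def inferior_border_v(self) -> float:
        """v-coordinate of the lowest open pixel row (mm)."""
        rows = np.where(self.mask.pixels.any(axis=1))[0]
        if len(rows) == 0:
            raise ValueError("empty aperture has no inferior border")
        return float(self.grid.v_coords()[rows[-1]])


def polygon_to_mask(poly: Polygon | MultiPolygon, grid: ImagePlaneGrid) -> ApertureMask:
    """Rasterize a BEV polygon: a pixel is open iff its centre is inside."""
    uu, vv = grid.meshgrid()
    if poly.is_empty:
        return ApertureMask(np.zeros(grid.shape, dtype=bool), grid)
    inside = shapely.contains_xy(poly, uu, vv)
    return ApertureMask(inside, grid)


def mask_to_polygon(mask: ApertureMask) -> Polygon:
    """Outer polygon of a mask via marching squares at the 0.5 level."""
    if mask.is_empty():
        return Polygon()
    padded = np.pad(mask.pixels.astype(float), 1)
    s = mask.grid.pixel_spacing_mm
    u0 = mask.grid.u_coords()[0]
    v0 = mask.grid.v_coords()[0]
    polys = []
    for c in measure.find_contours(padded, 0.5):
        u = u0 + (c[:, 1] - 1) * s
        v = v0 - (c[:, 0] - 1) * s
        if len(c) >= 4:
            p = Polygon(np.column_stack([u, v]))
            if p.is_valid and p.area > 0:
                polys.append(p)
    if not polys:
        return Polygon()
    return max(polys, key=lambda p: p.area)


def aperture_from_mask(
    mask: ApertureMask,
    technique: str = "traditional",
    extent: str = "C1",
    **kw,
) -> FieldAperture:
    return FieldAperture(
        polygon=mask_to_polygon(mask), mask=mask, technique=technique, extent=extent, **kw
    )


def mlc_to_mask(beam: BeamDefinition, grid: ImagePlaneGrid) -> ApertureMask:
    """Rasterize a beam's jaw + MLC collimation onto an image grid.

    A pixel is open iff its centre lies inside the jaw rectangle and, if
    an MLC is fitted, inside its leaf row's open (left, right) interval.
    """
    x1, x2, y1, y2 = beam.jaws_mm
    u = grid.u_coords()
    v = grid.v_coords()
    uu, vv = np.meshgrid(u, v)
    open_px = (uu >= x1) & (uu <= x2) & (vv >= y1) & (vv <= y2)
    flags: list[str] = []
    if beam.mlc is not None and beam.leaf_positions_mm is not None:
        mlc = beam.mlc
        rows = mlc.row_of_v(vv)
        valid = (rows >= 0) & (rows < mlc.n_pairs)
        lp = beam.leaf_positions_mm
        left = np.where(valid, lp[np.clip(rows, 0, mlc.n_pairs - 1), 0], 0.0)
        right = np.where(valid, lp[np.clip(rows, 0, mlc.n_pairs - 1), 1], 0.0)
        open_px &= valid & (uu > left) & (uu < right)
    ext = grid.extent()
    if x1 < ext[0] or x2 > ext[1] or y1 < ext[2] or y2 > ext[3]:
        flags.append("jaw box truncated by image grid")
    return ApertureMask(open_px, grid, flags=flags)


def mask_to_mlc(
    aperture: FieldAperture,
    mlc: MLCModel | None = None,
    jaw_margin_mm: float = 2.0,
) -> tuple[tuple[float, float, float, float], np.ndarray]:
    """Fit MLC leaves and jaws that enclose an aperture.

    Per leaf row the open interval is the full u-extent of the aperture's
    open pixels over that row's v-interval, widened to pixel edges
    (fit-to-enclose: leaves never shield aperture area).  Rows without
    aperture overlap are parked closed at the nearest open row's left
    edge.  Returns ``(jaws, leaf_positions)``.
    """
    if mlc is None:
        mlc = MLCModel()
    if aperture.mask.is_empty():
        raise ValueError("cannot fit an MLC to an empty aperture")
    grid = aperture.grid
    half = grid.pixel_spacing_mm / 2.0
    u = grid.u_coords()
    v = grid.v_coords()
    px = aperture.mask.pixels
    edges = mlc.row_edges()
    leaf = np.zeros((mlc.n_pairs, 2))
    open_rows = []
    for k in range(mlc.n_pairs):
        lo, hi = edges[k], edges[k + 1]
        band = (v >= lo) & (v < hi)
        cols = px[band].any(axis=0)
        if cols.any():
            l = u[cols].min() - half
            r = u[cols].max() + half
            if r - l > 2 * mlc.travel_limit_mm:
                raise ValueError(f"aperture wider than leaf travel in row {k}")
            leaf[k] = (l, r)
            open_rows.append(k)
    if not open_rows:
        raise ValueError("aperture does not overlap any MLC leaf row")
    for k in range(mlc.n_pairs):
        if k not in open_rows:
            nearest = min(open_rows, key=lambda r: abs(r - k))
            park = leaf[nearest, 0]
            leaf[k] = (park, park)
    rows_any = np.where(px.any(axis=1))[0]
    cols_any = np.where(px.any(axis=0))[0]
    jaws = (
        float(u[cols_any[0]] - half - jaw_margin_mm),
        float(u[cols_any[-1]] + half + jaw_margin_mm),
        float(v[rows_any[-1]] - half - jaw_margin_mm),
        float(v[rows_any[0]] + half + jaw_margin_mm),
    )
    return jaws, leaf


def clip_to_body(mask: ApertureMask, body_projection: Polygon) -> ApertureMask:
    """Intersect a mask with the projected body contour (pre-processing).

    An empty intersection is returned as an empty mask carrying a warning
    flag rather than raising.
    """
    body = polygon_to_mask(body_projection, mask.grid)
    out = mask.pixels & body.pixels
    flags = list(mask.flags)
    if not out.any():
        flags.append("empty intersection with body projection")
    return ApertureMask(out, mask.grid, flags=flags)


_DIRECTION_CLASSES = {
    "anterior": np.array([1.0, 0.0]),  # +u
    "posterior": np.array([-1.0, 0.0]),  # -u
    "cranial": np.array([0.0, 1.0]),  # +v
}


def add_skin_flash(
    mask: ApertureMask,
    body_projection: Polygon,
    flash_mm: float = 10.0,
    directions: tuple[str, ...] = ("anterior", "posterior", "cranial"),
) -> FieldAperture:
    """Extend the aperture ``flash_mm`` beyond the body contour.

    Wherever the (body-clipped) mask reaches the projected body boundary,
    the aperture is pushed outward to exactly ``flash_mm`` outside the
    body, but only where the outward normal lies within 45 degrees of an
    allowed direction class (anterior +u, posterior -u, cranial +v).  The
    inferior border and interior edges (e.g., eye shields) are untouched.
    """
    if flash_mm < 0:
        raise ValueError("flash_mm must be nonnegative")
    grid = mask.grid
    body = polygon_to_mask(body_projection, grid).pixels
    m = mask.pixels & body
    if flash_mm == 0:
        am = ApertureMask(m, grid, flags=list(mask.flags))
        ap = aperture_from_mask(am)
        ap.flash_applied = True
        ap.flash_mm = 0.0
        return ap

    s = grid.pixel_spacing_mm
    # Body-boundary pixels the aperture touches (within one pixel).
    boundary = body & ~ndimage.binary_erosion(body)
    touched = boundary & ndimage.binary_dilation(m, iterations=1)

    # For every exterior pixel: distance to the body and the nearest body
    # pixel (EDT with index return); flash where that nearest pixel is a
    # touched boundary pixel and the outward direction is allowed.
    dist, (inz, inx) = ndimage.distance_transform_edt(
        ~body, sampling=(s, s), return_indices=True
    )
    near_touched = touched[inz, inx]
    rr, cc = np.indices(grid.shape)
    dr = (rr - inz).astype(float)  # +dr is -v (rows grow downward)
    dc = (cc - inx).astype(float)  # +dc is +u
    norm = np.hypot(dr, dc)
    with np.errstate(invalid="ignore", divide="ignore"):
        dir_u = dc / norm
        dir_v = -dr / norm
    allowed = np.zeros(grid.shape, dtype=bool)
    cos45 = np.cos(np.deg2rad(45.0)) - 1e-9
    for name in directions:
        ref = _DIRECTION_CLASSES[name]
        allowed |= (dir_u * ref[0] + dir_v * ref[1]) >= cos45
    flash_px = (~body) & (dist <= flash_mm + 1e-9) & near_touched & allowed
    # The inferior border is never flashed: nothing below the lowest open row.
    bottom_row = int(np.where(m.any(axis=1))[0][-1]) if m.any() else -1
    flash_px[bottom_row + 1 :, :] = False

    ext = grid.extent()
    poly_b = body_projection
    if (
        poly_b.bounds[0] - flash_mm < ext[0] - s
        or poly_b.bounds[2] + flash_mm > ext[1] + s
        or poly_b.bounds[3] + flash_mm > ext[3] + s
    ):
        raise ValueError("skin flash would exceed the image grid; enlarge the grid")

    out = ApertureMask(m | flash_px, grid, flags=list(mask.flags))
    ap = aperture_from_mask(out)
    ap.flash_applied = True
    ap.flash_mm = float(flash_mm)
    return ap
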
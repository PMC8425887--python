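"""Divergent-beam geometry: DRR ray casting, BEV projection, 3D expansion.

Beams-eye-view (BEV) convention
-------------------------------
The image plane sits at the isocenter (magnification 1 there); the source
is ``sad_mm`` upstream along the beam axis.  BEV axes for lateral beams
use a *common* convention so a single segmentation model can serve both
opposed fields:

* ``u`` — patient **anterior** positive,
* ``v`` — patient **superior** positive,

for both the left-lateral (gantry 90) and right-lateral (gantry 270)
beam; the 270 beam's native image is mirrored into this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint, MultiPolygon, Polygon
from shapely.ops import unary_union

from .core import Contour3D, CTVolume
from .voxels import mask_to_contour, rasterize_rings

__all__ = [
    "BeamGeometry",
    "ImagePlaneGrid",
    "DRRImage",
    "project_point",
    "project_points",
    "project_contour_bev",
    "compute_drr",
    "expand_contour_3d",
]


@dataclass(frozen=True)
class BeamGeometry:
    """Source/isocenter geometry of one beam."""

    gantry_deg: float
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sad_mm: float = 1000.0

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (e_u, e_v, s_hat) in patient LPS coordinates.

        ``s_hat`` points from the isocenter toward the source.  ``e_u`` is
        chosen so that u is patient-anterior for both lateral beams
        (beams with gantry in (180, 360) are mirrored into the common
        frame).
        """
        g = np.deg2rad(self.gantry_deg)
        s_hat = np.array([np.sin(g), -np.cos(g), 0.0])
        e_v = np.array([0.0, 0.0, 1.0])
        e_u = np.array([s_hat[1], -s_hat[0], 0.0])
        if 180.0 < self.gantry_deg < 360.0:
            e_u = -e_u
        return e_u, e_v, s_hat

    @property
    def source_mm(self) -> np.ndarray:
        _, _, s_hat = self.basis()
        return np.asarray(self.isocenter_mm) + self.sad_mm * s_hat


def project_points(points: np.ndarray, beam: BeamGeometry) -> np.ndarray:
    """Perspective-project (n, 3) patient-mm points to (n, 2) BEV mm."""
    p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(beam.isocenter_mm)
    e_u, e_v, s_hat = beam.basis()
    d = p @ s_hat
    if np.any(d >= beam.sad_mm):
        raise ValueError("point at or behind the radiation source")
    scale = beam.sad_mm / (beam.sad_mm - d)
    return np.column_stack([(p @ e_u) * scale, (p @ e_v) * scale])


def project_point(p, beam: BeamGeometry) -> tuple[float, float]:
    """Project a single 3D point; returns (u, v) in BEV mm."""
    uv = project_points(np.asarray(p, dtype=float)[None, :], beam)[0]
    return float(uv[0]), float(uv[1])


@dataclass(frozen=True)
class ImagePlaneGrid:
    """Regular pixel grid on the isocenter plane.

    Row 0 is the top of the image (largest v); column 0 is the smallest
    u.  Pixel (row, col) centres are at
    ``u = (col - (W-1)/2) * s`` and ``v = ((H-1)/2 - row) * s``.
    """

    pixel_spacing_mm: float = 2.0
    width: int = 144
    height: int = 224

    def __post_init__(self) -> None:
        if self.pixel_spacing_mm <= 0 or self.width <= 0 or self.height <= 0:
            raise ValueError("grid parameters must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def u_coords(self) -> np.ndarray:
        s = self.pixel_spacing_mm
        return (np.arange(self.width) - (self.width - 1) / 2.0) * s

    def v_coords(self) -> np.ndarray:
        s = self.pixel_spacing_mm
        return ((self.height - 1) / 2.0 - np.arange(self.height)) * s

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.u_coords(), self.v_coords())

    def uv_to_pixel(self, u, v) -> tuple[np.ndarray, np.ndarray]:
        """Continuous (row, col) of BEV points."""
        s = self.pixel_spacing_mm
        col = np.asarray(u) / s + (self.width - 1) / 2.0
        row = (self.height - 1) / 2.0 - np.asarray(v) / s
        return row, col

    def extent(self) -> tuple[float, float, float, float]:
        """(u_min, u_max, v_min, v_max) of pixel centres."""
        u = self.u_coords()
        v = self.v_coords()
        return float(u[0]), float(u[-1]), float(v[-1]), float(v[0])


@dataclass
class DRRImage:
    """Digitally reconstructed radiograph: water-equivalent path length (mm).

    ``coverage_ok`` is False on pixels whose ray entered or left the CT
    grid through attenuating material (anatomy truncated by the scan).
    """

    pixels: np.ndarray
    grid: ImagePlaneGrid
    beam: BeamGeometry
    coverage_ok: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != self.grid.shape:
            raise ValueError("DRR pixel array does not match its grid")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("DRR pixels must be finite and nonnegative")
        if self.coverage_ok is None:
            self.coverage_ok = np.ones(self.pixels.shape, dtype=bool)


def project_contour_bev(contour: Contour3D, beam: BeamGeometry) -> Polygon:
    """Silhouette of the solid bounded by a per-slice contour, in BEV mm.

    Built as the union over adjacent slice pairs of the convex hull of
    their projected vertices — exact (to sampling density) for convex
    solids, and a tight cover for the mildly non-convex anatomy here.
    """
    zs = contour.slice_positions
    if not zs:
        raise ValueError("empty contour cannot be projected")
    slice_pts = []
    for z in zs:
        pts = np.vstack(
            [np.column_stack([r, np.full(len(r), z)]) for r in contour.rings[z]]
        )
        slice_pts.append(project_points(pts, beam))
    if len(slice_pts) == 1:
        if len(slice_pts[0]) < 3:
            raise ValueError("degenerate contour: single slice with <3 points")
        hulls = [MultiPoint(slice_pts[0]).convex_hull]
    else:
        hulls = [
            MultiPoint(np.vstack([slice_pts[i], slice_pts[i + 1]])).convex_hull
            for i in range(len(slice_pts) - 1)
        ]
    hulls = [h for h in hulls if isinstance(h, Polygon) and not h.is_empty]
    if not hulls:
        raise ValueError("degenerate contour: projection has no area")
    sil = unary_union(hulls)
    if isinstance(sil, MultiPolygon):
        sil = max(sil.geoms, key=lambda g: g.area)
    return Polygon(sil.exterior)


def hu_to_mu_rel(hu: np.ndarray) -> np.ndarray:
    """Water-relative linear attenuation: max(0, 1 + HU/1000)."""
    return np.clip(1.0 + np.asarray(hu, dtype=float) / 1000.0, 0.0, None)


def compute_drr(
    ct: CTVolume,
    beam: BeamGeometry,
    grid: ImagePlaneGrid,
    step_mm: float | None = None,
    _mu: np.ndarray | None = None,
) -> DRRImage:
    """Ray-cast a DRR: per pixel the line integral of mu_rel (mm of water).

    Trilinear sampling along each source->pixel ray at a step of at most
    half the smallest voxel spacing (or ``step_mm`` if given and smaller).
    """
    mu = hu_to_mu_rel(ct.hu) if _mu is None else _mu
    max_step = min(ct.spacing_mm) / 2.0
    if step_mm is not None:
        max_step = min(max_step, step_mm)

    src = beam.source_mm
    e_u, e_v, _ = beam.basis()
    iso = np.asarray(beam.isocenter_mm)
    uu, vv = grid.meshgrid()
    H, W = grid.shape
    targets = (
        iso[None, :]
        + uu.reshape(-1, 1) * e_u[None, :]
        + vv.reshape(-1, 1) * e_v[None, :]
    )
    dirs = targets - src[None, :]
    lengths = np.linalg.norm(dirs, axis=1)
    dirs = dirs / lengths[:, None]

    # Slab intersection of each ray with the CT bounding box (voxel-centre
    # extents padded by half a voxel).
    x, y, z = ct.voxel_centers()
    lo = np.array([x[0], y[0], z[0]]) - np.asarray(ct.spacing_mm) / 2.0
    hi = np.array([x[-1], y[-1], z[-1]]) + np.asarray(ct.spacing_mm) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo[None, :] - src[None, :]) / dirs
        t2 = (hi[None, :] - src[None, :]) / dirs
    tnear = np.nanmax(np.minimum(t1, t2), axis=1)
    tfar = np.nanmin(np.maximum(t1, t2), axis=1)
    hit = tfar > tnear
    tnear = np.where(hit, tnear, 0.0)
    tfar = np.where(hit, tfar, 0.0)

    seg = tfar - tnear
    n_samples = max(int(np.ceil(seg.max() / max_step)) + 1, 2)
    pix = np.zeros(H * W)
    edge_mu = np.zeros(H * W)
    dx, dy, dz = ct.spacing_mm
    origin = np.array(ct.origin_mm)

    chunk = max(1, int(4e6 // n_samples))
    frac = np.linspace(0.0, 1.0, n_samples)
    for a in range(0, H * W, chunk):
        b = min(a + chunk, H * W)
        ts = tnear[a:b, None] + seg[a:b, None] * frac[None, :]
        pts = src[None, None, :] + dirs[a:b, None, :] * ts[:, :, None]
        idx = np.empty((3,) + ts.shape)
        idx[0] = (pts[:, :, 2] - origin[2]) / dz  # z index
        idx[1] = (pts[:, :, 1] - origin[1]) / dy  # y index
        idx[2] = (pts[:, :, 0] - origin[0]) / dx  # x index
        vals = ndimage.map_coordinates(mu, idx, order=1, mode="constant", cval=0.0)
        dl = seg[a:b] / (n_samples - 1)
        pix[a:b] = np.trapezoid(vals, dx=1.0, axis=1) * dl
        # Edge samples must sit at least half a voxel inside the bounding
        # box: closer to the face the trilinear lookup falls into the zero
        # padding and reads 0 even when anatomy touches the box.
        jr = np.ceil(min(ct.spacing_mm) / 2.0 / np.maximum(dl, 1e-9))
        jr = np.clip(jr, 1, (n_samples - 1) // 2).astype(int)
        near = np.take_along_axis(vals, jr[:, None], axis=1)[:, 0]
        far = np.take_along_axis(vals, (n_samples - 1 - jr)[:, None], axis=1)[:, 0]
        edge_mu[a:b] = np.maximum(near, far)

    # Threshold midway between air and soft tissue: CT noise puts "air"
    # voxels at mu up to ~0.1 (HU sd 20-30), real anatomy at ~1.
    coverage_ok = (edge_mu < 0.3).reshape(H, W)
    return DRRImage(pixels=pix.reshape(H, W), grid=grid, beam=beam, coverage_ok=coverage_ok)


def expand_contour_3d(
    contour: Contour3D,
    margin_mm: float,
    inplane_spacing_mm: float = 2.0,
    pad_mm: float = 15.0,
) -> Contour3D:
    """Isotropic 3D expansion (Minkowski sum with a ball of ``margin_mm``).

    The contour is voxelized on a working grid, the Euclidean distance
    transform of the exterior is thresholded at the margin, and per-slice
    polygons are re-extracted; the output surface is accurate to about
    half a working voxel.
    """
    if margin_mm < 0:
        raise ValueError("margin must be nonnegative")
    zs = contour.slice_positions
    if not zs:
        raise ValueError("cannot expand an empty contour")
    pts = contour.points()
    dz = np.median(np.diff(zs)) if len(zs) > 1 else inplane_spacing_mm
    pad = margin_mm + pad_mm
    x0, x1 = pts[:, 0].min() - pad, pts[:, 0].max() + pad
    y0, y1 = pts[:, 1].min() - pad, pts[:, 1].max() + pad
    s = inplane_spacing_mm
    x = np.arange(x0, x1 + s, s)
    y = np.arange(y0, y1 + s, s)
    n_pad_z = int(np.ceil(pad / dz)) + 1
    z = np.concatenate(
        [
            zs[0] - dz * np.arange(n_pad_z, 0, -1),
            np.arange(zs[0], zs[-1] + dz / 2, dz),
            zs[-1] + dz * np.arange(1, n_pad_z + 1),
        ]
    )
    mask = np.zeros((len(z), len(y), len(x)), dtype=bool)
    for zpos, rings in contour.rings.items():
        k = int(round((zpos - z[0]) / dz))
        if 0 <= k < len(z):
            mask[k] |= rasterize_rings(rings, x, y)
    if not mask.any():
        raise ValueError("contour voxelized to an empty mask")
    dist = ndimage.distance_transform_edt(~mask, sampling=(dz, s, s))
    expanded = dist <= margin_mm
    if (
        expanded[0].any()
        or expanded[-1].any()
        or expanded[:, 0].any()
        or expanded[:, -1].any()
        or expanded[:, :, 0].any()
        or expanded[:, :, -1].any()
    ):
        raise ValueError("margin expansion exceeds the working grid")
    return mask_to_contour(expanded, x, y, z, name=contour.name)
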
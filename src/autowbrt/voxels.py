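"""Conversions between contours and voxel masks.

Rasterization uses pixel-centre membership; contour extraction uses
marching squares at the 0.5 level, so mask -> contour -> mask roundtrips
are stable to within one voxel.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage import measure

from .core import Contour3D, CTVolume

__all__ = [
    "rasterize_rings",
    "contour_to_mask",
    "mask_to_contour",
    "mask_volume_mm3",
]


def rasterize_rings(
    rings: list[np.ndarray], x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Rasterize closed (x, y) rings onto a grid; returns bool (ny, nx).

    Multiple rings are unioned (no hole semantics; the anatomy here has
    none).
    """
    xx, yy = np.meshgrid(x, y)
    out = np.zeros(xx.shape, dtype=bool)
    for ring in rings:
        poly = Polygon(ring)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        out |= shapely.contains_xy(poly, xx, yy)
    return out


def contour_to_mask(contour: Contour3D, ct: CTVolume, tol_mm: float = 0.75) -> np.ndarray:
    """Voxelize a per-slice contour onto a CT grid (bool, indexed [z, y, x]).

    Contour slices are assigned to the nearest grid slice within
    ``tol_mm`` of half the slice spacing.
    """
    x, y, z = ct.voxel_centers()
    dz = ct.spacing_mm[2]
    mask = np.zeros(ct.shape, dtype=bool)
    for zpos, rings in contour.rings.items():
        k = int(round((zpos - z[0]) / dz))
        if k < 0 or k >= len(z) or abs(z[k] - zpos) > dz / 2 + tol_mm:
            continue
        mask[k] |= rasterize_rings(rings, x, y)
    return mask


def mask_to_contour(
    mask: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    name: str = "",
) -> Contour3D:
    """Extract per-slice closed polygons from a 3D bool mask [z, y, x]."""
    rings: dict[float, list[np.ndarray]] = {}
    dx = x[1] - x[0] if len(x) > 1 else 1.0
    dy = y[1] - y[0] if len(y) > 1 else 1.0
    for k in range(mask.shape[0]):
        sl = mask[k]
        if not sl.any():
            continue
        padded = np.pad(sl.astype(float), 1)
        slice_rings = []
        for c in measure.find_contours(padded, 0.5):
            # (row, col) in padded index space -> (x, y) mm
            cx = x[0] + (c[:, 1] - 1) * dx
            cy = y[0] + (c[:, 0] - 1) * dy
            ring = np.column_stack([cx, cy])
            if len(ring) >= 3:
                slice_rings.append(ring)
        if slice_rings:
            rings[float(z[k])] = slice_rings
    return Contour3D(rings=rings, name=name)


def mask_volume_mm3(mask: np.ndarray, spacing_mm) -> float:
    return float(mask.sum()) * float(np.prod(spacing_mm))
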
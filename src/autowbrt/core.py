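"""Core 3D domain types shared across the pipeline.

All 3D coordinates are patient LPS millimetres (x = patient left, y =
posterior, z = superior), matching DICOM.  2D beams-eye-view (BEV) types
live in :mod:`autowbrt.projection` and :mod:`autowbrt.aperture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CTVolume",
    "Contour3D",
    "StructureSet",
    "MLCModel",
    "BeamDefinition",
    "PlanSpec",
]


@dataclass
class CTVolume:
    """A CT scan: Hounsfield units on a regular axis-aligned grid.

    ``hu`` is indexed ``[z, y, x]`` (slice, row, column).  ``origin_mm`` is
    the patient-coordinate position of the centre of voxel ``(0, 0, 0)``
    (i.e. of ``hu[0, 0, 0]``), and ``spacing_mm`` is ``(dx, dy, dz)``.
    """

    hu: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 3 or self.hu.size == 0:
            raise ValueError("CT grid must be a non-empty 3D array")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("CT contains non-finite HU values")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape  # (nz, ny, nx)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1D arrays of x, y, z coordinates of voxel centres (mm)."""
        ox, oy, oz = self.origin_mm
        dx, dy, dz = self.spacing_mm
        nz, ny, nx = self.hu.shape
        return (
            ox + dx * np.arange(nx),
            oy + dy * np.arange(ny),
            oz + dz * np.arange(nz),
        )

    def point_to_index(self, p: Sequence[float]) -> tuple[float, float, float]:
        """Continuous (z, y, x) voxel index of a patient-space point."""
        ox, oy, oz = self.origin_mm
        dx, dy, dz = self.spacing_mm
        return (
            (p[2] - oz) / dz,
            (p[1] - oy) / dy,
            (p[0] - ox) / dx,
        )


@dataclass
class Contour3D:
    """Per-slice closed planar polygons of one structure, in patient mm.

    ``rings`` maps slice z-position (mm) to a list of ``(n, 2)`` arrays of
    (x, y) vertices; each ring is implicitly closed (last vertex joins the
    first) and must be simple.
    """

    rings: dict[float, list[np.ndarray]]
    name: str = ""

    def __post_init__(self) -> None:
        for z, polys in self.rings.items():
            for ring in polys:
                if ring.ndim != 2 or ring.shape[1] != 2 or ring.shape[0] < 3:
                    raise ValueError(
                        f"contour {self.name!r} at z={z}: rings need >=3 2D vertices"
                    )

    @property
    def slice_positions(self) -> list[float]:
        return sorted(self.rings)

    def is_empty(self) -> bool:
        return not self.rings

    def points(self) -> np.ndarray:
        """All vertices as an ``(n, 3)`` array of (x, y, z)."""
        out = []
        for z in self.slice_positions:
            for ring in self.rings[z]:
                out.append(np.column_stack([ring, np.full(len(ring), z)]))
        if not out:
            return np.empty((0, 3))
        return np.vstack(out)


@dataclass
class StructureSet:
    """Named contours sharing a frame of reference."""

    structures: dict[str, Contour3D]
    frame_of_reference: str = ""

    def __getitem__(self, name: str) -> Contour3D:
        if name not in self.structures:
            raise KeyError(
                f"structure {name!r} not present; available: {sorted(self.structures)}"
            )
        return self.structures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    def names(self) -> list[str]:
        return sorted(self.structures)

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.structures]
        if missing:
            raise KeyError(f"missing required structure(s): {missing}")


@dataclass(frozen=True)
class MLCModel:
    """Multileaf-collimator geometry at the isocenter plane.

    Leaf rows run along the BEV u-axis and are stacked along v, centred on
    v = 0: row ``k`` spans ``v in [v0 + k*w, v0 + (k+1)*w)`` with
    ``v0 = -n_pairs * w / 2``.  The default 60 pairs x 5 mm is a common
    clinical configuration.
    """

    n_pairs: int = 60
    leaf_width_mm: float = 5.0
    travel_limit_mm: float = 200.0

    def __post_init__(self) -> None:
        if self.n_pairs <= 0 or self.leaf_width_mm <= 0 or self.travel_limit_mm <= 0:
            raise ValueError("MLC geometry parameters must be positive")

    @property
    def v_min(self) -> float:
        return -self.n_pairs * self.leaf_width_mm / 2.0

    def row_edges(self) -> np.ndarray:
        """v-coordinates of the n_pairs + 1 leaf-row boundaries."""
        return self.v_min + self.leaf_width_mm * np.arange(self.n_pairs + 1)

    def row_of_v(self, v: np.ndarray) -> np.ndarray:
        """Leaf-row index of each v (may fall outside [0, n_pairs))."""
        return np.floor((np.asarray(v) - self.v_min) / self.leaf_width_mm).astype(int)


@dataclass
class BeamDefinition:
    """A static treatment beam: geometry, collimation and weight."""

    gantry_deg: float
    isocenter_mm: tuple[float, float, float]
    jaws_mm: tuple[float, float, float, float]  # (x1, x2, y1, y2) at isocenter
    mlc: MLCModel | None = None
    leaf_positions_mm: np.ndarray | None = None  # (n_pairs, 2) of (left, right)
    weight: float = 1.0
    sad_mm: float = 1000.0
    energy_label: str = "6MV"
    machine_label: str = "generic-linac"
    name: str = ""
    jaw_only: bool = False

    def __post_init__(self) -> None:
        x1, x2, y1, y2 = self.jaws_mm
        if not (x1 < x2 and y1 < y2):
            raise ValueError("jaws must satisfy x1 < x2 and y1 < y2")
        if not np.isfinite(self.weight) or self.weight < 0:
            raise ValueError("beam weight must be finite and nonnegative")
        if not (0.0 <= self.gantry_deg < 360.0):
            raise ValueError("gantry angle must lie in [0, 360)")
        if self.leaf_positions_mm is not None:
            lp = np.asarray(self.leaf_positions_mm, dtype=float)
            if self.mlc is not None and lp.shape != (self.mlc.n_pairs, 2):
                raise ValueError("leaf positions shape must be (n_pairs, 2)")
            if np.any(lp[:, 0] > lp[:, 1] + 1e-9):
                raise ValueError("each leaf pair must satisfy left <= right")
            self.leaf_positions_mm = lp


@dataclass
class PlanSpec:
    """A lateral-opposed whole-brain plan: two equal-weight beams.

    The clinical convention for this technique is gantry 270 (right
    lateral) and 90 (left lateral), equal weights summing to 1, with the
    prescription normalized to 100% at the marked isocenter.
    """

    beams: list[BeamDefinition]
    prescription_gy: float = 30.0
    n_fractions: int = 10
    normalization_point_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    machine_label: str = "generic-linac"
    energy_label: str = "6MV"
    apertures: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.beams) != 2:
            raise ValueError("a lateral-opposed plan has exactly two beams")
        gantries = sorted(b.gantry_deg for b in self.beams)
        if gantries != [90.0, 270.0]:
            raise ValueError("beams must be at gantry 270 and 90 degrees")
        w = [b.weight for b in self.beams]
        if abs(w[0] - w[1]) > 1e-9 or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("beam weights must be equal and sum to 1")
        if self.prescription_gy <= 0 or self.n_fractions <= 0:
            raise ValueError("prescription must be positive")
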
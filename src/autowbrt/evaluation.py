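"""Quantitative aperture evaluation.

Predicted and reference fields are compared along the *shielded* field
edge — the part of the aperture boundary lying inside the projected body
(the curved anterior-inferior edge plus the inferior border), excluding
everything attributable to skin flash — using the directed mean surface
distance, the Hausdorff distance, and the inferior-border offset at the
chosen vertebral interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiLineString, Polygon

from .aperture import FieldAperture

__all__ = [
    "EdgeCurve",
    "EdgeMetrics",
    "extract_anterior_inferior_edge",
    "mean_surface_distance",
    "hausdorff_distance",
    "inferior_border_offset",
    "evaluate_cohort",
]


@dataclass
class EdgeCurve:
    """Ordered polyline(s) along a shielded field edge, in BEV mm.

    ``runs`` are maximal contiguous boundary arcs (usually one); points
    within each run are spaced at most one pixel apart.
    """

    runs: list[np.ndarray]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.runs or sum(len(r) for r in self.runs) < 2:
            raise ValueError("edge curve needs at least two points")

    @property
    def points(self) -> np.ndarray:
        return np.vstack(self.runs)

    def as_lines(self) -> MultiLineString:
        lines = [LineString(r) for r in self.runs if len(r) >= 2]
        if not lines:
            # single-point runs only: degenerate, represent as tiny segments
            p = self.points
            lines = [LineString([p[0], p[0] + 1e-9])]
        return MultiLineString(lines)


@dataclass(frozen=True)
class EdgeMetrics:
    """Edge-agreement metrics for one predicted/reference field pair."""

    msd_mm: float  # directed, predicted -> reference
    msd_sym_mm: float
    hd_mm: float  # symmetric Hausdorff
    hd_directed_mm: float
    inferior_offset_mm: float
    case_id: str = ""
    beam_side: str = ""

    def __post_init__(self) -> None:
        vals = (self.msd_mm, self.msd_sym_mm, self.hd_mm, self.hd_directed_mm,
                self.inferior_offset_mm)
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ValueError("edge metrics must be finite and nonnegative")
        if self.hd_mm < self.msd_sym_mm - 1e-9:
            raise ValueError("Hausdorff distance cannot be below the symmetric MSD")


def _resample(run: np.ndarray, max_spacing: float) -> np.ndarray:
    out = [run[0]]
    for a, b in zip(run[:-1], run[1:]):
        seg = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(seg / max_spacing)))
        for k in range(1, n + 1):
            out.append(a + (b - a) * k / n)
    return np.asarray(out)


def extract_anterior_inferior_edge(
    aperture: FieldAperture,
    body_projection: Polygon,
    flash_mm: float | None = None,
) -> EdgeCurve:
    """The shielded part of the aperture boundary, ordered and resampled.

    Boundary points are kept iff they lie inside the projected body by
    more than one pixel — which excludes the skin-flash arcs (outside or
    on the body) and keeps the blocked anterior/inferior edge.  Runs are
    ordered from the anterior-most endpoint toward the posterior end of
    the inferior border and resampled at <= 1 pixel spacing.
    """
    poly = aperture.polygon
    if poly.is_empty:
        raise ValueError("empty aperture has no edge")
    s = aperture.grid.pixel_spacing_mm
    # Densify: exact polygons carry straight segments with endpoint-only
    # vertices; the keep-filter below is pointwise and needs <= 1 px spacing.
    ext = shapely.segmentize(LineString(poly.exterior.coords), s)
    pts = np.asarray(ext.coords)[:-1]  # drop closing duplicate
    inside = shapely.contains_xy(body_projection, pts[:, 0], pts[:, 1])
    depth = shapely.distance(
        shapely.points(pts), LineString(body_projection.exterior.coords)
    )
    keep = inside & (depth > s)
    if not keep.any():
        raise ValueError("no shielded edge: aperture follows body + flash everywhere")

    # Maximal contiguous runs along the closed boundary (with wraparound).
    n = len(pts)
    if keep.all():
        runs_idx = [np.arange(n)]
    else:
        start = int(np.argmin(keep))  # a removed point
        order = (np.arange(n) + start) % n
        runs_idx = []
        current: list[int] = []
        for i in order:
            if keep[i]:
                current.append(i)
            elif current:
                runs_idx.append(np.array(current))
                current = []
        if current:
            runs_idx.append(np.array(current))
    runs = [_resample(pts[idx], s) for idx in runs_idx if len(idx) >= 2]
    if not runs:
        raise ValueError("no shielded edge: kept boundary arcs are degenerate")
    # Orient: anterior-most endpoint first.
    ends = [(r[0], r[-1]) for r in runs]
    if max(e[0][0] for e in ends) < max(e[1][0] for e in ends):
        runs = [r[::-1] for r in reversed(runs)]
    return EdgeCurve(
        runs=runs,
        provenance=f"{aperture.technique}/{aperture.extent}/"
        f"{aperture.beam_side or 'unknown-side'}: shielded boundary",
    )


def _directed(edge_a: EdgeCurve, edge_b: EdgeCurve) -> np.ndarray:
    """Min point-to-polyline distances from a's points to b."""
    target = edge_b.as_lines()
    return shapely.distance(shapely.points(edge_a.points), target)


def mean_surface_distance(
    edge_a: EdgeCurve, edge_b: EdgeCurve, mode: str = "directed"
) -> float:
    """Mean of closest point-to-polyline distances (point-to-segment)."""
    d_ab = float(_directed(edge_a, edge_b).mean())
    if mode == "directed":
        return d_ab
    if mode == "symmetric":
        d_ba = float(_directed(edge_b, edge_a).mean())
        return 0.5 * (d_ab + d_ba)
    raise ValueError(f"unknown mode {mode!r}")


def hausdorff_distance(
    edge_a: EdgeCurve, edge_b: EdgeCurve, mode: str = "symmetric"
) -> float:
    """Max of closest point-to-polyline distances."""
    d_ab = float(_directed(edge_a, edge_b).max())
    if mode == "directed":
        return d_ab
    if mode == "symmetric":
        d_ba = float(_directed(edge_b, edge_a).max())
        return max(d_ab, d_ba)
    raise ValueError(f"unknown mode {mode!r}")


def _border_v(aperture: FieldAperture) -> tuple[float, bool]:
    """Inferior-border v: median v of the lowest-pixel band, posterior half."""
    poly = aperture.polygon
    if poly.is_empty:
        raise ValueError("empty aperture")
    s = aperture.grid.pixel_spacing_mm
    pts = np.asarray(poly.exterior.coords)[:-1]
    u_mid = 0.5 * (pts[:, 0].min() + pts[:, 0].max())
    post = pts[pts[:, 0] <= u_mid]
    if len(post) == 0:
        return float(pts[:, 1].min()), True
    v_min = post[:, 1].min()
    band = post[post[:, 1] <= v_min + s]
    if len(band) < 3 or band[:, 0].max() - band[:, 0].min() < 3 * s:
        return float(pts[:, 1].min()), True  # no horizontal segment: fall back
    return float(np.median(band[:, 1])), False


def inferior_border_offset(pred: FieldAperture, ref: FieldAperture) -> float:
    """|v_pred - v_ref| of the two fields' inferior borders (mm)."""
    vp, _ = _border_v(pred)
    vr, _ = _border_v(ref)
    return abs(vp - vr)


def evaluate_cohort(pairs) -> dict:
    """Edge metrics for (pred, ref, body_projection, flash_mm) pairs.

    Returns ``{"per_case": DataFrame, "summary": {metric: {mean, sd}}}``;
    per-case failures become row-level ``error`` entries instead of
    aborting the cohort.  The sd is the sample standard deviation (n-1),
    reported as 0 for a single case.
    """
    if not pairs:
        raise ValueError("need at least one (pred, ref) pair")
    rows = []
    for pred, ref, body, flash_mm in pairs:
        row = {"case_id": pred.meta.get("case_id", ""), "beam_side": pred.beam_side}
        try:
            e_pred = extract_anterior_inferior_edge(pred, body, flash_mm)
            e_ref = extract_anterior_inferior_edge(ref, body, flash_mm)
            row.update(
                msd_mm=mean_surface_distance(e_pred, e_ref, "directed"),
                msd_sym_mm=mean_surface_distance(e_pred, e_ref, "symmetric"),
                hd_mm=hausdorff_distance(e_pred, e_ref, "symmetric"),
                hd_directed_mm=hausdorff_distance(e_pred, e_ref, "directed"),
                inferior_offset_mm=inferior_border_offset(pred, ref),
                error="",
            )
        except (ValueError, KeyError) as exc:
            row.update(error=str(exc))
        rows.append(row)
    per_case = pd.DataFrame(rows)
    metrics = ["msd_mm", "msd_sym_mm", "hd_mm", "hd_directed_mm", "inferior_offset_mm"]
    summary = {}
    for m in metrics:
        if m in per_case:
            vals = per_case[m].dropna()
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            summary[m] = {"mean": float(vals.mean()), "sd": sd, "n": int(len(vals))}
    return {"per_case": per_case, "summary": summary}
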
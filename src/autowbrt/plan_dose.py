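"""Lateral-opposed plan assembly, toy dose and DVH metrics.

The dose engine here is an explicitly labeled *toy* model — primary
exponential attenuation of each beam inside its divergent aperture cone,
with no scatter, penumbra or heterogeneity correction — whose only
purpose is to make the plan-evaluation pipeline executable and testable
end to end.  Its numbers are not clinical dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .aperture import FieldAperture, mask_to_mlc, mlc_to_mask
from .core import BeamDefinition, CTVolume, MLCModel, PlanSpec
from .projection import BeamGeometry, ImagePlaneGrid, hu_to_mu_rel

__all__ = [
    "DoseGrid",
    "DVHMetric",
    "build_plan",
    "compute_toy_dose",
    "dvh_metric",
    "dvh_report",
]

TOY_MU_EFF_PER_MM = 0.005  # effective attenuation of the toy beam model

GANTRY_BY_SIDE = {"right-lateral": 270.0, "left-lateral": 90.0}


@dataclass
class DoseGrid:
    """Dose in percent of prescription on the CT grid (100 = Rx at norm point)."""

    dose: np.ndarray
    ct: CTVolume

    def __post_init__(self) -> None:
        if self.dose.shape != self.ct.shape:
            raise ValueError("dose grid must match the CT grid")
        if np.any(self.dose < 0) or not np.all(np.isfinite(self.dose)):
            raise ValueError("dose must be finite and nonnegative")


@dataclass(frozen=True)
class DVHMetric:
    structure: str
    metric: str  # "D99%", "D95%", "D1%" or "mean"
    value_gy: float


def build_plan(
    case,
    apertures: dict[str, FieldAperture],
    prescription_gy: float = 30.0,
    n_fractions: int = 10,
    isocenter_mm=None,
    mlc: MLCModel | None = None,
    machine_label: str = "generic-linac",
    energy_label: str = "6MV",
) -> PlanSpec:
    """Assemble the two-beam lateral-opposed plan from per-side apertures.

    Beams sit at gantry 270 (right lateral) and 90 (left lateral) with
    weight 0.5 each; MLC leaves and jaws are fitted to each aperture.
    """
    if set(apertures) != {"left-lateral", "right-lateral"}:
        raise ValueError("need exactly one aperture per lateral beam side")
    if prescription_gy <= 0 or n_fractions <= 0:
        raise ValueError("prescription must be positive")
    iso = tuple(isocenter_mm if isocenter_mm is not None else case.isocenter_mm)
    mlc = mlc or MLCModel()
    beams = []
    for side in ("right-lateral", "left-lateral"):
        jaws, leaves = mask_to_mlc(apertures[side], mlc)
        beams.append(
            BeamDefinition(
                gantry_deg=GANTRY_BY_SIDE[side],
                isocenter_mm=iso,
                jaws_mm=jaws,
                mlc=mlc,
                leaf_positions_mm=leaves,
                weight=0.5,
                energy_label=energy_label,
                machine_label=machine_label,
                name=side,
            )
        )
    return PlanSpec(
        beams=beams,
        prescription_gy=prescription_gy,
        n_fractions=n_fractions,
        normalization_point_mm=iso,
        machine_label=machine_label,
        energy_label=energy_label,
        apertures=dict(apertures),
    )


def compute_toy_dose(
    plan: PlanSpec,
    ct: CTVolume,
    mu_eff_per_mm: float = TOY_MU_EFF_PER_MM,
    body_mask: np.ndarray | None = None,
) -> DoseGrid:
    """Toy dose: weighted sum over beams of exp(-mu_eff * WED) in the cone.

    Water-equivalent depth (WED) is accumulated along the beam axis; the
    divergent aperture cone is evaluated by perspective-projecting each
    voxel to the BEV and sampling the beam's aperture mask (binary
    transmission).  The result is normalized to 100% at the plan's
    normalization point, which must receive dose from the open fields.
    """
    mu = hu_to_mu_rel(ct.hu)
    x, y, z = ct.voxel_centers()
    dx = ct.spacing_mm[0]
    total = np.zeros(ct.shape)
    for beam in plan.beams:
        side = beam.name or {270.0: "right-lateral", 90.0: "left-lateral"}[beam.gantry_deg]
        if side in plan.apertures:
            ap_mask = plan.apertures[side].mask
        else:
            # Plans read back from disk carry no raster apertures; rebuild
            # one from the beam's jaw/MLC collimation on a default grid.
            ap_mask = mlc_to_mask(beam, ImagePlaneGrid())
        geom = BeamGeometry(
            gantry_deg=beam.gantry_deg,
            isocenter_mm=beam.isocenter_mm,
            sad_mm=beam.sad_mm,
        )
        # Radiological depth along the beam axis (+-x for lateral beams),
        # midpoint-accumulated per voxel column.
        if beam.gantry_deg == 90.0:  # source on patient left (+x): integrate right-to-left
            cs = np.cumsum(mu[:, :, ::-1], axis=2)[:, :, ::-1] * dx
            wed = cs - mu * dx / 2.0
        elif beam.gantry_deg == 270.0:
            cs = np.cumsum(mu, axis=2) * dx
            wed = cs - mu * dx / 2.0
        else:
            raise ValueError("toy dose engine supports lateral beams only")
        fluence = np.exp(-mu_eff_per_mm * np.clip(wed, 0.0, None))

        # Divergence-aware cone test: project voxel centres to the BEV and
        # sample the aperture raster (nearest pixel).
        e_u, e_v, s_hat = geom.basis()
        iso = np.asarray(beam.isocenter_mm)
        xx = (x - iso[0])[None, None, :]
        yy = (y - iso[1])[None, :, None]
        zz = (z - iso[2])[:, None, None]
        d = xx * s_hat[0] + yy * s_hat[1] + zz * s_hat[2]
        scale = beam.sad_mm / (beam.sad_mm - d)
        u = (xx * e_u[0] + yy * e_u[1] + zz * e_u[2]) * scale
        v = (xx * e_v[0] + yy * e_v[1] + zz * e_v[2]) * scale
        grid = ap_mask.grid
        row, col = grid.uv_to_pixel(u, v)
        inside = ndimage.map_coordinates(
            ap_mask.pixels.astype(float),
            np.stack([row, col]),
            order=0,
            mode="constant",
            cval=0.0,
        ).astype(bool)
        total += beam.weight * fluence * inside

    iso_idx = tuple(int(round(i)) for i in ct.point_to_index(plan.normalization_point_mm))
    if not all(0 <= i < s for i, s in zip(iso_idx, ct.shape)):
        raise ValueError("normalization point lies outside the CT grid")
    iso_dose = total[iso_idx]
    if iso_dose <= 0:
        raise ValueError("normalization point receives no dose (outside the fields?)")
    return DoseGrid(dose=total * (100.0 / iso_dose), ct=ct)


def dvh_metric(
    dose: DoseGrid,
    structure_mask: np.ndarray,
    metric: str,
    prescription_gy: float,
) -> DVHMetric:
    """Dx% (lower-interpolation percentile) or mean dose of a structure, in Gy.

    Dx% is the largest dose d such that at least x% of the structure's
    voxels receive >= d, i.e. the (100 - x)th percentile with lower
    interpolation; values are scaled from percent-of-prescription.
    """
    m = np.asarray(structure_mask, dtype=bool)
    if m.shape != dose.dose.shape:
        raise ValueError("structure mask must match the dose grid")
    if not m.any():
        raise ValueError("empty structure mask")
    vals = dose.dose[m]
    if metric == "mean":
        pct = float(vals.mean())
        name = "mean"
    else:
        if not (metric.startswith("D") and metric.endswith("%")):
            raise ValueError(f"unknown DVH metric {metric!r}")
        xq = float(metric[1:-1])
        if not 0 < xq <= 100:
            raise ValueError("Dx% requires 0 < x <= 100")
        pct = float(np.percentile(vals, 100.0 - xq, method="lower"))
        name = metric
    return DVHMetric(structure="", metric=name, value_gy=pct / 100.0 * prescription_gy)


def dvh_report(
    dose: DoseGrid,
    structure_masks: dict[str, np.ndarray],
    prescription_gy: float,
    spec: dict[str, list[str]] | None = None,
) -> list[DVHMetric]:
    """Standard whole-brain plan metrics: brain D99/D95/D1 and mean lens dose."""
    if spec is None:
        spec = {
            "brain": ["D99%", "D95%", "D1%"],
            "lens_l": ["mean"],
            "lens_r": ["mean"],
        }
    out = []
    for struct, metrics in spec.items():
        for metric in metrics:
            m = dvh_metric(dose, structure_masks[struct], metric, prescription_gy)
            out.append(DVHMetric(structure=struct, metric=m.metric, value_gy=m.value_gy))
    return out
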
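"""End-to-end orchestration used by the CLI, examples and evaluation runs.

Wires the stages together: cohort generation -> DRR/label dataset ->
model training -> per-case field building -> plan + toy dose -> DVH and
aperture-edge reports.  Everything here is a thin composition of the
module-level operations; no numerics of its own.
"""

from __future__ import annotations

import numpy as np

from .aperture import FieldAperture
from .evaluation import evaluate_cohort
from .field_builder import (
    FieldRequest,
    build_scalp_sparing_field,
    build_traditional_field,
    compute_vertebral_landmarks,
)
from .phantom import PhantomCase, generate_cohort
from .plan_dose import build_plan, compute_toy_dose, dvh_report
from .projection import compute_drr, project_contour_bev
from .segmentation import (
    ModelState,
    examples_from_cases,
    hard_dice,
    predict_aperture,
    split_dataset,
    train_model,
)
from .voxels import contour_to_mask

__all__ = [
    "structure_mask",
    "build_fields_for_case",
    "plan_case",
    "train_on_cohort",
    "run_end2end",
]


def structure_mask(case: PhantomCase, name: str) -> np.ndarray:
    """Voxel mask of a named structure on the case's CT grid."""
    if case.masks and name in case.masks:
        return case.masks[name]
    return contour_to_mask(case.structures[name], case.ct)


def build_fields_for_case(
    case: PhantomCase,
    model: ModelState,
    request: FieldRequest,
    sides=("left-lateral", "right-lateral"),
) -> dict[str, FieldAperture]:
    """Predict and assemble the requested field option for each lateral beam."""
    landmarks = compute_vertebral_landmarks(case.structures, case.ct)
    fields: dict[str, FieldAperture] = {}
    for side in sides:
        beam = case.beam(side)
        body = project_contour_bev(case.structures["body"], beam)
        drr = compute_drr(case.ct, beam, case.bev_grid)
        pred = predict_aperture(model, drr, body)
        trad = build_traditional_field(pred, body, landmarks, request, beam, side)
        trad.meta["case_id"] = case.case_id
        if request.technique == "scalp_sparing":
            field = build_scalp_sparing_field(
                trad, case.structures["brain"], beam, landmarks, request
            )
            field.meta["case_id"] = case.case_id
        else:
            field = trad
        fields[side] = field
    return fields


def plan_case(
    case: PhantomCase,
    fields: dict[str, FieldAperture],
    prescription_gy: float = 30.0,
    n_fractions: int = 10,
):
    """Build the lateral-opposed plan, compute toy dose and DVH metrics."""
    plan = build_plan(
        case, fields, prescription_gy=prescription_gy, n_fractions=n_fractions
    )
    dose = compute_toy_dose(plan, case.ct)
    masks = {n: structure_mask(case, n) for n in ("brain", "lens_l", "lens_r")}
    metrics = dvh_report(dose, masks, prescription_gy)
    return plan, dose, metrics


def train_on_cohort(
    cases: list[PhantomCase],
    ratios=(0.6, 0.2, 0.2),
    seed: int = 0,
    config: dict | None = None,
):
    """Split a cohort, train the segmentation model, return model + split."""
    split = split_dataset([c.case_id for c in cases], ratios, seed)
    by_id = {c.case_id: c for c in cases}
    train_ex = examples_from_cases([by_id[i] for i in split.train_ids])
    cv_ex = examples_from_cases([by_id[i] for i in split.cv_ids])
    model = train_model(train_ex, cv_ex, config, seed=seed)
    return model, split


def run_end2end(
    n_cases: int = 8,
    seed: int = 3,
    technique: str = "traditional",
    train_config: dict | None = None,
    prescription_gy: float = 30.0,
    n_fractions: int = 10,
) -> dict:
    """Cohort -> train -> predict -> fields -> plan -> dose -> DVH -> evaluate.

    Test-set fields are built at each case's clinical extent and compared
    against that case's reference aperture; returns a result dict with the
    model, the edge-metric report and per-case DVH tables.
    """
    cases = generate_cohort(n_cases, seed=seed)
    model, split = train_on_cohort(cases, seed=seed, config=train_config)
    by_id = {c.case_id: c for c in cases}
    eval_ids = split.test_ids if split.test_ids else [c.case_id for c in cases]

    pairs = []
    dvh_rows = []
    test_dice = []
    for cid in eval_ids:
        case = by_id[cid]
        request = FieldRequest(technique=technique, extent=case.clinical_extent)
        fields = build_fields_for_case(case, model, request)
        for side, field in fields.items():
            beam = case.beam(side)
            body = project_contour_bev(case.structures["body"], beam)
            ref = case.reference_apertures[(side, case.clinical_extent)]
            ref.meta.setdefault("case_id", cid)
            pairs.append((field, ref, body, request.flash_mm))
            test_dice.append(hard_dice(field.mask.pixels, ref.mask.pixels))
        _, _, metrics = plan_case(
            case, fields, prescription_gy=prescription_gy, n_fractions=n_fractions
        )
        for m in metrics:
            dvh_rows.append(
                {"case_id": cid, "structure": m.structure, "metric": m.metric,
                 "value_gy": m.value_gy}
            )
    report = evaluate_cohort(pairs)
    return {
        "model": model,
        "split": split,
        "cases": cases,
        "edge_report": report,
        "dvh": dvh_rows,
        "test_field_dice": test_dice,
    }
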
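# autowbrt

Automated field definition and planning for whole-brain radiotherapy (WBRT),
exercised end-to-end on synthetic head phantoms.

## What it does

WBRT is delivered with two opposed lateral photon beams; the planning work is
essentially drawing one beam's-eye-view (BEV) aperture: open over the brain
and skull, caudal border at a cervical vertebral landmark, skin flash outside
the patient surface, and an eye shield whose anterior edge keeps the lenses
out of the field. `autowbrt` automates that chain:

1. **Synthetic phantoms** — seeded, parametric head-and-neck CTs with skull,
   brain, eyes (lenses, bony orbital rims), C1–C3 vertebrae, plus exact
   reference apertures used as labels and ground truth.
2. **Projection / DRR** — shared BEV convention for both laterals
   (u = anterior, v = superior, SAD 1000 mm), ray-cast water-equivalent
   path-length DRRs with a per-pixel coverage flag.
3. **Aperture segmentation** — a small trainable per-pixel model
   (multiscale context features + MLP) mapping the lateral DRR to the open
   field, with seeded train/cross-validation/test cohort splits.
4. **Field construction rules** — caudal border at the C1/C2 or C2/C3
   interspace midpoint, body clipping, exactly-10 mm skin flash on
   anterior/posterior/cranial sides only, optional scalp-sparing trim to
   brain + 5 mm.
5. **Plan & dose** — single-level MLC fit (fit-to-enclose), two equal-weight
   opposed beams (gantry 270°/90°), 30 Gy / 10 fractions, a toy
   exponential-attenuation dose engine normalized to 100% at the brain
   centroid, DVH metrics (brain D99%/D95%/D1%, mean lens dose).
6. **Evaluation** — distances between predicted and reference *shielded
   edges* (the aperture boundary inside the body outline): directed and
   symmetric mean surface distance, Hausdorff distance, inferior border
   offset.
7. **I/O & CLI** — DICOM CT / RT-STRUCT / RT-PLAN round-trips, PNG + sidecar
   images, `.npz` case bundles, and an `autowbrt` command-line pipeline that
   writes a JSON run manifest next to every artifact.

See [docs/methods.md](docs/methods.md) for the full model, parameters and
limitations. The dose engine is deliberately simple — DVH numbers are
internally consistent, not clinical.

## Worked example

Build lateral-opposed fields from a known aperture, plan, and compute dose
(`examples/03_fields_plan_and_dose.py`):

```python
from autowbrt import (
    FieldRequest, PhantomSpec, build_plan, build_traditional_field,
    compute_toy_dose, dvh_report, generate_phantom, project_contour_bev,
)
from autowbrt.field_builder import compute_vertebral_landmarks
from autowbrt.pipeline import structure_mask

case = generate_phantom(PhantomSpec(seed=42))
landmarks = compute_vertebral_landmarks(case.structures, case.ct)
request = FieldRequest(extent=case.clinical_extent)

fields = {}
for side in ("left-lateral", "right-lateral"):
    beam = case.beam(side)
    body = project_contour_bev(case.structures["body"], beam)
    ref = case.reference_apertures[(side, case.clinical_extent)]
    fields[side] = build_traditional_field(
        ref.mask, body, landmarks, request, beam, side
    )

plan = build_plan(case, fields)
dose = compute_toy_dose(plan, case.ct)
masks = {n: structure_mask(case, n) for n in ("brain", "lens_l", "lens_r")}
for m in dvh_report(dose, masks, prescription_gy=30.0):
    print(f"{m.structure:8s} {m.metric:5s} = {m.value_gy:5.1f} Gy")
```

Output:

```
left-lateral: inferior border at v = -129.0 mm, flash applied: True
right-lateral: inferior border at v = -129.0 mm, flash applied: True
beam right-lateral: gantry 270 deg, weight 0.5, jaws x [-102, 106] mm
beam left-lateral: gantry 90 deg, weight 0.5, jaws x [-102, 106] mm
dose at isocenter: 100.0% (normalization point)
brain    D99%  =  29.7 Gy
brain    D95%  =  30.0 Gy
brain    D1%   =  34.2 Gy
lens_l   mean  =   0.0 Gy
lens_r   mean  =   0.0 Gy
```

The lens means are zero because the eye shield is swept to the anterior
field edge, which keeps the shape deliverable by a single-level MLC.

The other examples walk through the phantom (`01`), projection geometry and
DRRs (`02`), the full learning loop on a small cohort (`04`), and the same
pipeline as CLI commands (`05_cli_workflow.sh`).

## Command line

```bash
autowbrt cohort --n 6 --seed 7 --out cohort/
autowbrt train --cohort cohort/ --seed 7 --out model.npz
autowbrt phantom --seed 99 --out case.npz
autowbrt build-fields --case case.npz --model model.npz --out fields/
autowbrt build-plan --case case.npz --fields fields/ --out plan.dcm
autowbrt dose --case case.npz --plan plan.dcm --out dose.npz
autowbrt dvh --case case.npz --dose dose.npz --out dvh.json
autowbrt end2end --n 8 --seed 3 --out run/     # everything in one command
```

Exit codes: 0 success, 1 pipeline error (stderr names the failing stage),
2 invalid configuration.

## Repository layout

```
src/autowbrt/     package (phantom, projection, aperture, segmentation,
                  field_builder, plan_dose, evaluation, rt_io, pipeline, cli)
tests/            unit + acceptance suites (oracle-based where possible)
examples/         short narrative scripts, one per capability
scripts/          acceptance.py — recompute headline results as JSON
docs/methods.md   model, parameters, numerical choices, limitations
```
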
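"""Train the aperture model on a small cohort and score the held-out cases.

Runs the full learning loop on 10 phantoms (6 train / 2 cross-validation /
2 test): DRR + reference-aperture examples, pixel-MLP training with
best-by-cv-Dice checkpointing, then field construction on the test cases
and edge-distance evaluation against each case's reference field.
Takes about a minute; scale n_cases up for tighter statistics.
"""

import numpy as np

from autowbrt.pipeline import run_end2end

result = run_end2end(n_cases=10, seed=7)

split = result["split"]
print(f"split: {len(split.train_ids)} train / {len(split.cv_ids)} cv / "
      f"{len(split.test_ids)} test")

best_cv = max(e["cv_dice"] for e in result["model"].log
              if np.isfinite(e["cv_dice"]))
print(f"best cross-validation Dice during training: {best_cv:.3f}")

dice = result["test_field_dice"]
print(f"built field vs reference field Dice on test beams: "
      f"mean {np.mean(dice):.3f} (n={len(dice)})")

summary = result["edge_report"]["summary"]
msd = summary["msd_mm"]
print(f"shielded-edge distance, predicted -> reference: "
      f"{msd['mean']:.2f} +/- {msd['sd']:.2f} mm (n={msd['n']})")
print(f"inferior border offset: "
      f"{summary['inferior_offset_mm']['mean']:.2f} mm mean")

brain_d95 = [r["value_gy"] for r in result["dvh"]
             if r["structure"] == "brain" and r["metric"] == "D95%"]
print(f"brain D95% on test cases: {np.mean(brain_d95):.1f} Gy mean "
      "(toy dose engine, 30 Gy prescription)")
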
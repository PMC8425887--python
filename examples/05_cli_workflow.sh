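#!/usr/bin/env bash
# The same pipeline as a sequence of CLI commands with file artifacts.
# Each command writes a JSON run manifest next to its output.
set -euo pipefail

out=$(mktemp -d)
echo "working in $out"

# 1. a small cohort of synthetic cases (one .npz bundle per case)
autowbrt cohort --n 6 --seed 7 --out "$out/cohort"

# 2. train the aperture segmentation model on it
autowbrt train --cohort "$out/cohort" --seed 7 --out "$out/model.npz"

# 3. one fresh case, its lateral DRR, predicted fields, plan and dose
autowbrt phantom --seed 99 --out "$out/case.npz"
autowbrt drr --case "$out/case.npz" --side left-lateral --out "$out/drr.png"
autowbrt build-fields --case "$out/case.npz" --model "$out/model.npz" \
    --out "$out/fields"
autowbrt build-plan --case "$out/case.npz" --fields "$out/fields" \
    --out "$out/plan.dcm"
autowbrt dose --case "$out/case.npz" --plan "$out/plan.dcm" \
    --out "$out/dose.npz"
autowbrt dvh --case "$out/case.npz" --dose "$out/dose.npz" \
    --out "$out/dvh.json"

# 4. cohort-level evaluation of the trained model
autowbrt evaluate --cohort "$out/cohort" --model "$out/model.npz" \
    --out "$out/eval"

echo "artifacts:"
ls "$out"
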
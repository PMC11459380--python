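#!/usr/bin/env bash
# Full pipeline from the shell: simulate a branching ensemble, test its
# branch arm for directionality, scan start points, score features, plot.
set -euo pipefail

trajdir simulate --model branching --seed 1 --n-cells-per-arm 200 \
    --out-dir out/sim

trajdir analyse --attributes out/sim/attributes.csv \
    --pseudotime out/sim/pseudotime.csv \
    --method bySteps --n-samples 50 --n-null 99 --seed 2 \
    --out-dir out/analysis

trajdir branch-scan --attributes out/sim/attributes.csv \
    --pseudotime out/sim/pseudotime.csv \
    --method bySteps --n-samples 50 --n-null 99 --seed 2 \
    --start-fractions 0:0.5:0.1 --out-dir out/scan

trajdir gene-scores --results out/analysis/results.json --k 3 \
    --out-dir out/genes

trajdir plot --results out/analysis/results.json \
    --scan out/scan/results.json --out-dir out/plots
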
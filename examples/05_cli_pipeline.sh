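#!/usr/bin/env bash
# The same pipeline from the shell: simulate -> train -> predict -> evaluate.
# Writes everything under ./scratch-example (safe to delete).
set -euo pipefail

out=scratch-example
mkdir -p "$out"

phosfx simulate --seed 7 --out "$out/data" --n-proteins 60 --n-sites 80 --n-pairs 60

phosfx train-site \
    --fasta "$out/data/proteins.fasta" --sites "$out/data/sites.tsv" \
    --out "$out/site-model.npz" --epochs 20 --batch-size 32 --dim 16

phosfx predict-sites \
    --fasta "$out/data/proteins.fasta" --model "$out/site-model.npz" \
    --out "$out/site-predictions.tsv" --dim 16

phosfx evaluate \
    --predictions "$out/site-predictions.tsv" --truth "$out/data/sites.tsv" \
    --score-column p_functional --out "$out/site-report.json"

cat "$out/site-report.json"
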
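#!/usr/bin/env bash
# Shell workflow: generate a fixture, run the pipeline, score the result.
set -euo pipefail

workdir=$(mktemp -d)
echo "working in $workdir"

# 1. a small planted-module fixture (expression.tsv, network.tsv, truth.json)
netbiclust simulate --out "$workdir/fixture" \
    --n-genes 300 --n-samples 60 --n-modules 4 \
    --module-size 15 15 --in-mean 3 --seed 11

# 2. full pipeline at the default hyperparameters (p=0.01, alpha=0.5, beta/K=1)
netbiclust run \
    --expression "$workdir/fixture/expression.tsv" \
    --network "$workdir/fixture/network.tsv" \
    --out "$workdir/run" --seed 11

# 3. cell-level Jaccard of recovered vs planted biclusters
netbiclust evaluate \
    --found "$workdir/run/biclusters.tsv" \
    --truth "$workdir/fixture/truth.json" \
    --out "$workdir/report.json"

head -3 "$workdir/run/biclusters.tsv"
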
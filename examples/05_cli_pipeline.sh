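#!/usr/bin/env bash
# Full command-line pipeline: simulate trees and sequences, then compute
# gene and site concordance factors and run the introgression screen.
#
# Run from the repository root:  bash examples/05_cli_pipeline.sh
set -euo pipefail

work=$(mktemp -d)
trap 'rm -rf "$work"' EXIT

cat > "$work/sim.yaml" <<'YAML'
species_tree: "((((A:1,B:1):0.5,C:1.5):1,D:2.5):1,E:3.5);"
pulses:
  - {donor: C, recipient: A, time: 0.5, gamma: 0.3}
n_loci: 500
seed: 42
YAML

echo "(((( A:1,B:1):0.5,C:1.5):1,D:2.5):1,E:3.5);" | tr -d ' ' > "$work/species.nwk"

deltacf simulate-msc --config "$work/sim.yaml" \
    --out-trees "$work/genes.nwk" --truth "$work/truth.tsv"

deltacf simulate-seqs --trees "$work/genes.nwk" --out-dir "$work/alns" \
    --length 300 --scale 0.05 --seed 7

deltacf concord "$work/species.nwk" "$work/genes.nwk" \
    --out-table "$work/concord.tsv" --out-tree "$work/annotated.nwk" \
    --scf --aln-dir "$work/alns" --n-quartets 100 --seed 3

echo "--- concordance table ---"
cat "$work/concord.tsv"

deltacf delta "$work/species.nwk" "$work/genes.nwk" \
    --out "$work/delta.tsv" --n-boot 1000 --seed 11

echo "--- delta table ---"
cat "$work/delta.tsv"
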
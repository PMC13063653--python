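#!/bin/sh
# End-to-end shell pipeline on a synthetic 20-subject cohort.
set -e
OUT=${1:-scratch/pipeline-demo}

dentasym simulate --output-dir "$OUT/sim" --seed 5 --n-subjects 20
dentasym analyze --input "$OUT/sim/ratings.csv" --output-dir "$OUT/analysis"
dentasym reliability --input "$OUT/sim/ratings.csv" --output-dir "$OUT/reliability"
dentasym cohort --input "$OUT/sim/ratings.csv" --output-dir "$OUT/cohort"

echo "wrote:"
find "$OUT" -name '*.csv' -o -name '*.json' | sort
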
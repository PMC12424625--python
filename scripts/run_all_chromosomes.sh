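#!/usr/bin/env bash
# Fan out one chromjet process per chromosome of a contact map.
#
#   scripts/run_all_chromosomes.sh <input> <resolution> <exp> <outdir> chr1 chr2 ...
#
# Each chromosome runs independently; merge afterwards with
# chromjet.jet_io.combine_chromosomes on the per-chromosome output folders.
set -euo pipefail

if [ "$#" -lt 5 ]; then
    echo "usage: $0 <input> <resolution> <exp:hic|replihic> <outdir> <chrom> [chrom ...]" >&2
    exit 1
fi

INPUT=$1; RESOLUTION=$2; EXP=$3; OUTDIR=$4; shift 4

for CHROM in "$@"; do
    chromjet --input "$INPUT" --chrom "$CHROM" --resolution "$RESOLUTION" \
             --exp "$EXP" --out "$OUTDIR/$CHROM" &
done
wait
echo "all chromosomes done -> $OUTDIR"
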
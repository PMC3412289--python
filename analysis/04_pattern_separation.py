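#!/usr/bin/env python
"""The four-condition pattern-separation experiment at desk scale.

Runs distinct- and similar-pair inputs through the calibrated CA3-like and
EC-like pathways and compares the output Hamming distances with the
chance-level binomial reference.  Writes the full artifact set under
results/experiment/ and prints the condition table.
"""

import argparse
from pathlib import Path

from ca1sep.experiment import (
    REFERENCE_BIOPHYSICAL,
    make_desk_config,
    report,
    run_experiment,
    write_result,
)

OUT = Path(__file__).resolve().parents[1] / "results"

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

res = run_experiment(make_desk_config(args.seed))
write_result(res, OUT / "experiment")
df = report(res)
print(df.to_string(index=False))

print("\nDistinct input pairs leave the outputs at chance-level distance "
      "(separation_ratio ~ 1): the patch fully re-randomizes already-distinct "
      "codes.  Similar input pairs stay far below chance for both pathways.  "
      "Between pathways, the threshold surrogate makes the CA3-like route the "
      "more sensitive one (each changed input cell reaches fan-out-many CA1 "
      "cells, and CA3 fan-out is larger); the full-scale compartmental model "
      "shows the opposite asymmetry, driven by dendritic integration that the "
      "surrogate does not represent.")

print("\nFull-scale compartmental-model reference values (for orientation, "
      "not reproduced by the surrogate):")
for (pw, cond), ref in sorted(REFERENCE_BIOPHYSICAL.items()):
    print(f"  {pw:>3} {cond:>8}: mean HD {ref['mean_hd']}, sd {ref['sd_hd']}, "
          f"spikes {ref['mean_spikes']} +/- {ref['sd_spikes']}")
print("\nartifacts under", OUT / "experiment")
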
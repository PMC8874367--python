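#!/usr/bin/env python
"""Hydrogel-film thickness sweep (0.100 / 0.125 / 0.150 mm) at constant time.

Films line the channel surfaces of both conduit segments; their emission
surface is ~166x the reference microsphere system, so they are compared only
among themselves.  Expected outcome: mean GDNF volume fraction increases
with film thickness (the same released mass is held in a smaller lumen).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ngc_elute.study import build_manifest, run_study

OUT = Path(__file__).resolve().parents[1] / "results" / "film"
res = run_study(build_manifest("film"), h=0.02, out_dir=OUT)
if not res.ok:
    sys.exit(1)

print(f"Film study -> {OUT}")
ids = ["film_t0.100", "film_t0.125", "film_t0.150"]
vals = [res.readouts[i].mean_alpha for i in ids]
for i, v in zip(ids, vals):
    print(f"  {i}: mean GDNF volume fraction {v:.3e}")
print(f"increments: {100*(vals[1]/vals[0]-1):+.1f} % then {100*(vals[2]/vals[1]-1):+.1f} %")
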
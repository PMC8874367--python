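#!/usr/bin/env python
"""Constant-released-mass comparison of the sixteen release-system cases.

Simulation times follow the emission-area budget (larger carriers release
for proportionally less time), so every case receives the same GDNF mass.
Expected outcome: single- and double-layer microsphere systems become
comparable while the bulk hydrogel falls far behind.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ngc_elute.study import build_manifest, run_study

OUT = Path(__file__).resolve().parents[1] / "results" / "constant_mass"
res = run_study(build_manifest("constant_mass"), h=0.02, out_dir=OUT)
if not res.ok:
    for cid, msg in res.failures.items():
        print(f"FAILED {cid}: {msg}", file=sys.stderr)
    sys.exit(1)

cmp_ = res.comparisons.sort_values("rank")
print(f"Constant-mass study, {len(res.readouts)} cases -> {OUT}")
print(cmp_.to_string())
print(
    f"\ndouble/single ratio: {cmp_.loc['o_double_layer', 'ratio_to_baseline']:.2f}"
    f"   bulk/single ratio: {cmp_.loc['p_bulk_hydrogel', 'ratio_to_baseline']:.2f}"
)
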
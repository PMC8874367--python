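#!/usr/bin/env python
"""Constant-release-time comparison of all sixteen release-system cases.

Every system releases for the same 519 s at the common boundary speed, so
the released mass scales with the carrier's emitting perimeter.  Expected
outcome: the double-layer microsphere system leads, the bulk hydrogel
trails, and microsphere quantity raises the mean GDNF volume fraction
roughly in proportion.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ngc_elute.study import build_manifest, run_study

OUT = Path(__file__).resolve().parents[1] / "results" / "constant_time"
res = run_study(build_manifest("constant_time"), h=0.02, out_dir=OUT)
if not res.ok:
    for cid, msg in res.failures.items():
        print(f"FAILED {cid}: {msg}", file=sys.stderr)
    sys.exit(1)

cmp_ = res.comparisons.sort_values("rank")
print(f"Constant-time study, {len(res.readouts)} cases -> {OUT}")
print(cmp_.to_string())
dbl = cmp_.loc["o_double_layer", "ratio_to_baseline"]
blk = cmp_.loc["p_bulk_hydrogel", "ratio_to_baseline"]
comb = cmp_.loc["n_combined", "pct_change"]
print(f"\ndouble/single ratio: {dbl:.2f}   bulk/single ratio: {blk:.2f}")
print(f"combined model vs default: {comb:+.1f} %")
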
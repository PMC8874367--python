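#!/usr/bin/env python
"""Regenerate the release-profile narrowing and constant-mass budget tables.

The 60-day GDNF release profile (5 ng burst over 1 day + 1.5 ng sustained
over 59 days) is scaled down by 1e-4 to a 519 s schedule with unchanged
release velocities; the constant-mass protocol then assigns every release
system a simulation time inversely proportional to its emission surface.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ngc_elute.release_model import release_velocities, modified_profile, release_profile_table, constant_mass_budget_table

OUT = Path(__file__).resolve().parents[1] / "results" / "tables"
OUT.mkdir(parents=True, exist_ok=True)

t1 = release_profile_table()
t1.to_csv(OUT / "release_profiles.csv", index=False)
t2 = constant_mass_budget_table()
t2.to_csv(OUT / "constant_mass_budget.csv", index=False)

bv, cv = release_velocities(modified_profile())
print("Narrowed profile: 9 s burst + 510 s continuous = 519 s total")
print(f"  burst velocity      {bv:.3e} ng/s")
print(f"  continuous velocity {cv:.3e} ng/s")
print(f"\nConstant-mass budget ({len(t2)} systems) -> {OUT / 'constant_mass_budget.csv'}")
print(t2.to_string(index=False))
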
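"""Case readouts: domain-averaged GDNF volume fraction and comparisons.

The study's performance scalar is the area-weighted mean of the secondary
phase volume fraction over the fluid region at the last scheduled time step.
A whole-domain variant (walls and release bodies counted as alpha = 0 area)
is available behind a flag and reported alongside in study outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ngc_elute.geometry import DomainGrid
from ngc_elute.mixture_solver import MixtureState

__all__ = ["CaseReadout", "mean_volume_fraction", "compare_cases", "velocity_magnitude"]


@dataclass(frozen=True)
class CaseReadout:
    """Scalar summary of one simulated case."""

    case_id: str
    mode: str  # constant_time | constant_mass
    final_time: float  # s
    mean_alpha: float
    max_velocity: float  # m/s
    steady_state_time: float | None = None

    def __post_init__(self) -> None:
        if self.mean_alpha < 0:
            raise ValueError("mean_alpha must be >= 0")


def mean_volume_fraction(
    state: MixtureState, grid: DomainGrid, region: str = "fluid"
) -> float:
    """Area-weighted mean volume fraction.

    ``region='fluid'`` averages over fluid cells only (walls and release
    bodies excluded, the default readout); ``region='domain'`` divides the
    same stored amount by the whole domain area instead.
    """
    fluid = grid.fluid
    n = int(fluid.sum())
    if n == 0:
        raise ValueError("grid has no fluid cells to average over")
    total = float(state.alpha[fluid].sum())
    if region == "fluid":
        return total / n
    if region == "domain":
        return total / state.alpha.size
    raise ValueError(f"unknown averaging region {region!r}")


def compare_cases(
    readouts: list[CaseReadout] | dict[str, float], baseline: str
) -> pd.DataFrame:
    """Pairwise comparison of case readouts against a named baseline.

    Returns one row per case with its mean alpha, the ratio to the baseline,
    the percentage change ``(new - old) / old * 100`` and the rank (1 =
    highest mean alpha).  All readouts must share the same protocol mode.
    """
    if isinstance(readouts, dict):
        values = dict(readouts)
    else:
        modes = {r.mode for r in readouts}
        if len(readouts) < 2:
            raise ValueError("need at least two readouts to compare")
        if len(modes) > 1:
            raise ValueError(f"readouts mix protocols: {sorted(modes)}")
        values = {r.case_id: r.mean_alpha for r in readouts}
    if baseline not in values:
        raise KeyError(f"baseline case {baseline!r} not among {sorted(values)}")
    base = values[baseline]
    order = sorted(values, key=values.get, reverse=True)
    rows = []
    for cid in values:
        val = values[cid]
        rows.append(
            {
                "case_id": cid,
                "mean_alpha": val,
                "ratio_to_baseline": val / base if base != 0 else np.inf,
                "pct_change": (val - base) / base * 100.0 if base != 0 else np.inf,
                "rank": order.index(cid) + 1,
            }
        )
    return pd.DataFrame(rows).set_index("case_id")


def velocity_magnitude(state: MixtureState) -> np.ndarray:
    """Cell-centered Euclidean norm of the mixture velocity (m/s)."""
    uc = 0.5 * (state.u[:, :-1] + state.u[:, 1:])
    vc = 0.5 * (state.v[:-1, :] + state.v[1:, :])
    return np.hypot(uc, vc)
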
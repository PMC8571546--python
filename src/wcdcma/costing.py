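"""Cost accrual: MarkovTrace -> discounted and undiscounted lifetime costs.

Costs accrue at cycle start (cycle 0 undiscounted, no half-cycle
correction).  The bridge episode cost — WCD rental price or the
low-intensity hospital stay (daily cost x length of stay) — is charged per
entry into BRIDGE, which with a one-cycle bridge equals the per-cycle BRIDGE
occupancy; reinfection re-entries therefore re-incur the arm's episode cost
and a new reimplantation.  All other components are expected event counts or
state occupancy multiplied by unit costs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from wcdcma.markov import HealthState, MarkovTrace
from wcdcma.parameters import Arm, CYCLES_PER_YEAR, ModelParameters

__all__ = ["ArmResult", "COST_COMPONENTS", "discount_factor", "accrue_costs"]

COST_COMPONENTS = (
    "bridge",
    "reimplantation",
    "post_icd_monthly",
    "hf_hospitalization",
    "generator_replacement",
    "lead_revision",
)


def discount_factor(cycle_index, annual_rate: float):
    """Present-value factor ``(1 + r)^(-cycle/12)`` for a monthly cycle index.

    Accepts a scalar or an array of cycle indices; cycle 0 is undiscounted.
    """
    if annual_rate < 0:
        raise ValueError("annual discount rate must be >= 0")
    cycle = np.asarray(cycle_index)
    if np.any(cycle < 0):
        raise ValueError("cycle_index must be >= 0")
    out = (1.0 + annual_rate) ** (-cycle / CYCLES_PER_YEAR)
    return float(out) if np.isscalar(cycle_index) else out


@dataclass(frozen=True)
class ArmResult:
    """Lifetime costs for one arm with a per-component breakdown.

    ``components`` maps each cost component to an ``(undiscounted,
    discounted)`` pair; the pairs sum to the totals.
    """

    arm: Arm
    total_cost: float
    total_cost_discounted: float
    components: dict[str, tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "arm": self.arm.value,
            "total_cost": self.total_cost,
            "total_cost_discounted": self.total_cost_discounted,
            "components": {k: {"undiscounted": u, "discounted": d} for k, (u, d) in self.components.items()},
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"component": k, "cost": u, "cost_discounted": d} for k, (u, d) in self.components.items()]
        rows.append({"component": "total", "cost": self.total_cost, "cost_discounted": self.total_cost_discounted})
        return pd.DataFrame(rows)


def accrue_costs(trace: MarkovTrace, params: ModelParameters, arm: Arm) -> ArmResult:
    """Attach the arm's unit costs to a cohort trace.

    Per cycle: bridge occupancy x the arm's episode cost, reimplantation
    events x the implantation tariff, POST_ICD occupancy x the monthly
    management cost, and heart-failure / generator-replacement / lead-failure
    event counts x their unit costs.  The discounted column multiplies each
    cycle by :func:`discount_factor`.
    """
    if trace.events.shape[0] != trace.occupancy.shape[0]:
        raise ValueError("trace occupancy and events have inconsistent lengths")
    costs = params.costs
    cycles = np.arange(trace.n_cycles)
    df = discount_factor(cycles, params.settings.annual_discount_rate)

    per_cycle = {
        "bridge": trace.bridge_entries * costs.bridge_episode_cost(arm),
        "reimplantation": trace.event_series("reimplantation") * costs.icd_implant_cost,
        "post_icd_monthly": trace.occupancy[:, HealthState.POST_ICD] * costs.post_icd_monthly_cost,
        "hf_hospitalization": trace.event_series("hf_hospitalization") * costs.hf_hosp_cost,
        "generator_replacement": trace.event_series("generator_replacement") * costs.generator_replacement_cost,
        "lead_revision": trace.event_series("lead_failure") * costs.lead_revision_cost,
    }
    components = {name: (float(series.sum()), float((series * df).sum())) for name, series in per_cycle.items()}
    total = sum(u for u, _ in components.values())
    total_disc = sum(d for _, d in components.values())
    return ArmResult(arm=arm, total_cost=total, total_cost_discounted=total_disc, components=components)
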
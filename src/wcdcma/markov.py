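"""Monthly state-transition cohort engine.

Four health states: BRIDGE (the one-month post-explant period, protected by
the arm's strategy), POST_ICD (alive with a reimplanted device), and the two
absorbing death states (cardiac vs other causes).  The cohort starts 100% in
BRIDGE at the start age and is propagated cycle by cycle until the alive
fraction falls below ``occupancy_epsilon`` or the terminal age is reached.

Both treatment arms share identical clinical parameters (the equal-efficacy
assumption of a cost-minimization analysis), so their traces are identical;
arms differ only in which bridge cost the costing layer attaches.

Combination of competing monthly risks:

* BRIDGE — SCA death, excess cardiac death and background death are treated
  as independent and combined on the complement scale,
  ``1 - (1-d_sca)(1-q_ex)(1-q_bg)``; survivors undergo reimplantation, which
  kills a fraction ``p_procedural_death`` (classed cardiac).  SCA, excess
  and procedural deaths are cardiac; background deaths non-cardiac.
* POST_ICD — the listed monthly probabilities are marginal and mutually
  exclusive: cardiac death ``q_ex``, other death ``q_bg``, then reinfection
  (return to BRIDGE) among death survivors.  Heart-failure hospitalization
  is drawn among death survivors; lead failure among those who also escape
  reinfection.

Generator replacement is a pure cost event at exact multiples of the battery
life since (re)implantation.  Because exit from POST_ICD is memoryless given
the cycle, the engine tracks each reimplantation sub-cohort exactly via the
cumulative stay-probability product, so expected replacement counts carry no
mean-field approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from wcdcma.parameters import (
    Arm,
    CYCLES_PER_YEAR,
    ModelParameters,
    background_monthly_mortality,
)

__all__ = [
    "HealthState",
    "EVENT_TYPES",
    "MarkovTrace",
    "build_transition_matrix",
    "run_cohort",
    "ModelError",
]


class ModelError(RuntimeError):
    """Structural inconsistency detected while building or running the model."""


class HealthState(IntEnum):
    BRIDGE = 0
    POST_ICD = 1
    DEAD_CARDIAC = 2
    DEAD_OTHER = 3


N_STATES = len(HealthState)

EVENT_TYPES = (
    "sca_during_bridge",
    "reimplantation",
    "procedural_death",
    "hf_hospitalization",
    "reinfection_explant",
    "lead_failure",
    "generator_replacement",
)
_EV = {name: i for i, name in enumerate(EVENT_TYPES)}


@dataclass(frozen=True)
class MarkovTrace:
    """Per-cycle cohort occupancy, expected event counts and ages for one arm.

    ``occupancy[t]`` is the state distribution at the start of cycle ``t``;
    ``events[t]`` the expected per-patient event counts during cycle ``t``
    (columns ordered as :data:`EVENT_TYPES`); ``ages[t]`` the cohort age in
    years at cycle ``t``.
    """

    occupancy: np.ndarray
    events: np.ndarray
    ages: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy[:, HealthState.BRIDGE] + self.occupancy[:, HealthState.POST_ICD]

    @property
    def bridge_entries(self) -> np.ndarray:
        """Per-cycle expected entries into BRIDGE (the state lasts one cycle)."""
        return self.occupancy[:, HealthState.BRIDGE]

    @property
    def expected_bridge_episodes(self) -> float:
        """Expected lifetime number of bridge episodes per patient (>= 1 with reinfection)."""
        return float(self.bridge_entries.sum())

    def event_series(self, name: str) -> np.ndarray:
        return self.events[:, _EV[name]]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"cycle": np.arange(self.n_cycles), "age": self.ages})
        for state in HealthState:
            frame[state.name.lower()] = self.occupancy[:, state]
        for i, name in enumerate(EVENT_TYPES):
            frame[name] = self.events[:, i]
        return frame

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def _bridge_row(params: ModelParameters, q_bg: float) -> tuple[np.ndarray, float]:
    """Transition row for BRIDGE; also returns the pre-procedure survivor mass."""
    c = params.clinical
    d_sca = c.p_sca_bridge_month * (1.0 - c.event_survival * c.vtvf_termination)
    q_ex = c.excess_cardiac_monthly
    surv = (1.0 - d_sca) * (1.0 - q_ex) * (1.0 - q_bg)
    cardiac_pre = 1.0 - (1.0 - d_sca) * (1.0 - q_ex)
    other = (1.0 - d_sca) * (1.0 - q_ex) * q_bg
    row = np.zeros(N_STATES)
    row[HealthState.POST_ICD] = surv * (1.0 - c.p_procedural_death)
    row[HealthState.DEAD_CARDIAC] = cardiac_pre + surv * c.p_procedural_death
    row[HealthState.DEAD_OTHER] = other
    return row, surv


def _post_icd_row(params: ModelParameters, q_bg: float, cycle_index: int) -> np.ndarray:
    c = params.clinical
    q_ex = c.excess_cardiac_monthly
    row = np.zeros(N_STATES)
    if q_bg >= 1.0:
        # absorbing terminal age: cardiac share q_ex, remainder non-cardiac
        row[HealthState.DEAD_CARDIAC] = q_ex
        row[HealthState.DEAD_OTHER] = 1.0 - q_ex
        return row
    if q_ex + q_bg > 1.0 + 1e-12:
        raise ModelError(
            f"competing death probabilities exceed 1 in cycle {cycle_index}: "
            f"excess {q_ex} + background {q_bg}"
        )
    reinf = (1.0 - q_ex - q_bg) * c.p_reinfection_monthly
    row[HealthState.DEAD_CARDIAC] = q_ex
    row[HealthState.DEAD_OTHER] = q_bg
    row[HealthState.BRIDGE] = reinf
    row[HealthState.POST_ICD] = 1.0 - q_ex - q_bg - reinf
    return row


def build_transition_matrix(
    params: ModelParameters,
    cycle_index: int,
    arm: Arm = Arm.WCD,
) -> np.ndarray:
    """Transition matrix for one cycle (rows: from-state, columns: to-state).

    The arm is accepted for interface symmetry but does not change the
    matrix: under the equal-efficacy assumption all clinical dynamics are
    shared and arms differ only in costs.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    age = params.clinical.start_age + cycle_index / CYCLES_PER_YEAR
    q_bg = background_monthly_mortality(params.life_table, age)
    matrix = np.zeros((N_STATES, N_STATES))
    matrix[HealthState.BRIDGE], _ = _bridge_row(params, q_bg)
    matrix[HealthState.POST_ICD] = _post_icd_row(params, q_bg, cycle_index)
    matrix[HealthState.DEAD_CARDIAC, HealthState.DEAD_CARDIAC] = 1.0
    matrix[HealthState.DEAD_OTHER, HealthState.DEAD_OTHER] = 1.0
    sums = matrix.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-12):
        raise ModelError(f"transition rows do not sum to 1 in cycle {cycle_index}: {sums}")
    return matrix


def run_cohort(params: ModelParameters, arm: Arm = Arm.WCD) -> MarkovTrace:
    """Propagate the cohort from 100% BRIDGE at the start age to absorption.

    Stops when the alive fraction drops below ``occupancy_epsilon`` or the
    life-table terminal age is reached; the terminal age is absorbing
    (annual death probability 1), so the horizon is bounded.
    """
    c = params.clinical
    eps = params.settings.occupancy_epsilon
    max_cycles = params.max_cycles

    occupancy = [np.array([1.0, 0.0, 0.0, 0.0])]
    events: list[np.ndarray] = []
    ages = [float(c.start_age)]

    # Reimplantation sub-cohorts for exact expected generator-replacement
    # counts: entry mass per cycle plus the cumulative POST_ICD stay product.
    entry_mass: dict[int, float] = {}
    stay_cumprod = [1.0]

    t = 0
    while True:
        occ = occupancy[t]
        age = c.start_age + t / CYCLES_PER_YEAR
        q_bg = background_monthly_mortality(params.life_table, age)
        bridge_row, surv = _bridge_row(params, q_bg)
        post_row = _post_icd_row(params, q_bg, t)

        occ_b = occ[HealthState.BRIDGE]
        occ_p = occ[HealthState.POST_ICD]
        death_free = 1.0 - post_row[HealthState.DEAD_CARDIAC] - post_row[HealthState.DEAD_OTHER]

        ev = np.zeros(len(EVENT_TYPES))
        ev[_EV["sca_during_bridge"]] = occ_b * c.p_sca_bridge_month
        ev[_EV["reimplantation"]] = occ_b * surv * (1.0 - c.p_procedural_death)
        ev[_EV["procedural_death"]] = occ_b * surv * c.p_procedural_death
        ev[_EV["hf_hospitalization"]] = occ_p * death_free * c.p_hf_hosp_monthly
        ev[_EV["reinfection_explant"]] = occ_p * post_row[HealthState.BRIDGE]
        ev[_EV["lead_failure"]] = occ_p * death_free * (1.0 - c.p_reinfection_monthly) * c.p_lead_failure_monthly

        repl = 0.0
        life = c.battery_life_months
        t0 = t - life
        while t0 >= 0:
            mass = entry_mass.get(t0, 0.0)
            if mass > 0.0 and stay_cumprod[t0] > 0.0:
                repl += mass * stay_cumprod[t] / stay_cumprod[t0]
            t0 -= life
        ev[_EV["generator_replacement"]] = repl
        events.append(ev)

        alive = occ_b + occ_p
        if alive < eps or t >= max_cycles:
            break

        matrix = np.zeros((N_STATES, N_STATES))
        matrix[HealthState.BRIDGE] = bridge_row
        matrix[HealthState.POST_ICD] = post_row
        matrix[HealthState.DEAD_CARDIAC, HealthState.DEAD_CARDIAC] = 1.0
        matrix[HealthState.DEAD_OTHER, HealthState.DEAD_OTHER] = 1.0

        nxt = occ @ matrix
        occupancy.append(nxt)
        ages.append(c.start_age + (t + 1) / CYCLES_PER_YEAR)
        entry_mass[t + 1] = ev[_EV["reimplantation"]]
        stay_cumprod.append(stay_cumprod[t] * post_row[HealthState.POST_ICD])
        t += 1

    return MarkovTrace(
        occupancy=np.asarray(occupancy),
        events=np.asarray(events),
        ages=np.asarray(ages),
    )
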
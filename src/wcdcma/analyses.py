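"""Cost-minimization analyses: base case, one-way sensitivity, threshold, tornado.

Sign convention: the cost difference ``delta`` is WCD minus standard of
care, so a negative delta means the WCD saves money; reports print savings
as a positive "cost reduction".

Because the two arms share one cohort trace and differ only in the bridge
episode cost, the discounted delta is exactly affine in each episode cost:

    delta = (wcd_episode_cost - standard_episode_cost) * E[bridge episodes]

with the expectation discount-weighted for the discounted column.  The
bridge-episode multiplier (expected lifetime bridge entries per patient,
>= 1 and > 1 whenever reinfection is possible) is exposed on
:class:`CMAResult` so that any gap between the delta and the single-episode
cost difference is directly diagnosable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from wcdcma.costing import ArmResult, accrue_costs, discount_factor
from wcdcma.markov import run_cohort
from wcdcma.parameters import Arm, ModelParameters

__all__ = [
    "CMAResult",
    "SensitivityCurve",
    "TornadoEntry",
    "parameter_names",
    "get_parameter",
    "set_parameter",
    "run_cma",
    "one_way_cost_sensitivity",
    "threshold_standard_care_cost",
    "tornado",
    "DEFAULT_TORNADO_PARAMETERS",
]

# name -> (section, field, is_probability); "standard_care_cost" is virtual:
# it reads/writes the per-episode stay cost by scaling the daily cost.
_REGISTRY: dict[str, tuple[str, str, bool]] = {
    "p_sca_bridge_month": ("clinical", "p_sca_bridge_month", True),
    "event_survival": ("clinical", "event_survival", True),
    "vtvf_termination": ("clinical", "vtvf_termination", True),
    "p_procedural_death": ("clinical", "p_procedural_death", True),
    "excess_cardiac_monthly": ("clinical", "excess_cardiac_monthly", True),
    "p_hf_hosp_monthly": ("clinical", "p_hf_hosp_monthly", True),
    "p_reinfection_monthly": ("clinical", "p_reinfection_monthly", True),
    "p_lead_failure_monthly": ("clinical", "p_lead_failure_monthly", True),
    "wcd_episode_cost": ("costs", "wcd_episode_cost", False),
    "hosp_daily_cost": ("costs", "hosp_daily_cost", False),
    "hosp_los_days": ("costs", "hosp_los_days", False),
    "icd_implant_cost": ("costs", "icd_implant_cost", False),
    "generator_replacement_cost": ("costs", "generator_replacement_cost", False),
    "hf_hosp_cost": ("costs", "hf_hosp_cost", False),
    "lead_revision_cost": ("costs", "lead_revision_cost", False),
    "post_icd_monthly_cost": ("costs", "post_icd_monthly_cost", False),
    "annual_discount_rate": ("settings", "annual_discount_rate", False),
}
_ALIASES = {"wcd_cost": "wcd_episode_cost"}

DEFAULT_TORNADO_PARAMETERS: tuple[str, ...] = (
    "wcd_episode_cost",
    "standard_care_cost",
    "icd_implant_cost",
    "generator_replacement_cost",
    "hf_hosp_cost",
    "lead_revision_cost",
    "post_icd_monthly_cost",
    "p_sca_bridge_month",
    "event_survival",
    "p_procedural_death",
    "excess_cardiac_monthly",
    "p_hf_hosp_monthly",
    "p_reinfection_monthly",
    "p_lead_failure_monthly",
)


def parameter_names() -> list[str]:
    """Names accepted by the sensitivity analyses."""
    return sorted(set(_REGISTRY) | {"standard_care_cost"} | set(_ALIASES))


def _resolve(name: str) -> str:
    name = _ALIASES.get(name, name)
    if name != "standard_care_cost" and name not in _REGISTRY:
        raise KeyError(f"unknown parameter {name!r}; valid names: {', '.join(parameter_names())}")
    return name


def get_parameter(params: ModelParameters, name: str) -> float:
    name = _resolve(name)
    if name == "standard_care_cost":
        return params.costs.standard_care_episode_cost
    section, fld, _ = _REGISTRY[name]
    return float(getattr(getattr(params, section), fld))


def set_parameter(params: ModelParameters, name: str, value: float) -> ModelParameters:
    """Return a copy of ``params`` with one named parameter set to ``value``.

    Probabilities are clipped to [0, 1] (relative perturbations of values
    near 1 would otherwise leave the valid range); costs must be >= 0.
    """
    name = _resolve(name)
    if name == "standard_care_cost":
        los = params.costs.hosp_los_days
        if los <= 0:
            raise ValueError("cannot set standard_care_cost with zero length of stay")
        return set_parameter(params, "hosp_daily_cost", value / los)
    section, fld, is_prob = _REGISTRY[name]
    if is_prob:
        value = min(max(value, 0.0), 1.0)
    updated = getattr(params, section).model_copy(update={fld: value})
    return params.model_copy(update={section: updated})


@dataclass(frozen=True)
class CMAResult:
    """Base-case cost-minimization comparison of the two arms."""

    wcd: ArmResult
    standard: ArmResult
    delta: float
    delta_discounted: float
    bridge_episodes: float
    bridge_episodes_discounted: float

    @property
    def bridge_episode_multiplier(self) -> float:
        """Expected lifetime bridge episodes per patient (1 = no reinfection loop)."""
        return self.bridge_episodes

    def to_table(self) -> pd.DataFrame:
        """Two-column cost table per arm plus the delta row."""
        return pd.DataFrame(
            [
                {"treatment": "WCD", "cost": self.wcd.total_cost, "cost_discounted": self.wcd.total_cost_discounted},
                {
                    "treatment": "Standard of care",
                    "cost": self.standard.total_cost,
                    "cost_discounted": self.standard.total_cost_discounted,
                },
                {"treatment": "WCD versus standard of care", "cost": self.delta, "cost_discounted": self.delta_discounted},
            ]
        )

    def to_dict(self) -> dict:
        return {
            "wcd": self.wcd.to_dict(),
            "standard": self.standard.to_dict(),
            "delta": self.delta,
            "delta_discounted": self.delta_discounted,
            "bridge_episodes": self.bridge_episodes,
            "bridge_episodes_discounted": self.bridge_episodes_discounted,
        }


@dataclass(frozen=True)
class SensitivityCurve:
    """Cost difference as one parameter sweeps a relative range."""

    varied_parameter: str
    points: list[tuple[float, float]]
    baseline_index: int

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.points, columns=[self.varied_parameter, "delta_discounted"])
        frame["is_baseline"] = [i == self.baseline_index for i in range(len(self.points))]
        return frame


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    delta_low: float
    delta_high: float

    @property
    def spread(self) -> float:
        return abs(self.delta_high - self.delta_low)


def run_cma(params: ModelParameters) -> CMAResult:
    """Run both arms on the shared cohort trace and difference their costs."""
    trace = run_cohort(params, Arm.WCD)
    wcd = accrue_costs(trace, params, Arm.WCD)
    standard = accrue_costs(trace, params, Arm.STANDARD)
    df = discount_factor(np.arange(trace.n_cycles), params.settings.annual_discount_rate)
    episodes = trace.expected_bridge_episodes
    episodes_disc = float((trace.bridge_entries * df).sum())
    return CMAResult(
        wcd=wcd,
        standard=standard,
        delta=wcd.total_cost - standard.total_cost,
        delta_discounted=wcd.total_cost_discounted - standard.total_cost_discounted,
        bridge_episodes=episodes,
        bridge_episodes_discounted=episodes_disc,
    )


def one_way_cost_sensitivity(
    params: ModelParameters,
    target: str,
    rel_min: float = -0.30,
    rel_max: float = 0.30,
    steps: int = 13,
) -> SensitivityCurve:
    """Sweep one parameter over relative perturbations of its base value.

    The grid is evenly spaced over ``[1 + rel_min, 1 + rel_max]`` times the
    base value and always contains the unperturbed baseline point.
    """
    target = _resolve(target)
    if rel_min >= rel_max:
        raise ValueError("rel_min must be < rel_max")
    if steps < 2:
        raise ValueError("steps must be >= 2")
    base = get_parameter(params, target)
    multipliers = list(np.linspace(1.0 + rel_min, 1.0 + rel_max, steps))
    if not any(abs(m - 1.0) < 1e-12 for m in multipliers):
        multipliers = sorted(multipliers + [1.0])
    points: list[tuple[float, float]] = []
    baseline_index = -1
    for i, mult in enumerate(multipliers):
        if abs(mult - 1.0) < 1e-12:
            baseline_index = i
            perturbed = params
            value = base
        else:
            value = base * mult
            perturbed = set_parameter(params, target, value)
            value = get_parameter(perturbed, target)  # reflect any clipping
        points.append((value, run_cma(perturbed).delta_discounted))
    return SensitivityCurve(varied_parameter=target, points=points, baseline_index=baseline_index)


def threshold_standard_care_cost(params: ModelParameters) -> float:
    """Standard-care episode cost at which the discounted delta is zero.

    Exploits exact affinity of the delta in the episode cost (two-point line
    solve).  With equal efficacy across arms the break-even point equals the
    WCD episode cost, independent of every other parameter.
    """
    base = params.costs.standard_care_episode_cost
    s0, s1 = base, base * 1.2 if base > 0 else (base + 1000.0)
    if s1 == s0:
        s1 = s0 + 1000.0
    d0 = run_cma(set_parameter(params, "standard_care_cost", s0)).delta_discounted
    d1 = run_cma(set_parameter(params, "standard_care_cost", s1)).delta_discounted
    slope = (d1 - d0) / (s1 - s0)
    if abs(slope) < 1e-12:
        raise ValueError("degenerate model: delta insensitive to standard-care cost (zero bridge occupancy)")
    return s0 - d0 / slope


def tornado(
    params: ModelParameters,
    spec: Sequence[tuple[str, float, float]] | None = None,
) -> list[TornadoEntry]:
    """One-way sensitivity at both extremes for each parameter, ranked by spread.

    ``spec`` lists ``(parameter, rel_min, rel_max)`` perturbations; the
    default sweeps every cost and clinical probability at +/-30%.
    """
    if spec is None:
        spec = [(name, -0.30, 0.30) for name in DEFAULT_TORNADO_PARAMETERS]
    if not spec:
        raise ValueError("tornado spec must be nonempty")
    entries = []
    for name, rel_min, rel_max in spec:
        name = _resolve(name)
        base = get_parameter(params, name)
        low = run_cma(set_parameter(params, name, base * (1.0 + rel_min))).delta_discounted
        high = run_cma(set_parameter(params, name, base * (1.0 + rel_max))).delta_discounted
        entries.append(TornadoEntry(parameter=name, delta_low=low, delta_high=high))
    return sorted(entries, key=lambda e: e.spread, reverse=True)
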
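"""Model inputs: life table, clinical probabilities, unit costs, settings.

All inputs are bundled in :class:`ModelParameters`, which is what the cohort
engine, costing and analysis layers consume.  Probabilities live on a monthly
(cycle) scale unless their name says otherwise; conversions between annual
and per-cycle probabilities are done on the hazard scale so that composing a
per-cycle probability over a year recovers the annual one exactly.

Unit costs are in euro, from the perspective of the Italian National Health
Service.  Main-text inputs (WCD episode price, daily ward cost and length of
stay, discount rate, cohort start age, event survival, battery life) carry
their published values as defaults; inputs published only in supplementary
material (procedural death, heart-failure hospitalization, reinfection and
lead-failure probabilities, DRG tariffs, monthly follow-up cost) carry
documented plausible placeholder defaults and are ordinary config entries, so
exact values can be dropped in via ``load_parameters``.
"""

from __future__ import annotations

import logging
import math
from enum import Enum
from pathlib import Path
from typing import Any, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

logger = logging.getLogger("wcdcma")

__all__ = [
    "Arm",
    "LifeTable",
    "ClinicalParameters",
    "CostParameters",
    "ModelSettings",
    "ModelParameters",
    "load_parameters",
    "annual_to_cycle_prob",
    "background_monthly_mortality",
    "calibrate_excess_cardiac_mortality",
]

CYCLES_PER_YEAR = 12


class Arm(str, Enum):
    """Treatment strategy during the one-month bridge after explantation."""

    WCD = "WCD"
    STANDARD = "STANDARD"


class LifeTable(BaseModel):
    """Age-indexed annual all-cause death probabilities for the general population.

    Ages must be contiguous integers; the terminal age is absorbing
    (``q_annual == 1``).  Any table satisfying the invariants is accepted —
    national statistics (e.g. ISTAT) or a synthetic Gompertz–Makeham table.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    ages: tuple[int, ...]
    q_annual: tuple[float, ...]

    @model_validator(mode="after")
    def _check(self) -> "LifeTable":
        if len(self.ages) != len(self.q_annual) or not self.ages:
            raise ValueError("life table needs matching, nonempty age and q_annual columns")
        for a0, a1 in zip(self.ages, self.ages[1:]):
            if a1 != a0 + 1:
                raise ValueError(f"life-table ages must be contiguous integers; gap at {a0}->{a1}")
        if self.ages[0] > 61:
            raise ValueError("life table must start at or below age 61 to cover the cohort")
        for q in self.q_annual:
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"q_annual={q} outside [0, 1]")
        if self.q_annual[-1] != 1.0:
            raise ValueError("q_annual at the terminal age must be 1 (absorbing)")
        return self

    @property
    def min_age(self) -> int:
        return self.ages[0]

    @property
    def max_age(self) -> int:
        return self.ages[-1]

    def q_at(self, age: float) -> float:
        """Annual death probability at ``floor(age)``; 1 beyond the terminal age."""
        year = math.floor(age)
        if year >= self.max_age:
            return 1.0
        if year < self.min_age:
            raise ValueError(f"age {age} below life-table minimum {self.min_age}")
        return self.q_annual[year - self.min_age]

    @classmethod
    def from_csv(cls, source: Union[str, Path]) -> "LifeTable":
        """Read a two-column ``age,q_annual`` CSV (one row per integer age)."""
        frame = pd.read_csv(source, float_precision="round_trip")
        expected = ["age", "q_annual"]
        if list(frame.columns) != expected:
            raise ValueError(f"life-table CSV must have columns {expected}, got {list(frame.columns)}")
        return cls(ages=tuple(int(a) for a in frame["age"]), q_annual=tuple(float(q) for q in frame["q_annual"]))

    def to_csv(self, path: Union[str, Path]) -> None:
        # 17 significant digits so float64 values round-trip exactly
        pd.DataFrame({"age": self.ages, "q_annual": self.q_annual}).to_csv(
            path, index=False, float_format="%.17g"
        )


class _Probability(float):
    pass


def _prob_field(default: float, description: str) -> Any:
    return Field(default=default, ge=0.0, le=1.0, description=description)


class ClinicalParameters(BaseModel):
    """Clinical transition probabilities and timing assumptions.

    Monthly probabilities apply per one-month cycle.  ``excess_cardiac_monthly``
    is the constant excess cardiac death probability layered on top of the
    age-increasing general-population mortality; it can be supplied directly
    or produced by :func:`calibrate_excess_cardiac_mortality` from trial
    summaries (cumulative ICD-arm mortality and SCD prevalence).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    start_age: int = Field(default=61, ge=0, description="cohort age at explantation, years")
    p_sca_bridge_month: float = _prob_field(0.05, "probability of a sudden cardiac arrest during the 1-month bridge")
    event_survival: float = _prob_field(0.855, "probability a bridge SCA is survived (given treated VT/VF termination)")
    vtvf_termination: float = _prob_field(1.0, "probability a treated VT/VF episode is terminated")
    p_procedural_death: float = _prob_field(0.005, "probability reimplantation results in procedural death (placeholder)")
    excess_cardiac_monthly: float = _prob_field(0.0033, "constant monthly excess cardiac death probability (placeholder calibration)")
    scd_fraction: float = _prob_field(1.0, "fraction of ICD-cohort excess mortality attributed to SCD in calibration")
    p_hf_hosp_monthly: float = _prob_field(0.005, "monthly probability of heart-failure hospitalization after reimplantation (placeholder)")
    p_reinfection_monthly: float = _prob_field(0.0008, "monthly probability of new ICD infection triggering explant (placeholder)")
    p_lead_failure_monthly: float = _prob_field(0.0008, "monthly probability of lead failure requiring revision (placeholder)")
    battery_life_months: int = Field(default=60, ge=1, description="generator lifetime, months")
    battery_min_failure_free_months: int = Field(default=24, ge=0, description="months with zero battery failure")

    @model_validator(mode="after")
    def _check(self) -> "ClinicalParameters":
        if self.battery_min_failure_free_months > self.battery_life_months:
            raise ValueError("battery_min_failure_free_months must not exceed battery_life_months")
        return self


class CostParameters(BaseModel):
    """Unit costs in euro (Italian NHS perspective).

    The bridge is charged per episode: the WCD arm pays ``wcd_episode_cost``
    per bridge entry, the standard-care arm pays
    ``hosp_daily_cost * hosp_los_days``.  DRG-based tariffs and the monthly
    post-ICD management cost default to documented placeholders.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    wcd_episode_cost: float = Field(default=3600.0, ge=0)
    hosp_daily_cost: float = Field(default=250.0, ge=0)
    hosp_los_days: float = Field(default=21.0, ge=0)
    icd_implant_cost: float = Field(default=16000.0, ge=0, description="DRG tariff for ICD (re)implantation (placeholder)")
    generator_replacement_cost: float = Field(default=9500.0, ge=0, description="DRG tariff for generator replacement (placeholder)")
    hf_hosp_cost: float = Field(default=4000.0, ge=0, description="cost per heart-failure hospitalization (placeholder)")
    lead_revision_cost: float = Field(default=6500.0, ge=0, description="cost per lead revision (placeholder)")
    post_icd_monthly_cost: float = Field(default=450.0, ge=0, description="monthly management cost after reimplantation (placeholder)")

    @property
    def standard_care_episode_cost(self) -> float:
        """Per-episode cost of the low-intensity hospital stay."""
        return self.hosp_daily_cost * self.hosp_los_days

    def bridge_episode_cost(self, arm: Arm) -> float:
        return self.wcd_episode_cost if arm is Arm.WCD else self.standard_care_episode_cost


class ModelSettings(BaseModel):
    """Run settings: discounting, cycle length, lifetime-horizon stopping rule."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    annual_discount_rate: float = Field(default=0.03, ge=0.0)
    cycle_length_months: int = Field(default=1)
    occupancy_epsilon: float = Field(default=1e-9, gt=0.0)
    arm: Arm | None = Field(default=None, description="optional default arm for reporting")

    @model_validator(mode="after")
    def _check(self) -> "ModelSettings":
        if self.cycle_length_months != 1:
            raise ValueError("the model is defined on a fixed 1-month cycle")
        return self


class ModelParameters(BaseModel):
    """Complete input bundle: clinical + cost parameters, settings, life table."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    clinical: ClinicalParameters = Field(default_factory=ClinicalParameters)
    costs: CostParameters = Field(default_factory=CostParameters)
    settings: ModelSettings = Field(default_factory=ModelSettings)
    life_table: LifeTable

    @model_validator(mode="after")
    def _check(self) -> "ModelParameters":
        if not (self.life_table.min_age <= self.clinical.start_age <= self.life_table.max_age):
            raise ValueError(
                f"start_age {self.clinical.start_age} outside life-table range "
                f"[{self.life_table.min_age}, {self.life_table.max_age}]"
            )
        return self

    @property
    def max_cycles(self) -> int:
        """Cycles from start age to the absorbing terminal age."""
        return (self.life_table.max_age - self.clinical.start_age) * CYCLES_PER_YEAR

    def to_config_dict(self) -> dict[str, Any]:
        """Config document (without the life table) as written/read by the CLI."""
        out: dict[str, Any] = {
            "clinical": self.clinical.model_dump(),
            "costs": self.costs.model_dump(),
            "settings": self.settings.model_dump(),
        }
        if out["settings"]["arm"] is not None:
            out["settings"]["arm"] = out["settings"]["arm"].value
        else:
            del out["settings"]["arm"]
        return out


def load_parameters(
    config_source: Union[str, Path, dict, None],
    life_table_source: Union[str, Path, LifeTable],
) -> ModelParameters:
    """Load and validate a full parameter set.

    Parameters
    ----------
    config_source
        Path to a YAML/JSON config, a raw YAML string, an already-parsed
        mapping, or ``None`` for all defaults.  The document may contain
        ``clinical``, ``costs`` and ``settings`` sections; unknown keys are
        rejected.  Missing keys fall back to defaults (logged).
    life_table_source
        Path to an ``age,q_annual`` CSV, or a :class:`LifeTable`.  Required:
        the model cannot run without background mortality.
    """
    if isinstance(life_table_source, LifeTable):
        life_table = life_table_source
    else:
        path = Path(life_table_source)
        if not path.exists():
            raise FileNotFoundError(f"life table not found: {path}")
        life_table = LifeTable.from_csv(path)

    if config_source is None:
        doc: dict[str, Any] = {}
    elif isinstance(config_source, dict):
        doc = dict(config_source)
    else:
        if isinstance(config_source, Path):
            text = config_source.read_text()
        else:
            try:
                is_file = Path(config_source).is_file()
            except OSError:
                is_file = False
            text = Path(config_source).read_text() if is_file else str(config_source)
        doc = yaml.safe_load(text) or {}
        if not isinstance(doc, dict):
            raise ValueError("config must be a mapping of sections to key/value pairs")

    known = {"clinical", "costs", "settings"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}; expected subset of {sorted(known)}")
    for section in known - set(doc):
        logger.debug("config section %r absent; using defaults", section)

    params = ModelParameters(
        clinical=ClinicalParameters(**doc.get("clinical", {})),
        costs=CostParameters(**doc.get("costs", {})),
        settings=ModelSettings(**doc.get("settings", {})),
        life_table=life_table,
    )
    defaulted = sorted(
        set(ClinicalParameters.model_fields) - set(doc.get("clinical", {}))
        | set(CostParameters.model_fields) - set(doc.get("costs", {}))
    )
    if defaulted:
        logger.info("defaults applied for: %s", ", ".join(defaulted))
    return params


def annual_to_cycle_prob(p_annual: float, cycles_per_year: int) -> float:
    """Convert an annual probability to a per-cycle probability on the hazard scale.

    Returns ``1 - (1 - p_annual) ** (1 / cycles_per_year)``, so that composing
    the per-cycle probability over ``cycles_per_year`` cycles recovers the
    annual probability exactly.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"p_annual={p_annual} outside [0, 1]")
    if cycles_per_year < 1:
        raise ValueError("cycles_per_year must be >= 1")
    return 1.0 - (1.0 - p_annual) ** (1.0 / cycles_per_year)


def background_monthly_mortality(life_table: LifeTable, age: float) -> float:
    """Monthly general-population death probability at a (fractional) age.

    The age is floored to whole years for the life-table lookup; beyond the
    terminal age the probability is 1 (absorbing).
    """
    if age >= life_table.max_age:
        return 1.0
    return annual_to_cycle_prob(life_table.q_at(age), CYCLES_PER_YEAR)


def calibrate_excess_cardiac_mortality(
    trial_cum_mortality: float,
    trial_followup_years: float,
    scd_fraction: float,
    life_table: LifeTable,
    cohort_age: float,
) -> float:
    """Constant monthly excess cardiac death probability from trial summaries.

    Converts the trial's cumulative all-cause mortality to a constant monthly
    hazard, subtracts the life-table background hazard at the cohort age
    (hazard-scale subtraction, floored at zero), scales the excess by the
    SCD-attributable fraction, and returns it as a monthly probability.  The
    excess is calibrated once at the cohort start age and held constant over
    all cycles, while general-population mortality keeps rising with age.
    """
    if not 0.0 <= trial_cum_mortality < 1.0:
        raise ValueError("trial_cum_mortality must be in [0, 1)")
    if trial_followup_years <= 0:
        raise ValueError("trial_followup_years must be positive")
    if not 0.0 <= scd_fraction <= 1.0:
        raise ValueError("scd_fraction must be in [0, 1]")
    h_total_monthly = -math.log(1.0 - trial_cum_mortality) / (trial_followup_years * CYCLES_PER_YEAR)
    q_bg = life_table.q_at(cohort_age)
    if q_bg >= 1.0:
        logger.warning("background mortality saturates at age %s; excess set to 0", cohort_age)
        return 0.0
    h_bg_monthly = -math.log(1.0 - q_bg) / CYCLES_PER_YEAR
    excess = h_total_monthly - h_bg_monthly
    if excess <= 0.0:
        logger.warning(
            "background hazard (%.3g/mo) exceeds trial hazard (%.3g/mo); excess cardiac mortality set to 0",
            h_bg_monthly,
            h_total_monthly,
        )
        return 0.0
    return 1.0 - math.exp(-scd_fraction * excess)
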
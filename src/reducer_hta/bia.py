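"""Budget-impact engine.

Compares total payer expenditure under two market-mix scenarios — a flat
device share versus an incremental-uptake share — over a multi-year horizon,
on the same eligible population. For each scenario and year the engine
tracks arm headcounts, arm costs, and healthcare-resource-utilization (HRU)
event counts by driver; the budget impact is the year-by-year differential
(revised minus current) and the avoided HRU counts are current minus
revised.

Costs are undiscounted by default, the standard budget-impact convention;
``discounted=True`` applies the parameter set's discount spec for
exploration. Headcounts are carried at full precision — only the patient
funnel is rounded to whole persons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .parameters import (
    HRU_DRIVERS,
    ArmRates,
    DrugComponent,
    FunnelSpec,
    HruProfile,
    MarketMixSpec,
    ParameterSet,
    UnitCosts,
    round_half_up,
    weighted_annual_drug_cost,
)
from .cua import discount_factor

__all__ = [
    "ScenarioYear",
    "BudgetImpactResult",
    "build_funnel",
    "market_trajectory",
    "per_patient_annual_cost",
    "run_scenario",
    "differential_budget_impact",
]

# unit-cost field backing each HRU driver
_DRIVER_COST = {
    "hospitalizations": "hospitalization",
    "ed_admissions": "ed_admission",
    "coronarographies": "coronarography",
    "outpatient_visits": "outpatient_visit",
    "pci": "elective_pci",
}


@dataclass
class ScenarioYear:
    """One model year of one scenario."""

    year: int
    n_reducer: float
    n_soc: float
    cost_reducer_arm: float
    cost_soc_arm: float
    hru_counts: dict[str, float]

    @property
    def total(self) -> float:
        return self.cost_reducer_arm + self.cost_soc_arm


@dataclass
class BudgetImpactResult:
    """Differential budget impact of the revised versus the current market mix."""

    scenario1: list[ScenarioYear]
    scenario2: list[ScenarioYear]
    differential_per_year: list[float]
    cumulative_differential: float
    avoided_hru_per_year: list[dict[str, float]]
    five_year_totals: dict[str, float]
    average_annual: dict[str, float]

    def detail_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (scenario, year, driver)."""
        rows = []
        for name, years in (("current", self.scenario1), ("revised", self.scenario2)):
            for sy in years:
                for driver in HRU_DRIVERS:
                    rows.append(
                        {
                            "scenario": name,
                            "year": sy.year,
                            "driver": driver,
                            "n_reducer": sy.n_reducer,
                            "n_soc": sy.n_soc,
                            "events": sy.hru_counts[driver],
                            "total_cost_eur": sy.total,
                        }
                    )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for y, (d, avoided) in enumerate(
            zip(self.differential_per_year, self.avoided_hru_per_year), start=1
        ):
            row = {
                "year": y,
                "cost_current_eur": self.scenario1[y - 1].total,
                "cost_revised_eur": self.scenario2[y - 1].total,
                "differential_eur": d,
            }
            row.update({f"avoided_{k}": v for k, v in avoided.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def build_funnel(spec: FunnelSpec) -> list[int]:
    """Apply the eligibility funnel stage by stage.

    Each stage count is round-half-up(previous count x proportion), so every
    stage is an integer number of persons.
    """
    counts: list[int] = []
    current = spec.base_population
    for _label, proportion in spec.stages:
        current = round_half_up(current * proportion)
        counts.append(current)
    return counts


def eligible_population(params: ParameterSet) -> int:
    """Final funnel stage: patients eligible for the reducer at baseline."""
    counts = build_funnel(params.funnel)
    return counts[-1] if counts else params.funnel.base_population


def market_trajectory(spec: MarketMixSpec) -> list[float]:
    """Device share per year, full precision; the comparator holds 1 - share."""
    shares = [spec.device_share_year1 + (y - 1) * spec.annual_increment for y in range(1, spec.years + 1)]
    for y, s in enumerate(shares, start=1):
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"device share in year {y} is {s:.4f}, outside [0, 1]")
    return shares


def per_patient_annual_cost(
    arm: str,
    year_in_arm: int,
    costs: UnitCosts,
    hru: HruProfile,
    drugs: list[DrugComponent],
    drug_reduction: float = 0.0,
) -> float:
    """Expected annual cost of one patient in ``arm`` (EUR/patient/year).

    Sum over HRU drivers of rate x unit cost, plus the usage-weighted drug
    basket (optionally reduced in the reducer arm), plus the one-off implant
    cost in a reducer patient's first year.
    """
    if arm not in ("reducer", "soc"):
        raise ValueError(f"unknown arm {arm!r}")
    rates: ArmRates = getattr(hru, arm)
    total = sum(
        getattr(rates, driver) * getattr(costs, _DRIVER_COST[driver]) for driver in HRU_DRIVERS
    )
    total += weighted_annual_drug_cost(drugs, drug_reduction if arm == "reducer" else 0.0)
    if arm == "reducer" and year_in_arm == 1:
        total += costs.reducer_implant
    return total


def run_scenario(params: ParameterSet, mix: MarketMixSpec, discounted: bool = False) -> list[ScenarioYear]:
    """Simulate one market scenario over the horizon.

    The eligible pool starts at the funnel output and evolves each year by
    the configured incidence inflow and mortality outflow (both zero in the
    base case, i.e. a constant prevalent pool). Arm headcounts follow the
    market shares. Reducer patients newly captured in a year are implants
    that year (first-year cost including the device); reducer patients
    carried over from the previous year pay the steady-state reducer cost.
    """
    shares = market_trajectory(mix)
    horizon = min(params.horizon_years, mix.years)
    pool = float(eligible_population(params))
    out: list[ScenarioYear] = []
    prev_reducer = 0.0
    for y in range(1, horizon + 1):
        n_reducer = pool * shares[y - 1]
        n_soc = pool - n_reducer
        survivors = prev_reducer * (1.0 - params.annual_mortality)
        new_implants = max(0.0, n_reducer - survivors)
        continuing = n_reducer - new_implants

        c_new = per_patient_annual_cost("reducer", 1, params.costs, params.hru, params.drugs, params.drug_reduction_on_reducer)
        c_cont = per_patient_annual_cost("reducer", 2, params.costs, params.hru, params.drugs, params.drug_reduction_on_reducer)
        c_soc = per_patient_annual_cost("soc", y, params.costs, params.hru, params.drugs)

        df = discount_factor(params.discount.rate, y, params.discount.first_year_discounted) if discounted else 1.0
        cost_reducer = (new_implants * c_new + continuing * c_cont) * df
        cost_soc = n_soc * c_soc * df

        hru_counts = {
            driver: n_reducer * getattr(params.hru.reducer, driver)
            + n_soc * getattr(params.hru.soc, driver)
            for driver in HRU_DRIVERS
        }
        out.append(ScenarioYear(y, n_reducer, n_soc, cost_reducer, cost_soc, hru_counts))
        prev_reducer = n_reducer
        pool = pool * (1.0 - params.annual_mortality) + params.annual_incident_eligible
    return out


def differential_budget_impact(params: ParameterSet, discounted: bool = False) -> BudgetImpactResult:
    """Run both scenarios on identical populations and difference them.

    Differential = revised - current per year (negative values are savings);
    avoided HRU = current - revised event counts by driver.
    """
    s1 = run_scenario(params, params.current_mix, discounted)
    s2 = run_scenario(params, params.revised_mix, discounted)
    horizon = min(len(s1), len(s2))
    s1, s2 = s1[:horizon], s2[:horizon]

    differential = [b.total - a.total for a, b in zip(s1, s2)]
    avoided = [
        {driver: a.hru_counts[driver] - b.hru_counts[driver] for driver in HRU_DRIVERS}
        for a, b in zip(s1, s2)
    ]
    totals = {
        "current": sum(sy.total for sy in s1),
        "revised": sum(sy.total for sy in s2),
    }
    return BudgetImpactResult(
        scenario1=s1,
        scenario2=s2,
        differential_per_year=differential,
        cumulative_differential=sum(differential),
        avoided_hru_per_year=avoided,
        five_year_totals=totals,
        average_annual={k: v / horizon for k, v in totals.items()},
    )
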
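"""Synthetic patient-level cohorts with the statistical structure the model assumes.

The economic model consumes only aggregate inputs — per-patient-year HRU
rates, mean utilities, annual mortality — that were measured on an
observational cohort which is not publicly deposited. This module generates
patient-level stand-ins with exactly the structure those aggregates assume:

* event counts per driver are Poisson with the arm's annual rate times the
  patient's years of exposure (the minimal model consistent with a
  "events per patient per year" summary; overdispersion is out of scope);
* utilities are beta-distributed around the arm mean with the configured
  relative standard deviation (method of moments);
* death follows a geometric per-year hazard, censored administratively at
  the end of follow-up, on the model's yearly grid.

``estimate_parameters`` inverts the generator — rates as events per
patient-year at risk, utilities as sample means, mortality as the pooled
life-table hazard — so parameter-recovery round trips exercise every stage
of the pipeline without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .parameters import HRU_DRIVERS, ParameterSet, save_parameters
from .sensitivity import build_distribution

__all__ = [
    "SyntheticCohort",
    "TruthRecord",
    "CohortEstimates",
    "generate_cohort",
    "estimate_parameters",
    "km_survival",
    "rebuild_parameter_set",
]


@dataclass
class SyntheticCohort:
    """Patient-level synthetic data for one arm.

    ``patients`` holds one row per patient: integer event counts per HRU
    driver (totals over the patient's exposure), the utility weight, years
    of exposure, and the death year (NaN when the patient survives to the
    end of follow-up).
    """

    arm: str
    follow_up_years: int
    patients: pd.DataFrame

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def to_csv(self, path: str | Path) -> None:
        self.patients.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, arm: str, follow_up_years: int) -> "SyntheticCohort":
        return cls(arm=arm, follow_up_years=follow_up_years, patients=pd.read_csv(path))


@dataclass
class TruthRecord:
    """The ground-truth ParameterSet behind a synthetic cohort."""

    params: ParameterSet

    def save(self, path: str | Path) -> None:
        save_parameters(self.params, path)


@dataclass
class CohortEstimates:
    """Aggregates re-estimated from a patient-level cohort."""

    rates: dict[str, float]  # events per patient-year at risk, per driver
    utility_mean: float
    annual_mortality: float
    n_patients: int
    patient_years: float


def _arm_utility_mean(truth: ParameterSet, arm: str) -> float:
    t = truth.tree
    if arm == "reducer":
        # responder mixture: what the decision tree credits per alive patient-year
        return t.p_success * t.utility_success + (1.0 - t.p_success) * t.utility_soc
    return t.utility_soc


def generate_cohort(
    truth: ParameterSet,
    n_patients: int,
    arm: str,
    seed: int,
    follow_up_years: int | None = None,
) -> SyntheticCohort:
    """Draw a synthetic cohort for one arm from the ground-truth parameters."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if arm not in ("reducer", "soc"):
        raise ValueError(f"unknown arm {arm!r}")
    follow_up = truth.horizon_years if follow_up_years is None else follow_up_years
    rng = np.random.default_rng(seed)

    m = truth.annual_mortality
    if m > 0:
        death_year = rng.geometric(m, size=n_patients).astype(float)
        death_year[death_year > follow_up] = np.nan  # survives the observation window
    else:
        death_year = np.full(n_patients, np.nan)
    # the year of death still counts as a year at risk on the yearly grid
    exposure = np.where(np.isnan(death_year), follow_up, death_year)

    rates = getattr(truth.hru, arm)
    data: dict[str, np.ndarray] = {}
    for driver in HRU_DRIVERS:
        rate = getattr(rates, driver)
        data[driver] = rng.poisson(rate * exposure)

    u_mean = _arm_utility_mean(truth, arm)
    u_dist = build_distribution(u_mean, truth.uncertainty.relative_sd, "beta") if 0 < u_mean < 1 else None
    if u_dist is None:
        utility = np.full(n_patients, u_mean)
    else:
        utility = u_dist.rvs(size=n_patients, random_state=rng)

    data["utility"] = utility
    data["exposure_years"] = exposure
    data["death_year"] = death_year
    return SyntheticCohort(arm=arm, follow_up_years=follow_up, patients=pd.DataFrame(data))


def estimate_parameters(cohort: SyntheticCohort) -> CohortEstimates:
    """Re-estimate the generator's aggregates from patient-level data.

    Rates are total events over total patient-years at risk; mortality is the
    pooled discrete-time life-table hazard (deaths over at-risk person-years,
    which coincide with exposure on the yearly grid).
    """
    df = cohort.patients
    if len(df) < 2:
        raise ValueError("need at least 2 patients to estimate parameters")
    patient_years = float(df["exposure_years"].sum())
    if patient_years <= 0:
        raise ValueError("zero total exposure: rates are undefined")
    rates = {d: float(df[d].sum()) / patient_years for d in HRU_DRIVERS}
    deaths = float(df["death_year"].notna().sum())
    return CohortEstimates(
        rates=rates,
        utility_mean=float(df["utility"].mean()),
        annual_mortality=deaths / patient_years,
        n_patients=len(df),
        patient_years=patient_years,
    )


def km_survival(cohort: SyntheticCohort) -> pd.Series:
    """Kaplan-Meier survival on the yearly grid, S(0) = 1 through S(follow-up).

    Deaths occur at their death year; everyone else is administratively
    censored at the end of follow-up.
    """
    df = cohort.patients
    durations = df["exposure_years"].to_numpy(float)
    observed = df["death_year"].notna().to_numpy()
    km = KaplanMeierFitter()
    km.fit(durations, event_observed=observed)
    grid = list(range(cohort.follow_up_years + 1))
    surv = km.survival_function_at_times(grid)
    out = pd.Series(surv.to_numpy(float), index=grid, name="survival")
    out.index.name = "year"
    return out


def rebuild_parameter_set(
    template: ParameterSet,
    reducer_estimates: CohortEstimates,
    soc_estimates: CohortEstimates,
) -> ParameterSet:
    """Build a ParameterSet from cohort estimates, for recovery round trips.

    HRU rates and the SoC utility come straight from the estimates. The
    responder utility is solved from the reducer arm's mixture mean using the
    template's responder probability (a patient-level utility alone cannot
    separate the responder fraction from the responder utility). Mortality is
    pooled across arms.
    """
    rebuilt = template.copy()
    for driver in HRU_DRIVERS:
        setattr(rebuilt.hru.reducer, driver, reducer_estimates.rates[driver])
        setattr(rebuilt.hru.soc, driver, soc_estimates.rates[driver])

    u_soc = min(max(soc_estimates.utility_mean, 0.0), 1.0)
    p = template.tree.p_success
    u_mix = reducer_estimates.utility_mean
    u_success = (u_mix - (1.0 - p) * u_soc) / p if p > 0 else u_soc
    rebuilt.tree.utility_soc = u_soc
    rebuilt.tree.utility_success = min(max(u_success, 0.0), 1.0)

    total_deaths_py = (
        reducer_estimates.annual_mortality * reducer_estimates.patient_years
        + soc_estimates.annual_mortality * soc_estimates.patient_years
    )
    rebuilt.annual_mortality = total_deaths_py / (
        reducer_estimates.patient_years + soc_estimates.patient_years
    )
    return rebuilt
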
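"""Model inputs for the reducer budget-impact and cost-utility analyses.

Every input of the economic model lives here as a typed, validated record:
the patient funnel that narrows the Italian 65-74 population down to the
reducer-eligible pool, the two market-mix scenarios, unit costs (DRG tariffs
and outpatient fees), the antianginal drug basket, per-arm healthcare
resource utilization (HRU) rates, the decision-tree parameters of the
cost-utility analysis, discounting, and the uncertainty configuration shared
by the deterministic and probabilistic sensitivity analyses.

Percentages are stored as fractions throughout; formatting happens only at
the reporting edge. ``default_parameter_set`` returns the packaged base
case; a ``base_case.yaml`` mirroring it ships with the package.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "FunnelSpec",
    "MarketMixSpec",
    "UnitCosts",
    "DrugComponent",
    "ArmRates",
    "HruProfile",
    "TreeParams",
    "DiscountSpec",
    "UncertaintyConfig",
    "ParameterSet",
    "default_parameter_set",
    "validate",
    "load_parameters",
    "save_parameters",
    "weighted_annual_drug_cost",
    "round_half_up",
]

HRU_DRIVERS = ("hospitalizations", "ed_admissions", "coronarographies", "outpatient_visits", "pci")


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (away from floor)."""
    return int(math.floor(x + 0.5))


@dataclass
class FunnelSpec:
    """Stepwise narrowing from a base population to the treatment-eligible pool.

    Each stage applies a proportion to the (rounded, integer) count of the
    previous stage.
    """

    base_population: int
    stages: list[tuple[str, float]]


@dataclass
class MarketMixSpec:
    """Linear device-uptake trajectory: share(y) = year-1 share + (y-1) * increment."""

    device_share_year1: float
    annual_increment: float
    years: int = 5


@dataclass
class UnitCosts:
    """Unit costs in EUR per event (DRG tariffs / outpatient fee schedule)."""

    reducer_implant: float
    elective_pci: float
    hospitalization: float
    outpatient_visit: float
    ed_admission: float
    coronarography: float


@dataclass
class DrugComponent:
    """One antianginal drug class: annual per-patient cost and usage prevalence."""

    name: str
    annual_cost: float
    usage_rate: float


@dataclass
class ArmRates:
    """Annual HRU event rates per patient for one arm (events/patient/year)."""

    hospitalizations: float
    ed_admissions: float
    coronarographies: float
    outpatient_visits: float
    pci: float
    # sampling family used by the PSA for each rate; frequencies are normal
    distribution_family: str = "normal"

    def as_dict(self) -> dict[str, float]:
        return {d: getattr(self, d) for d in HRU_DRIVERS}


@dataclass
class HruProfile:
    """Per-arm HRU rate profiles (reducer vs. standard of care)."""

    reducer: ArmRates
    soc: ArmRates


@dataclass
class TreeParams:
    """Decision-tree inputs for the cost-utility analysis.

    The tree branches the reducer cohort into implant responders (utility
    ``utility_success``) and non-responders, who revert to the standard-of-care
    utility and annual cost. Death carries utility zero. ``annual_survival``
    holds, per arm, the probability of surviving each model year given alive
    at its start.
    """

    cohort_size: int
    p_success: float
    utility_success: float
    utility_soc: float
    annual_survival_reducer: list[float]
    annual_survival_soc: list[float]
    annual_cost_reducer_year1: float
    annual_cost_reducer_later: float
    annual_cost_soc: float
    # betas for probabilities/utilities, normals for the cost magnitudes
    distribution_family_probabilities: str = "beta"
    distribution_family_costs: str = "normal"


@dataclass
class DiscountSpec:
    """Annual discounting of costs and/or outcomes.

    With ``first_year_discounted`` False (default) year 1 is undiscounted and
    year y gets 1/(1+rate)^(y-1).
    """

    rate: float = 0.035
    apply_to_costs: bool = True
    apply_to_outcomes: bool = True
    first_year_discounted: bool = False


@dataclass
class UncertaintyConfig:
    """Shared settings for the tornado DSA and the Monte Carlo PSA."""

    relative_sd: float = 0.15
    n_draws: int = 1000
    seed: int = 12345
    dsa_delta: float = 0.15


@dataclass
class ParameterSet:
    """The complete, validated input bundle for one model run."""

    funnel: FunnelSpec
    current_mix: MarketMixSpec
    revised_mix: MarketMixSpec
    costs: UnitCosts
    drugs: list[DrugComponent]
    hru: HruProfile
    tree: TreeParams
    discount: DiscountSpec
    uncertainty: UncertaintyConfig
    horizon_years: int = 5
    # Annual inflow of newly eligible patients and their annual mortality are
    # not published for the base case; both default to zero, i.e. a constant
    # prevalent pool. They are first-class levers of the sensitivity analyses.
    annual_incident_eligible: float = 0.0
    annual_mortality: float = 0.0
    # Therapy de-escalation after implant was deliberately not credited in the
    # base case; exposed as a fraction of the drug cost removed in the reducer arm.
    drug_reduction_on_reducer: float = 0.0

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def to_dict(self) -> dict[str, Any]:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ParameterSet":
        return _build(cls, d, path="")


def weighted_annual_drug_cost(drugs: list[DrugComponent], reduction: float = 0.0) -> float:
    """Usage-weighted mean annual therapy cost per patient (EUR/patient/year).

    ``reduction`` removes a fraction of the basket cost (the post-implant
    therapy de-escalation lever; zero in the base case).
    """
    total = sum(d.annual_cost * d.usage_rate for d in drugs)
    return total * (1.0 - reduction)


# ---------------------------------------------------------------------------
# Packaged base case


def default_parameter_set() -> ParameterSet:
    """The packaged Italian base case.

    Funnel: 6,795,374 residents aged 65-74, of whom 245,771 have angina
    pectoris, 12% of those refractory, 60% of those eligible for the reducer
    (17,696 patients). Market mixes: a flat 1% device share versus an uptake
    scenario starting at 1.5% and growing 0.35 points/year. Unit costs are
    DRG tariffs; HRU rates and utilities (0.594 responder / 0.456 SoC) come
    from the Gallone et al. observational cohort, as do the per-patient
    annual tree costs (EUR 15,702 implant year / 6,988 SoC). The responder
    probability 0.9451 and the post-year-1 reducer annual cost of EUR 2,550
    are inferences consistent with the published year-1 cohort totals, not
    directly published values (see the methods note).
    """
    angina_prevalence = 245_771 / 6_795_374  # reproduces the printed 245,771 exactly
    funnel = FunnelSpec(
        base_population=6_795_374,
        stages=[
            ("angina_pectoris", angina_prevalence),
            ("refractory_angina", 0.12),
            ("eligible_for_reducer", 0.60),
        ],
    )
    return ParameterSet(
        funnel=funnel,
        current_mix=MarketMixSpec(device_share_year1=0.01, annual_increment=0.0, years=5),
        revised_mix=MarketMixSpec(device_share_year1=0.015, annual_increment=0.0035, years=5),
        costs=UnitCosts(
            reducer_implant=7000.00,
            elective_pci=6434.00,
            hospitalization=1870.00,
            outpatient_visit=88.06,
            ed_admission=193.00,
            coronarography=2142.00,
        ),
        drugs=[
            DrugComponent("beta_blockers", 27.29, 0.782),
            DrugComponent("calcium_channel_blockers", 114.04, 0.545),
            DrugComponent("nitrates", 37.41, 0.665),
            DrugComponent("ivabradine", 78.19, 0.181),
            DrugComponent("ranolazine", 827.32, 0.319),
        ],
        hru=HruProfile(
            reducer=ArmRates(
                hospitalizations=1.0,
                ed_admissions=0.1,
                coronarographies=0.2,
                outpatient_visits=0.7,
                pci=0.1,
            ),
            soc=ArmRates(
                hospitalizations=3.4,
                ed_admissions=0.2,
                coronarographies=1.0,
                outpatient_visits=2.1,
                pci=0.3,
            ),
        ),
        tree=TreeParams(
            cohort_size=10_000,
            p_success=0.9451,
            utility_success=0.594,
            utility_soc=0.456,
            annual_survival_reducer=[1.0] * 5,
            annual_survival_soc=[1.0] * 5,
            annual_cost_reducer_year1=15_702.0,
            annual_cost_reducer_later=2_550.0,
            annual_cost_soc=6_988.0,
        ),
        discount=DiscountSpec(rate=0.035),
        uncertainty=UncertaintyConfig(),
        horizon_years=5,
    )


# ---------------------------------------------------------------------------
# Validation — violations are data, not exceptions


def _frac(violations: list[str], name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        violations.append(f"{name} = {value!r} must be a fraction in [0, 1]")


def _nonneg(violations: list[str], name: str, value: float) -> None:
    if value < 0:
        violations.append(f"{name} = {value!r} must be >= 0")


def validate(params: ParameterSet) -> list[str]:
    """Check every structural invariant; return one message per violation.

    An empty list means the parameter set is internally consistent.
    """
    v: list[str] = []

    if params.funnel.base_population < 0:
        v.append("funnel.base_population must be >= 0")
    count = params.funnel.base_population
    for i, (label, p) in enumerate(params.funnel.stages):
        _frac(v, f"funnel.stages[{i}] ({label}) proportion", p)
        nxt = round_half_up(count * p) if 0.0 <= p <= 1.0 else count
        if nxt > count:
            v.append(f"funnel.stages[{i}] ({label}) count {nxt} exceeds previous stage {count}")
        count = nxt

    for mix_name in ("current_mix", "revised_mix"):
        mix: MarketMixSpec = getattr(params, mix_name)
        if mix.years < 1:
            v.append(f"{mix_name}.years must be >= 1")
        for y in range(1, max(mix.years, 1) + 1):
            share = mix.device_share_year1 + (y - 1) * mix.annual_increment
            if not (0.0 <= share <= 1.0):
                v.append(
                    f"{mix_name}: device share in year {y} is {share:.4f}, outside [0, 1]"
                )

    for f in dataclasses.fields(UnitCosts):
        _nonneg(v, f"costs.{f.name}", getattr(params.costs, f.name))

    for i, d in enumerate(params.drugs):
        _nonneg(v, f"drugs[{i}] ({d.name}).annual_cost", d.annual_cost)
        _frac(v, f"drugs[{i}] ({d.name}).usage_rate", d.usage_rate)

    for arm in ("reducer", "soc"):
        rates: ArmRates = getattr(params.hru, arm)
        for driver in HRU_DRIVERS:
            _nonneg(v, f"hru.{arm}.{driver}", getattr(rates, driver))

    t = params.tree
    if t.cohort_size < 1:
        v.append("tree.cohort_size must be >= 1")
    _frac(v, "tree.p_success", t.p_success)
    _frac(v, "tree.utility_success", t.utility_success)
    _frac(v, "tree.utility_soc", t.utility_soc)
    for arm_name, surv in (
        ("annual_survival_reducer", t.annual_survival_reducer),
        ("annual_survival_soc", t.annual_survival_soc),
    ):
        for i, s in enumerate(surv):
            _frac(v, f"tree.{arm_name}[{i}]", s)
    _nonneg(v, "tree.annual_cost_reducer_year1", t.annual_cost_reducer_year1)
    _nonneg(v, "tree.annual_cost_reducer_later", t.annual_cost_reducer_later)
    _nonneg(v, "tree.annual_cost_soc", t.annual_cost_soc)

    _nonneg(v, "discount.rate", params.discount.rate)
    _nonneg(v, "uncertainty.relative_sd", params.uncertainty.relative_sd)
    if params.uncertainty.n_draws < 1:
        v.append("uncertainty.n_draws must be >= 1")
    if params.uncertainty.dsa_delta <= 0:
        v.append("uncertainty.dsa_delta must be > 0")

    if params.horizon_years < 1:
        v.append("horizon_years must be >= 1")
    _nonneg(v, "annual_incident_eligible", params.annual_incident_eligible)
    _frac(v, "annual_mortality", params.annual_mortality)
    _frac(v, "drug_reduction_on_reducer", params.drug_reduction_on_reducer)

    return v


# ---------------------------------------------------------------------------
# Serialization (YAML, round-trip lossless)


def _asdict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj):
        return {f.name: _asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_asdict(x) for x in obj]
    return obj


_FIELD_TYPES = {
    "funnel": FunnelSpec,
    "current_mix": MarketMixSpec,
    "revised_mix": MarketMixSpec,
    "costs": UnitCosts,
    "hru": HruProfile,
    "tree": TreeParams,
    "discount": DiscountSpec,
    "uncertainty": UncertaintyConfig,
    "reducer": ArmRates,
    "soc": ArmRates,
}


class ParameterError(ValueError):
    """Raised when a configuration document cannot be mapped onto ParameterSet."""


def _build(cls: type, d: Any, path: str) -> Any:
    if not isinstance(d, dict):
        raise ParameterError(f"{path or cls.__name__}: expected a mapping, got {type(d).__name__}")
    kwargs: dict[str, Any] = {}
    names = {f.name for f in dataclasses.fields(cls)}
    for key in d:
        if key not in names:
            raise ParameterError(f"{path + '.' if path else ''}{key}: unknown field")
    for f in dataclasses.fields(cls):
        here = f"{path + '.' if path else ''}{f.name}"
        if f.name not in d:
            if f.default is not dataclasses.MISSING or f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
                continue
            raise ParameterError(f"{here}: missing required field")
        raw = d[f.name]
        if f.name == "stages":
            kwargs[f.name] = [(str(lbl), float(p)) for lbl, p in raw]
        elif f.name == "drugs":
            kwargs[f.name] = [_build(DrugComponent, x, f"{here}[{i}]") for i, x in enumerate(raw)]
        elif f.name in _FIELD_TYPES and isinstance(raw, dict):
            kwargs[f.name] = _build(_FIELD_TYPES[f.name], raw, here)
        else:
            kwargs[f.name] = raw
    return cls(**kwargs)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, val in override.items():
        if k in out and isinstance(out[k], dict) and isinstance(val, dict):
            out[k] = _merge(out[k], val)
        else:
            out[k] = val
    return out


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a ParameterSet to a YAML document (lossless round trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_parameters(path: str | Path, base: ParameterSet | None = None) -> ParameterSet:
    """Read a ParameterSet from YAML.

    With ``base`` given, the document may be partial: its keys override the
    base set and everything else is inherited. Without ``base`` the document
    must be complete; missing or unknown keys raise :class:`ParameterError`
    naming the offending field path.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ParameterError(f"{path}: top level must be a mapping")
    if base is not None:
        doc = _merge(base.to_dict(), doc)
    return ParameterSet.from_dict(doc)


def packaged_base_case_path() -> Path:
    """Path of the base_case.yaml shipped with the package."""
    return Path(str(resources.files("reducer_hta").joinpath("data/base_case.yaml")))
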
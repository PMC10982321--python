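"""Decision-tree cost-utility engine.

A hypothetical cohort (10,000 patients in the base case) is assigned to
either reducer implantation or the standard-of-care period. The reducer
branch splits into implant responders, who accrue the responder utility, and
non-responders, who revert to the standard-of-care utility and annual cost.
Each arm then moves through yearly alive/dead states; death contributes zero
utility and zero cost. Effectiveness is held constant over the horizon (no
decay), and both costs and QALYs are discounted at 3.5%/year with the first
model year undiscounted.

The incremental result per horizon is expressed as an ICER (EUR per QALY
gained) or, when the signs already decide it, as dominance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .parameters import DiscountSpec, ParameterSet, TreeParams

__all__ = [
    "ArmYearValue",
    "CuaResult",
    "discount_factor",
    "tree_expected_values",
    "icer_or_dominance",
    "cua_over_horizons",
    "percent_change",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
EQUIVALENT = "equivalent"


@dataclass
class ArmYearValue:
    """Cohort-level expected cost, QALYs and survivorship for one arm-year."""

    year: int
    expected_cost: float
    expected_qaly: float
    alive_fraction: float


@dataclass
class HorizonResult:
    horizon: int
    cost_reducer: float
    cost_soc: float
    qaly_reducer: float
    qaly_soc: float
    delta_cost: float
    delta_qaly: float
    verdict: str  # "dominant" / "dominated" / "equivalent" / formatted ICER

    @property
    def icer(self) -> float | None:
        """ICER in EUR/QALY, or None when dominance makes the ratio moot."""
        if self.verdict in (DOMINANT, DOMINATED, EQUIVALENT):
            return None
        return self.delta_cost / self.delta_qaly


@dataclass
class CuaResult:
    """Incremental cost-utility results for horizons 1..H."""

    horizons: list[HorizonResult]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "horizon_years": h.horizon,
                    "cost_reducer_eur": h.cost_reducer,
                    "cost_soc_eur": h.cost_soc,
                    "qaly_reducer": h.qaly_reducer,
                    "qaly_soc": h.qaly_soc,
                    "delta_cost_eur": h.delta_cost,
                    "delta_qaly": h.delta_qaly,
                    "icer_eur_per_qaly": h.icer,
                    "verdict": h.verdict,
                }
                for h in self.horizons
            ]
        )


def discount_factor(rate: float, year: int, first_year_discounted: bool = False) -> float:
    """Discount multiplier for model year ``year`` (1-based).

    Default convention treats year 1 as time zero: factor 1/(1+r)^(y-1).
    """
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if year < 1:
        raise ValueError("year index is 1-based")
    exponent = year if first_year_discounted else year - 1
    return 1.0 / (1.0 + rate) ** exponent


def _alive_fractions(annual_survival: list[float], horizon: int) -> list[float]:
    """Fraction of the cohort alive through each year (cumulative product)."""
    out, alive = [], 1.0
    for y in range(horizon):
        s = annual_survival[y] if y < len(annual_survival) else (annual_survival[-1] if annual_survival else 1.0)
        alive *= s
        out.append(alive)
    return out


def tree_expected_values(
    tree: TreeParams, discount: DiscountSpec, horizon: int
) -> dict[str, list[ArmYearValue]]:
    """Expected cohort cost and QALYs per arm per year.

    Reducer-arm per-patient utility each year is the responder mixture
    p*u_success + (1-p)*u_soc; the SoC arm accrues u_soc. Reducer year-1 cost
    is the implant-inclusive annual cost for everyone; afterwards responders
    pay the steady-state reducer cost and non-responders the SoC cost. All
    values scale with the fraction alive and the cohort size, then discount.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    p = tree.p_success
    u_mix = p * tree.utility_success + (1.0 - p) * tree.utility_soc
    cost_later = p * tree.annual_cost_reducer_later + (1.0 - p) * tree.annual_cost_soc

    out: dict[str, list[ArmYearValue]] = {"reducer": [], "soc": []}
    alive_r = _alive_fractions(tree.annual_survival_reducer, horizon)
    alive_s = _alive_fractions(tree.annual_survival_soc, horizon)
    for y in range(1, horizon + 1):
        dc = discount_factor(discount.rate, y, discount.first_year_discounted) if discount.apply_to_costs else 1.0
        dq = discount_factor(discount.rate, y, discount.first_year_discounted) if discount.apply_to_outcomes else 1.0

        cost_r_pp = tree.annual_cost_reducer_year1 if y == 1 else cost_later
        out["reducer"].append(
            ArmYearValue(
                year=y,
                expected_cost=alive_r[y - 1] * cost_r_pp * tree.cohort_size * dc,
                expected_qaly=alive_r[y - 1] * u_mix * tree.cohort_size * dq,
                alive_fraction=alive_r[y - 1],
            )
        )
        out["soc"].append(
            ArmYearValue(
                year=y,
                expected_cost=alive_s[y - 1] * tree.annual_cost_soc * tree.cohort_size * dc,
                expected_qaly=alive_s[y - 1] * tree.utility_soc * tree.cohort_size * dq,
                alive_fraction=alive_s[y - 1],
            )
        )
    return out


def icer_or_dominance(delta_cost: float, delta_qaly: float) -> str:
    """Classify an incremental (cost, QALY) pair.

    "dominant" when the strategy is no more expensive and strictly more
    effective (or strictly cheaper and equally effective); "dominated" for
    the mirror case; "equivalent" when both increments vanish; otherwise the
    ICER delta_cost/delta_qaly formatted to two decimals.
    """
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return EQUIVALENT
    if delta_qaly > 0.0 and delta_cost <= 0.0:
        return DOMINANT
    if delta_qaly == 0.0:
        return DOMINANT if delta_cost < 0.0 else DOMINATED
    if delta_qaly < 0.0 and delta_cost >= 0.0:
        return DOMINATED
    return f"{delta_cost / delta_qaly:.2f}"


def cua_over_horizons(params: ParameterSet, max_horizon: int | None = None) -> CuaResult:
    """Cumulative incremental results for every horizon 1..max_horizon."""
    horizon = max_horizon or params.horizon_years
    values = tree_expected_values(params.tree, params.discount, horizon)
    results: list[HorizonResult] = []
    cc_r = cc_s = cq_r = cq_s = 0.0
    for y in range(horizon):
        cc_r += values["reducer"][y].expected_cost
        cc_s += values["soc"][y].expected_cost
        cq_r += values["reducer"][y].expected_qaly
        cq_s += values["soc"][y].expected_qaly
        dc, dq = cc_r - cc_s, cq_r - cq_s
        results.append(
            HorizonResult(
                horizon=y + 1,
                cost_reducer=cc_r,
                cost_soc=cc_s,
                qaly_reducer=cq_r,
                qaly_soc=cq_s,
                delta_cost=dc,
                delta_qaly=dq,
                verdict=icer_or_dominance(dc, dq),
            )
        )
    return CuaResult(horizons=results)


def percent_change(old: float, new: float) -> float:
    """Relative decrease from ``old`` to ``new`` in percent: 100*(old-new)/old."""
    if old == 0:
        raise ZeroDivisionError("percent_change undefined for old = 0")
    return 100.0 * (old - new) / old
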
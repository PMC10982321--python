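"""Deterministic (tornado) and probabilistic (Monte Carlo) sensitivity analyses.

The one-way deterministic analysis perturbs each registered parameter by a
fixed relative deviation (±15% by default) while holding everything else at
base, recomputes the target outcome — the cumulative budget-impact
differential or the cost-utility ICER — and ranks parameters by the width of
the induced swing.

The probabilistic analysis draws every uncertain decision-tree parameter
from its distribution (beta for probabilities and utilities, normal
truncated at zero for cost and frequency magnitudes, each with a relative
standard deviation of 15% of the mean by default), reruns the cost-utility
model per draw, and summarizes the (ΔC, ΔQ) cloud on the cost-effectiveness
plane together with a cost-effectiveness acceptability curve (CEAC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .cua import cua_over_horizons
from .bia import differential_budget_impact
from .parameters import ParameterSet

__all__ = [
    "TornadoEntry",
    "PsaDraw",
    "PsaSummary",
    "DSA_REGISTRY",
    "one_way_dsa",
    "build_distribution",
    "run_psa",
]


# ---------------------------------------------------------------------------
# Tornado / one-way DSA


@dataclass
class TornadoEntry:
    parameter_name: str
    low_outcome: float
    high_outcome: float
    base_outcome: float

    @property
    def swing(self) -> float:
        return abs(self.high_outcome - self.low_outcome)


def _get_path(params: ParameterSet, path: str):
    obj = params
    for part in path.split("."):
        obj = getattr(obj, part)
    return obj


def _set_path(params: ParameterSet, path: str, value) -> None:
    parts = path.split(".")
    obj = params
    for part in parts[:-1]:
        obj = getattr(obj, part)
    setattr(obj, parts[-1], value)


# The registry names the levers the tornado varies, each backed by one or
# more dotted attribute paths into ParameterSet (paired paths move together,
# e.g. the PCI rate in both arms).
DSA_REGISTRY: dict[str, list[str]] = {
    "responder_percentage": ["tree.p_success"],
    "pci_rate": ["hru.reducer.pci", "hru.soc.pci"],
    "soc_hospitalization_rate": ["hru.soc.hospitalizations"],
    "soc_coronarography_rate": ["hru.soc.coronarographies"],
    "ed_admission_rate": ["hru.reducer.ed_admissions", "hru.soc.ed_admissions"],
    "mortality_rate": ["annual_mortality"],
    "drug_therapy_reduction": ["drug_reduction_on_reducer"],
    "outpatient_visit_rate": ["hru.reducer.outpatient_visits", "hru.soc.outpatient_visits"],
}


def _target_fn(target: str) -> Callable[[ParameterSet], float]:
    if target == "bia_differential":
        return lambda p: differential_budget_impact(p).cumulative_differential
    if target == "cua_icer":
        # the raw cost-per-QALY ratio at the full horizon, used as a
        # continuous outcome (negative in the dominant region)
        def icer(p: ParameterSet) -> float:
            h = cua_over_horizons(p).horizons[-1]
            return h.delta_cost / h.delta_qaly
        return icer
    raise ValueError(f"unknown DSA target {target!r}")


def one_way_dsa(
    params: ParameterSet, target: str = "cua_icer", delta: float | None = None
) -> list[TornadoEntry]:
    """Tornado analysis: perturb each registry parameter by ±delta.

    Every low/high outcome is a full-model recomputation with the single
    parameter set to base*(1-delta) or base*(1+delta). Entries come back
    sorted by descending swing.
    """
    delta = params.uncertainty.dsa_delta if delta is None else delta
    if delta <= 0:
        raise ValueError("delta must be > 0")
    fn = _target_fn(target)
    base_outcome = fn(params)

    entries: list[TornadoEntry] = []
    for name, paths in DSA_REGISTRY.items():
        outcomes = []
        for factor in (1.0 - delta, 1.0 + delta):
            perturbed = params.copy()
            for path in paths:
                base_value = _get_path(params, path)
                _set_path(perturbed, path, base_value * factor)
            outcomes.append(fn(perturbed))
        entries.append(TornadoEntry(name, outcomes[0], outcomes[1], base_outcome))
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter_name,
                "low": e.low_outcome,
                "high": e.high_outcome,
                "swing": e.swing,
                "base": e.base_outcome,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# Distributions


def build_distribution(mean: float, relative_sd: float, family: str):
    """Frozen scipy distribution for one uncertain parameter.

    sd = relative_sd * mean. Beta parameters come from the method of
    moments: with m the mean and v the variance, k = m(1-m)/v - 1,
    shape1 = m*k, shape2 = (1-m)*k. Frequencies and costs use a normal
    truncated at zero. relative_sd = 0 degenerates to a point mass.
    """
    if relative_sd < 0:
        raise ValueError("relative_sd must be >= 0")
    if relative_sd == 0:
        return _PointMass(mean)
    sd = relative_sd * mean
    if family == "beta":
        if not (0.0 < mean < 1.0):
            raise ValueError(f"beta requires mean in (0, 1), got {mean}")
        v = sd * sd
        if v >= mean * (1.0 - mean):
            raise ValueError(
                f"beta method of moments infeasible: variance {v:.4g} >= m(1-m) = {mean * (1 - mean):.4g}"
            )
        k = mean * (1.0 - mean) / v - 1.0
        return _OpenUnitBeta(mean * k, (1.0 - mean) * k)
    if family == "normal":
        if mean == 0:
            return _PointMass(0.0)
        a = (0.0 - mean) / sd  # truncate at zero: rates and costs cannot go negative
        return stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    raise ValueError(f"unknown distribution family {family!r}")


class _OpenUnitBeta:
    """Beta distribution whose draws are clipped to the open unit interval.

    Heavily skewed betas (e.g. a responder probability near 1 at 15%
    relative SD) can round to exactly 0.0 or 1.0 in floating point; clipping
    at machine precision keeps every draw a valid probability/utility.
    """

    def __init__(self, a: float, b: float):
        self.args = (a, b)
        self._dist = stats.beta(a, b)

    def rvs(self, size=None, random_state=None):
        lo = np.nextafter(0.0, 1.0)
        hi = np.nextafter(1.0, 0.0)
        return np.clip(self._dist.rvs(size=size, random_state=random_state), lo, hi)

    def mean(self) -> float:
        return float(self._dist.mean())


class _PointMass:
    """Degenerate distribution used when a parameter carries no uncertainty."""

    def __init__(self, value: float):
        self.value = value

    def rvs(self, size=None, random_state=None):
        if size is None:
            return self.value
        return np.full(size, self.value)

    def mean(self) -> float:
        return self.value


# ---------------------------------------------------------------------------
# PSA


@dataclass
class PsaDraw:
    draw_index: int
    delta_cost: float
    delta_qaly: float
    quadrant: str
    icer_if_defined: float | None


@dataclass
class PsaSummary:
    n_draws: int
    proportion_dominant: float
    mean_delta_cost: float
    mean_delta_qaly: float
    ceac: list[tuple[float, float]]

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ceac, columns=["wtp_eur_per_qaly", "probability_cost_effective"])


def _quadrant(delta_cost: float, delta_qaly: float) -> str:
    """Cost-effectiveness plane quadrant (x = ΔQ, y = ΔC); SE is dominance."""
    ns = "N" if delta_cost > 0 else "S"
    ew = "E" if delta_qaly > 0 else "W"
    return ns + ew


# PSA parameter registry: (dotted path, distribution family). Draw order is
# fixed to this order, so a given seed is reproducible within this package.
PSA_REGISTRY: list[tuple[str, str]] = [
    ("tree.p_success", "beta"),
    ("tree.utility_success", "beta"),
    ("tree.utility_soc", "beta"),
    ("tree.annual_cost_reducer_year1", "normal"),
    ("tree.annual_cost_reducer_later", "normal"),
    ("tree.annual_cost_soc", "normal"),
]


def _psa_distributions(params: ParameterSet):
    dists = []
    for path, family in PSA_REGISTRY:
        mean = _get_path(params, path)
        # probabilities sitting on the {0,1} boundary have zero feasible
        # beta variance; hold them fixed instead of failing the run
        if family == "beta" and not (0.0 < mean < 1.0):
            dists.append((path, _PointMass(mean)))
        else:
            dists.append((path, build_distribution(mean, params.uncertainty.relative_sd, family)))
    return dists


def run_psa(
    params: ParameterSet,
    n_draws: int | None = None,
    seed: int | None = None,
    wtp_grid: np.ndarray | None = None,
) -> tuple[list[PsaDraw], PsaSummary]:
    """Monte Carlo PSA of the cost-utility model at the full horizon.

    Each draw samples every registry parameter independently from its
    distribution, reruns the decision tree over the horizon, and records the
    incremental (cost, QALY) point. The CEAC reports, per willingness-to-pay
    threshold, the fraction of draws with non-negative incremental net
    monetary benefit λ·ΔQ − ΔC.
    """
    n = params.uncertainty.n_draws if n_draws is None else n_draws
    if n < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(params.uncertainty.seed if seed is None else seed)
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 100_001.0, 1000.0)

    dists = _psa_distributions(params)
    draws: list[PsaDraw] = []
    dc = np.empty(n)
    dq = np.empty(n)
    work = params.copy()
    for i in range(n):
        for path, dist in dists:
            _set_path(work, path, float(dist.rvs(random_state=rng)))
        h = cua_over_horizons(work).horizons[-1]
        dc[i], dq[i] = h.delta_cost, h.delta_qaly
        icer = h.delta_cost / h.delta_qaly if h.delta_qaly != 0.0 else None
        draws.append(PsaDraw(i, h.delta_cost, h.delta_qaly, _quadrant(h.delta_cost, h.delta_qaly), icer))

    dominant = np.mean((dc <= 0.0) & (dq > 0.0))
    ceac = [(float(w), float(np.mean(w * dq - dc >= 0.0))) for w in wtp_grid]
    summary = PsaSummary(
        n_draws=n,
        proportion_dominant=float(dominant),
        mean_delta_cost=float(dc.mean()),
        mean_delta_qaly=float(dq.mean()),
        ceac=ceac,
    )
    return draws, summary


def psa_draws_frame(draws: list[PsaDraw]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "draw": d.draw_index,
                "delta_cost_eur": d.delta_cost,
                "delta_qaly": d.delta_qaly,
                "quadrant": d.quadrant,
                "icer_eur_per_qaly": d.icer_if_defined,
            }
            for d in draws
        ]
    )
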
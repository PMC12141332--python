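"""Lifetime Markov cohort model and cost-effectiveness arithmetic.

The cohort allocated by a screening tree is propagated through annual cycles
over a fixed horizon.  Alive states carry a utility weight (QALY per year)
and possibly a device maintenance cost; every alive state transitions to the
absorbing ``dead`` state with the age-specific annual probability q[age];
unwarned mtDNA 12S rRNA carriers additionally transition to ototoxic
deafness with a constant annual hazard.  Costs and utilities accrue for each
cycle entered alive and are discounted by (1+r)^-t with t = 0 for the first
cycle (no half-cycle correction).  One-time screening-phase costs and
first-year device costs are charged at t = 0; device states pay their annual
maintenance cost from the second cycle onward.

A per-individual Monte Carlo simulator of the same specification is provided
as an independent cross-check of the cohort-matrix engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .lifetable import LifeTable
from .params import ParameterSet
from .trees import CohortAllocation

__all__ = [
    "STATES",
    "MarkovSpec",
    "CEResult",
    "compute_icers",
    "discount_factor",
    "microsimulate",
    "net_monetary_benefit",
    "run_markov",
]

STATES = (
    "normal",
    "carrier_unwarned",
    "mm_untreated",
    "mm_hearing_aid",
    "sp_untreated",
    "sp_ci",
    "deaf_ototoxic",
    "dead",
)
_IDX = {s: i for i, s in enumerate(STATES)}
_DEAD = _IDX["dead"]
_CARRIER = _IDX["carrier_unwarned"]
_OTOTOXIC = _IDX["deaf_ototoxic"]


@dataclass(frozen=True)
class MarkovSpec:
    """Per-state utilities and costs plus the ototoxicity hazard."""

    utilities: np.ndarray      # QALY weight per year, len(STATES)
    annual_costs: np.ndarray   # maintenance USD per year, len(STATES)
    first_year_costs: np.ndarray  # USD charged at t=0 instead of the annual cost
    ototoxic_hazard: float     # annual P(ototoxic deafness) for unwarned carriers

    def __post_init__(self):
        for arr_name in ("utilities", "annual_costs", "first_year_costs"):
            arr = np.asarray(getattr(self, arr_name), dtype=float)
            if arr.shape != (len(STATES),):
                raise ValueError(f"{arr_name} must have length {len(STATES)}")
            object.__setattr__(self, arr_name, arr)
        if np.any(self.utilities < 0) or np.any(self.utilities > 1):
            raise ValueError("utilities must lie in [0, 1]")
        if self.utilities[_DEAD] != 0:
            raise ValueError("dead state must have zero utility")
        if not 0 <= self.ototoxic_hazard <= 1:
            raise ValueError("ototoxic_hazard must lie in [0, 1]")

    @classmethod
    def from_params(cls, params: ParameterSet) -> "MarkovSpec":
        u = dict(
            normal=params.value("u_normal"),
            carrier_unwarned=params.value("u_normal"),
            mm_untreated=params.value("u_mm"),
            mm_hearing_aid=params.value("u_ha"),
            sp_untreated=params.value("u_sp"),
            sp_ci=params.value("u_ci"),
            deaf_ototoxic=params.value("u_sp"),
            dead=0.0,
        )
        ann = dict.fromkeys(STATES, 0.0)
        ann["mm_hearing_aid"] = params.value("cost_ha_annual")
        ann["sp_ci"] = params.value("cost_ci_annual")
        fy = dict.fromkeys(STATES, 0.0)
        fy["mm_hearing_aid"] = params.value("cost_ha_first_year")
        fy["sp_ci"] = params.value("cost_ci_first_year")
        return cls(
            utilities=np.array([u[s] for s in STATES]),
            annual_costs=np.array([ann[s] for s in STATES]),
            first_year_costs=np.array([fy[s] for s in STATES]),
            ototoxic_hazard=params.value("ototoxic_annual"),
        )


def discount_factor(rate: float, t: int) -> float:
    """(1+rate)^-t, the present-value weight of cycle t."""
    if rate <= -1:
        raise ValueError("rate must exceed -1")
    if t < 0:
        raise ValueError("t must be >= 0")
    return (1.0 + rate) ** (-t)


def _initial_occupancy(alloc: CohortAllocation) -> np.ndarray:
    occ = np.zeros(len(STATES))
    for state, n in alloc.initial_state_counts().items():
        occ[_IDX[state]] += n
    return occ


def run_markov(
    alloc: CohortAllocation,
    lt: LifeTable,
    spec: MarkovSpec,
    discount_rate: float,
    horizon: int,
) -> tuple[float, float]:
    """Propagate the cohort and return total discounted (cost USD, QALY)."""
    if horizon > len(lt):
        raise ValueError(f"life table covers {len(lt)} ages; horizon {horizon} too long")
    occ = _initial_occupancy(alloc)
    cohort = occ.sum()
    cost = alloc.screening_cost
    qaly = 0.0
    h = spec.ototoxic_hazard
    for t in range(horizon):
        df = discount_factor(discount_rate, t)
        state_cost = spec.first_year_costs if t == 0 else spec.annual_costs
        cost += df * float(occ @ state_cost)
        qaly += df * float(occ @ spec.utilities)
        q = lt.q[t]
        deaths = occ * q
        deaths[_DEAD] = 0.0
        occ = occ - deaths
        occ[_DEAD] += deaths.sum()
        onset = occ[_CARRIER] * h
        occ[_CARRIER] -= onset
        occ[_OTOTOXIC] += onset
        if abs(occ.sum() - cohort) > 1e-6 * max(1.0, cohort):
            raise AssertionError(f"occupancy drift at cycle {t}: {occ.sum()} != {cohort}")
    return cost, qaly


def microsimulate(
    alloc: CohortAllocation,
    lt: LifeTable,
    spec: MarkovSpec,
    discount_rate: float,
    horizon: int,
    n: int,
    rng: np.random.Generator,
) -> dict:
    """Individual-level Monte Carlo of the same model; oracle for run_markov.

    Samples ``n`` newborns from the allocation's initial-state distribution
    and simulates annual death/ototoxicity transitions per person.  Returns
    per-person means and standard errors of discounted cost and QALYs, with
    the (deterministic) per-person screening cost included in the cost mean.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    occ = _initial_occupancy(alloc)
    probs = occ / occ.sum()
    states = rng.choice(len(STATES), size=n, p=probs)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    for t in range(horizon):
        df = discount_factor(discount_rate, t)
        state_cost = spec.first_year_costs if t == 0 else spec.annual_costs
        cost += df * state_cost[states]
        qaly += df * spec.utilities[states]
        alive = states != _DEAD
        dies = alive & (rng.random(n) < lt.q[t])
        states[dies] = _DEAD
        carriers = states == _CARRIER
        onset = carriers & (rng.random(n) < spec.ototoxic_hazard)
        states[onset] = _OTOTOXIC
    screening_pp = alloc.screening_cost / alloc.cohort_size if alloc.cohort_size else 0.0
    return {
        "mean_cost": float(cost.mean()) + screening_pp,
        "mean_qaly": float(qaly.mean()),
        "se_cost": float(cost.std(ddof=1) / np.sqrt(n)),
        "se_qaly": float(qaly.std(ddof=1) / np.sqrt(n)),
        "n": n,
    }


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """NMB = wtp * qaly - cost (USD); the CEAC decision rule."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * qaly - cost


@dataclass
class CEResult:
    """Per-strategy totals and pairwise incremental comparisons."""

    reference: str
    totals: dict[str, tuple[float, float]]  # strategy -> (cost, qaly)
    rows: list[dict]  # strategy, cost, qaly, d_cost, d_qaly, icer, flag

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def icer(self, strategy: str) -> float | None:
        for row in self.rows:
            if row["strategy"] == strategy:
                return row["icer"]
        raise KeyError(strategy)


def compute_icers(
    results: Mapping[str, tuple[float, float]],
    reference: str,
    order: Sequence[str] | None = None,
) -> CEResult:
    """Incremental cost, incremental QALY, and ICER versus ``reference``.

    Strict dominance (more costly and less effective, or the reverse) is
    flagged rather than expressed as a ratio; a zero QALY increment leaves
    the ICER undefined.  Reported ICERs are rounded to 2 decimals.
    """
    if len(results) < 2:
        raise ValueError("need at least two strategies")
    if reference not in results:
        raise KeyError(f"reference strategy {reference!r} not in results")
    ref_cost, ref_qaly = results[reference]
    names = list(order) if order is not None else list(results)
    rows = [
        {
            "strategy": reference,
            "cost": ref_cost,
            "qaly": ref_qaly,
            "d_cost": None,
            "d_qaly": None,
            "icer": None,
            "flag": "reference",
        }
    ]
    for name in names:
        if name == reference:
            continue
        cost, qaly = results[name]
        d_cost, d_qaly = cost - ref_cost, qaly - ref_qaly
        if d_qaly == 0:
            icer, flag = None, "undefined"
        elif d_cost > 0 > d_qaly:
            icer, flag = None, "dominated"
        elif d_cost < 0 < d_qaly:
            icer, flag = None, "dominant"
        else:
            icer, flag = round(d_cost / d_qaly, 2), ""
        rows.append(
            {
                "strategy": name,
                "cost": cost,
                "qaly": qaly,
                "d_cost": d_cost,
                "d_qaly": d_qaly,
                "icer": icer,
                "flag": flag,
            }
        )
    return CEResult(reference=reference, totals=dict(results), rows=rows)
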
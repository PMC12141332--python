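"""End-to-end evaluation: parameters -> trees -> Markov -> (cost, QALY) per strategy."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .lifetable import LifeTable, default_life_table
from .markov_econ import CEResult, MarkovSpec, compute_icers, run_markov
from .params import ParameterSet
from .trees import STRATEGIES, CohortAllocation, build_strategy, evaluate_tree

__all__ = ["StrategyOutcome", "evaluate_strategies", "icer_pair"]


@dataclass
class StrategyOutcome:
    strategy: str
    alloc: CohortAllocation
    cost: float
    qaly: float


def evaluate_strategies(
    params: ParameterSet,
    lt: LifeTable | None = None,
    discount_rate: float | None = None,
    strategies: Sequence[str] = STRATEGIES,
    topology_path: str | Path | None = None,
    cohort_size: float | None = None,
) -> dict[str, StrategyOutcome]:
    """Run the full pipeline for each strategy at the given parameter values."""
    lt = lt if lt is not None else default_life_table()
    r = params.discount_rate if discount_rate is None else discount_rate
    n = params.cohort_size if cohort_size is None else cohort_size
    horizon = params.horizon
    spec = MarkovSpec.from_params(params)
    out: dict[str, StrategyOutcome] = {}
    for name in strategies:
        tree = build_strategy(name, params, topology_path)
        alloc = evaluate_tree(tree, n, strategy=name)
        cost, qaly = run_markov(alloc, lt, spec, r, horizon)
        out[name] = StrategyOutcome(name, alloc, cost, qaly)
    return out


def icer_pair(outcomes: dict[str, StrategyOutcome], strategy: str, reference: str) -> float | None:
    """ICER of ``strategy`` versus ``reference`` (None if undefined/dominance)."""
    res: CEResult = compute_icers(
        {k: (o.cost, o.qaly) for k, o in outcomes.items()}, reference=reference
    )
    return res.icer(strategy)
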
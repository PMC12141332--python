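"""Screening-strategy decision trees and their cohort evaluation.

Each strategy (UNHS only; targeted gene screening of UNHS referrals;
concurrent hearing + gene screening) is a chance-node tree read from a
declared topology file.  Branch probabilities resolve against a
:class:`~hearscreen.params.ParameterSet`; leaves are screening/diagnosis
outcome categories that map one-to-one onto initial Markov health states.
Evaluating a tree on a birth cohort multiplies branch probabilities down
every root-to-leaf path, giving expected person-counts per outcome category,
the derived performance tallies (diagnosed cases, hearing aids, implants,
ototoxicity warnings), and the expected one-time screening/diagnosis cost.

All internal arithmetic is real-valued; reported tallies are rounded
half-up to integers at reporting time only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache as _lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

import yaml

from ._expr import eval_expr
from .params import ParameterSet

__all__ = [
    "STRATEGIES",
    "CATEGORIES",
    "CATEGORY_STATE",
    "ChanceNode",
    "OutcomeLeaf",
    "CohortAllocation",
    "build_strategy",
    "evaluate_tree",
    "round_half_up",
    "screening_phase_cost",
]

STRATEGIES = ("unhs_only", "targeted", "concurrent")

#: Outcome categories a leaf may carry.
CATEGORIES = (
    "normal_hearing",
    "mm_intervened",
    "mm_unintervened",
    "sp_ci",
    "sp_no_ci",
    "mm_undetected",
    "sp_undetected",
    "mtdna_warned",
    "mtdna_unwarned_carrier",
)

#: Category -> initial Markov state.
CATEGORY_STATE = {
    "normal_hearing": "normal",
    "mm_intervened": "mm_hearing_aid",
    "mm_unintervened": "mm_untreated",
    "sp_ci": "sp_ci",
    "sp_no_ci": "sp_untreated",
    "mm_undetected": "mm_untreated",
    "sp_undetected": "sp_untreated",
    "mtdna_warned": "normal",
    "mtdna_unwarned_carrier": "carrier_unwarned",
}

#: Category -> performance tallies it contributes to.
_CATEGORY_TALLIES = {
    "mm_intervened": ("hearing_loss_diagnosed", "hearing_aids", "early_interventions"),
    "mm_unintervened": ("hearing_loss_diagnosed",),
    "sp_ci": ("hearing_loss_diagnosed", "cochlear_implants", "early_interventions"),
    "sp_no_ci": ("hearing_loss_diagnosed",),
    "mtdna_warned": ("ototoxicity_avoided",),
}

TALLY_NAMES = (
    "genetic_screened",
    "hearing_loss_diagnosed",
    "hearing_aids",
    "cochlear_implants",
    "early_interventions",
    "ototoxicity_avoided",
)

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class OutcomeLeaf:
    category: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown outcome category {self.category!r}")


@dataclass(frozen=True)
class ChanceNode:
    label: str
    branches: tuple  # of (probability, ChanceNode | OutcomeLeaf)
    one_time_cost: float = 0.0
    tally: str | None = None


TreeNode = Union[ChanceNode, OutcomeLeaf]


def default_topology_path() -> Path:
    return Path(resources.files("hearscreen").joinpath("data/topology_default.yaml"))


def _resolve(raw: Mapping, values: Mapping[str, float], where: str) -> ChanceNode:
    if "branches" not in raw:
        raise ValueError(f"{where}: node has no branches")
    cost = 0.0
    for cname in raw.get("costs", []) or []:
        if cname not in values:
            raise KeyError(f"{where}: unknown cost parameter {cname!r}")
        cost += values[cname]
    branches: list[tuple[float, TreeNode]] = []
    complement_at: int | None = None
    total = 0.0
    for i, braw in enumerate(raw["branches"]):
        expr = braw.get("p")
        if expr is None:
            raise ValueError(f"{where}: branch {i} lacks a probability")
        if "leaf" in braw:
            child: TreeNode = OutcomeLeaf(braw["leaf"])
        elif "node" in braw:
            child = _resolve(braw["node"], values, f"{where}/{raw.get('label', '?')}")
        else:
            raise ValueError(f"{where}: branch {i} needs 'leaf' or 'node'")
        if expr == "~":
            if complement_at is not None:
                raise ValueError(f"{where}: more than one complement branch")
            complement_at = i
            branches.append((math.nan, child))
            continue
        try:
            p = eval_expr(str(expr), values)
        except ZeroDivisionError:
            # a conditional probability whose conditioning event was driven to
            # probability zero by a perturbation; the subtree carries no mass,
            # so any value works — use 0
            p = 0.0
        if str(expr) in values:  # bare parameter reference: must be a probability
            if not -_SUM_TOL <= p <= 1 + _SUM_TOL:
                raise ValueError(
                    f"{where}: branch probability {expr!r} = {p} outside [0, 1]"
                )
        # derived expressions are clamped into [0, 1]: a perturbed scenario may
        # push a residual mass (e.g. unwarned carriers) below zero, which
        # means "none left", not an invalid tree
        p = min(max(p, 0.0), 1.0)
        total += p
        branches.append((p, child))
    if complement_at is not None:
        rest = 1.0 - total
        if rest < -_SUM_TOL:
            raise ValueError(f"{where}: branch probabilities exceed 1 ({total})")
        branches[complement_at] = (max(rest, 0.0), branches[complement_at][1])
    elif abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"{where}: branch probabilities sum to {total}, expected 1")
    return ChanceNode(
        label=str(raw.get("label", "node")),
        branches=tuple(branches),
        one_time_cost=cost,
        tally=raw.get("tally"),
    )


@_lru_cache(maxsize=8)
def _load_topology(path: str):
    # topology files are read many times per sensitivity analysis; cached by
    # path, so edits to a file already read in-process are not picked up
    return yaml.safe_load(Path(path).read_text())


def build_strategy(
    name: str,
    params: ParameterSet,
    topology_path: str | Path | None = None,
) -> ChanceNode:
    """Build one strategy's tree with probabilities resolved against ``params``."""
    if name not in STRATEGIES:
        raise ValueError(f"unknown strategy {name!r}; expected one of {STRATEGIES}")
    path = Path(topology_path) if topology_path is not None else default_topology_path()
    doc = _load_topology(str(path))
    if name not in doc:
        raise ValueError(f"{path}: no topology for strategy {name!r}")
    return _resolve(doc[name], params.values(), name)


@dataclass
class CohortAllocation:
    """Expected person-counts per outcome category for a given cohort size."""

    strategy: str
    cohort_size: float
    counts: dict[str, float] = field(default_factory=dict)
    tallies: dict[str, float] = field(default_factory=dict)
    screening_cost: float = 0.0  # expected one-time screening/diagnosis USD

    def total(self) -> float:
        return sum(self.counts.values())

    def rounded_tallies(self) -> dict[str, int]:
        """Reported integer tallies (half-up, applied at the end only)."""
        return {k: round_half_up(v) for k, v in self.tallies.items()}

    def initial_state_counts(self) -> dict[str, float]:
        """Expected persons per initial Markov state."""
        out: dict[str, float] = {}
        for cat, n in self.counts.items():
            state = CATEGORY_STATE[cat]
            out[state] = out.get(state, 0.0) + n
        return out

    def scaled(self, cohort_size: float) -> "CohortAllocation":
        if self.cohort_size == 0:
            raise ValueError("cannot rescale an empty-cohort allocation")
        k = cohort_size / self.cohort_size
        return CohortAllocation(
            strategy=self.strategy,
            cohort_size=cohort_size,
            counts={c: n * k for c, n in self.counts.items()},
            tallies={t: n * k for t, n in self.tallies.items()},
            screening_cost=self.screening_cost * k,
        )


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def evaluate_tree(tree: ChanceNode, cohort_size: float, *, strategy: str = "") -> CohortAllocation:
    """Propagate the cohort down the tree; expected counts per category."""
    if cohort_size < 0:
        raise ValueError("cohort_size must be >= 0")
    alloc = CohortAllocation(
        strategy=strategy,
        cohort_size=float(cohort_size),
        counts={c: 0.0 for c in CATEGORIES},
        tallies={t: 0.0 for t in TALLY_NAMES},
    )
    _walk(tree, float(cohort_size), alloc)
    if abs(alloc.total() - cohort_size) > 1e-6 * max(1.0, cohort_size):
        raise AssertionError(
            f"mass leak: leaves sum to {alloc.total()} for cohort {cohort_size}"
        )
    return alloc


def _walk(node: TreeNode, mass: float, alloc: CohortAllocation) -> None:
    if isinstance(node, OutcomeLeaf):
        alloc.counts[node.category] += mass
        for t in _CATEGORY_TALLIES.get(node.category, ()):
            alloc.tallies[t] += mass
        return
    alloc.screening_cost += mass * node.one_time_cost
    if node.tally is not None:
        alloc.tallies[node.tally] = alloc.tallies.get(node.tally, 0.0) + mass
    for p, child in node.branches:
        if p > 0.0:
            _walk(child, mass * p, alloc)


def screening_phase_cost(alloc: CohortAllocation, params: ParameterSet | None = None) -> float:
    """Total expected one-time screening + diagnosis cost for the cohort (USD).

    The cost is accumulated node-by-node during :func:`evaluate_tree`
    (hearing screen for everyone; gene screen for the strategy's screened
    population; hearing diagnosis for referrals and gene-screen failures;
    genetic diagnosis for gene-screen failures); ``params`` is accepted for
    interface symmetry and unused.
    """
    return alloc.screening_cost
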
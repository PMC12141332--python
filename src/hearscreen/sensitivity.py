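"""One-way (tornado) and probabilistic sensitivity analysis.

One-way analysis re-runs the whole tree+Markov+ICER pipeline at a
parameter's low and high bound (with sibling-group renormalization), all
other parameters at baseline.  Probabilistic analysis draws every non-fixed
parameter from a method-of-moments beta (probabilities, utilities) or gamma
(costs) distribution whose mean is the baseline; the published ranges are
treated as 95% intervals, so sd = (high - low)/(2*1.96).  Each Monte Carlo
draw uses its own spawned random substream, so enlarging the sample never
changes earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .markov_econ import net_monetary_benefit
from .params import Parameter, ParameterSet
from .pipeline import StrategyOutcome, evaluate_strategies, icer_pair

__all__ = [
    "TornadoEntry",
    "PSASample",
    "CEACCurve",
    "ceac",
    "ce_plane_quadrants",
    "fit_beta",
    "fit_gamma",
    "one_way",
    "run_psa",
    "tornado",
]

#: Ranges are read as 95% intervals: sd = width / (2 * 1.96).
RANGE_Z = 2 * 1.96

Model = Callable[[ParameterSet], dict[str, StrategyOutcome]]


# ---------------------------------------------------------------------------
# distribution fitting


def fit_beta(mean: float, low: float, high: float) -> tuple[float, float]:
    """Method-of-moments beta shapes with the given mean and range-implied sd.

    The variance is capped below mean*(1-mean) (at 99% of it) so the shapes
    stay positive; the fitted mean equals ``mean`` exactly.
    """
    if not 0 < mean < 1:
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    if low >= high:
        raise ValueError("low must be < high")
    sd = (high - low) / RANGE_Z
    var = min(sd * sd, 0.99 * mean * (1.0 - mean))
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma(mean: float, low: float, high: float) -> tuple[float, float]:
    """Method-of-moments gamma (shape, scale): shape*scale = mean exactly."""
    if mean <= 0:
        raise ValueError(f"gamma mean must be > 0, got {mean}")
    if low >= high:
        raise ValueError("low must be < high")
    sd = (high - low) / RANGE_Z
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


# ---------------------------------------------------------------------------
# one-way sensitivity (tornado)


@dataclass
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_low: float | None
    icer_high: float | None
    baseline_icer: float | None = None

    @property
    def span(self) -> float:
        if self.icer_low is None or self.icer_high is None:
            return math.nan
        return abs(self.icer_high - self.icer_low)

    @property
    def degenerate(self) -> bool:
        return self.low == self.high


def one_way(
    param_name: str,
    params: ParameterSet,
    model: Model,
    pair: tuple[str, str],
    baseline_icer: float | None = None,
) -> TornadoEntry:
    """Pipeline ICER for ``pair = (strategy, reference)`` at the parameter's
    low and high bound."""
    p: Parameter = params[param_name]
    icers = []
    for bound in (p.low, p.high):
        if bound == p.baseline:
            icers.append(
                baseline_icer
                if baseline_icer is not None
                else icer_pair(model(params), *pair)
            )
        else:
            perturbed = params.override(param_name, bound)
            icers.append(icer_pair(model(perturbed), *pair))
    return TornadoEntry(param_name, p.low, p.high, icers[0], icers[1], baseline_icer)


def tornado(
    params: ParameterSet,
    model: Model,
    pair: tuple[str, str],
    top: int | None = 20,
    parameter_names: Sequence[str] | None = None,
) -> list[TornadoEntry]:
    """All one-way entries for a strategy pair, sorted by span descending."""
    names = list(parameter_names) if parameter_names is not None else sorted(params.parameters)
    baseline_icer = icer_pair(model(params), *pair)
    entries = [one_way(n, params, model, pair, baseline_icer) for n in names]
    entries.sort(key=lambda e: (-1.0 if math.isnan(e.span) else e.span), reverse=True)
    return entries[:top] if top is not None else entries


# ---------------------------------------------------------------------------
# probabilistic sensitivity


@dataclass
class PSASample:
    draw: int
    values: dict[str, float]  # post-renormalization parameter values
    outcomes: dict[str, tuple[float, float]]  # strategy -> (cost, qaly)


@dataclass
class PSAResult:
    samples: list[PSASample]
    raw_draws: dict[str, np.ndarray] = field(default_factory=dict)  # pre-renormalization
    strategies: tuple[str, ...] = ()

    def __len__(self):
        return len(self.samples)

    def cost_qaly(self, strategy: str) -> tuple[np.ndarray, np.ndarray]:
        c = np.array([s.outcomes[strategy][0] for s in self.samples])
        q = np.array([s.outcomes[strategy][1] for s in self.samples])
        return c, q


def _sample_one(params: ParameterSet, rng: np.random.Generator) -> dict[str, float]:
    draws: dict[str, float] = {}
    for name in sorted(params.parameters):
        p = params[name]
        if p.psa_dist == "fixed" or p.degenerate:
            draws[name] = p.baseline
        elif p.psa_dist == "beta":
            a, b = fit_beta(p.baseline, p.low, p.high)
            draws[name] = float(rng.beta(a, b))
        elif p.psa_dist == "gamma":
            shape, scale = fit_gamma(p.baseline, p.low, p.high)
            draws[name] = float(rng.gamma(shape, scale))
        else:  # pragma: no cover - parameter validation forbids this
            raise ValueError(f"{name}: cannot sample dist {p.psa_dist!r}")
    return draws


def _renormalize_groups(draws: dict[str, float], params: ParameterSet) -> dict[str, float]:
    values = dict(draws)
    for group in params.groups:
        s = sum(values[n] for n in group)
        if s <= 0:
            raise ValueError(f"sampled probability group {group} sums to {s}")
        for n in group:
            values[n] = values[n] / s
    return values


def run_psa(
    params: ParameterSet,
    n: int,
    seed: int,
    model: Model | None = None,
    lt=None,
    discount_rate: float | None = None,
) -> PSAResult:
    """Seeded Monte Carlo over the parameter distributions; full pipeline per draw."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if model is None:
        model = lambda p: evaluate_strategies(p, lt=lt, discount_rate=discount_rate)
    children = np.random.SeedSequence(seed).spawn(n)
    samples: list[PSASample] = []
    raw: dict[str, list[float]] = {name: [] for name in sorted(params.parameters)}
    strategies: tuple[str, ...] = ()
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        draws = _sample_one(params, rng)
        for name, v in draws.items():
            raw[name].append(v)
        values = _renormalize_groups(draws, params)
        outcomes = model(params.with_values(values))
        strategies = tuple(outcomes)
        samples.append(
            PSASample(i, values, {k: (o.cost, o.qaly) for k, o in outcomes.items()})
        )
    return PSAResult(
        samples=samples,
        raw_draws={k: np.array(v) for k, v in raw.items()},
        strategies=strategies,
    )


def ce_plane_quadrants(
    samples: Sequence[PSASample], pair: tuple[str, str]
) -> dict[str, float]:
    """Fractions of draws per cost-effectiveness-plane quadrant.

    x = incremental QALY, y = incremental cost of ``pair[0]`` vs ``pair[1]``;
    quadrants are counted counter-clockwise from (+, +); draws on an axis are
    assigned to the positive side.
    """
    if not samples:
        raise ValueError("need at least one sample")
    counts = dict.fromkeys(("q1", "q2", "q3", "q4"), 0)
    strategy, reference = pair
    for s in samples:
        c1, q1 = s.outcomes[strategy]
        c0, q0 = s.outcomes[reference]
        de, dc = q1 - q0, c1 - c0
        if de >= 0:
            counts["q1" if dc >= 0 else "q4"] += 1
        else:
            counts["q2" if dc >= 0 else "q3"] += 1
    n = len(samples)
    return {k: v / n for k, v in counts.items()}


@dataclass
class CEACCurve:
    """Probability each strategy has the greatest net monetary benefit, by WTP."""

    wtp: np.ndarray
    strategies: tuple[str, ...]
    probabilities: np.ndarray  # shape (len(wtp), len(strategies))

    def prob(self, strategy: str) -> np.ndarray:
        return self.probabilities[:, self.strategies.index(strategy)]

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, w in enumerate(self.wtp):
            for j, s in enumerate(self.strategies):
                rows.append({"wtp": float(w), "strategy": s, "probability": self.probabilities[i, j]})
        return pd.DataFrame(rows)


def ceac(samples: Sequence[PSASample], wtp_grid: Sequence[float]) -> CEACCurve:
    """Cost-effectiveness acceptability curves; ties split equally."""
    if not samples:
        raise ValueError("need at least one sample")
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if np.any(np.diff(wtp) < 0):
        raise ValueError("wtp_grid must be ascending")
    strategies = tuple(samples[0].outcomes)
    probs = np.zeros((wtp.size, len(strategies)))
    for s in samples:
        nmbs = np.array(
            [
                [net_monetary_benefit(*s.outcomes[name], w) for name in strategies]
                for w in wtp
            ]
        )
        best = nmbs.max(axis=1, keepdims=True)
        tied = nmbs == best
        probs += tied / tied.sum(axis=1, keepdims=True)
    probs /= len(samples)
    return CEACCurve(wtp=wtp, strategies=strategies, probabilities=probs)
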
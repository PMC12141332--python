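"""Model parameters: loading, validation, ranges, and overrides.

The bundled default configuration carries every baseline probability, cost
(USD), and utility weight of the screening model, the one-way sensitivity
ranges, and the probabilistic-sensitivity distribution kind (beta for
probabilities/utilities, gamma for costs, or fixed).  Probabilities that sit
on the same chance node are declared as *probability groups*; overriding one
member renormalizes its siblings proportionally so the group keeps summing
to one.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ConfigError",
    "Parameter",
    "ParameterSet",
    "apply_percent_range",
    "load_parameters",
    "write_parameters",
]

_ROLES = {"probability", "cost", "utility", "rate", "structural"}
_DISTS = {"beta", "gamma", "fixed"}

GROUP_TOL = 1e-9


class ConfigError(ValueError):
    """Raised for a malformed or inconsistent model configuration."""


def apply_percent_range(baseline: float, pct: float, *, clamp_unit: bool = False):
    """Return ``(baseline*(1-pct), baseline*(1+pct))``.

    With ``clamp_unit=True`` (probabilities and utilities) the result is
    clamped into [0, 1].
    """
    if pct < 0:
        raise ValueError("pct must be >= 0")
    low = baseline * (1.0 - pct)
    high = baseline * (1.0 + pct)
    if clamp_unit:
        low = min(max(low, 0.0), 1.0)
        high = min(max(high, 0.0), 1.0)
    return low, high


@dataclass(frozen=True)
class Parameter:
    name: str
    role: str
    baseline: float
    low: float
    high: float
    psa_dist: str = "fixed"
    units: str = ""

    def __post_init__(self):
        if self.role not in _ROLES:
            raise ConfigError(f"{self.name}: unknown role {self.role!r}")
        if self.psa_dist not in _DISTS:
            raise ConfigError(f"{self.name}: unknown dist {self.psa_dist!r}")
        if not (self.low <= self.baseline <= self.high):
            raise ConfigError(
                f"{self.name}: low <= baseline <= high violated "
                f"({self.low}, {self.baseline}, {self.high})"
            )
        if self.role in ("probability", "utility"):
            if self.low < 0 or self.high > 1:
                raise ConfigError(f"{self.name}: {self.role} range outside [0, 1]")
            if self.psa_dist == "gamma":
                raise ConfigError(f"{self.name}: {self.role} cannot be gamma-distributed")
        if self.role == "cost":
            if self.low < 0:
                raise ConfigError(f"{self.name}: cost low bound must be >= 0")
            if self.psa_dist == "beta":
                raise ConfigError(f"{self.name}: cost cannot be beta-distributed")

    @property
    def degenerate(self) -> bool:
        return self.low == self.high


@dataclass
class ParameterSet:
    """A validated bundle of named parameters plus run settings."""

    parameters: dict[str, Parameter]
    groups: list[list[str]] = field(default_factory=list)
    cohort_size: int = 9_560_000
    horizon: int = 78
    discount_rate: float = 0.03
    wtp_grid: list[float] = field(default_factory=list)

    def __post_init__(self):
        self._validate()

    # -- access ---------------------------------------------------------
    def value(self, name: str) -> float:
        try:
            return self.parameters[name].baseline
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def __getitem__(self, name: str) -> Parameter:
        return self.parameters[name]

    def __contains__(self, name: str) -> bool:
        return name in self.parameters

    def values(self) -> dict[str, float]:
        return {k: p.baseline for k, p in self.parameters.items()}

    def group_of(self, name: str) -> list[str] | None:
        for g in self.groups:
            if name in g:
                return g
        return None

    def sweepable(self) -> list[str]:
        """Parameter names with a nondegenerate one-way range."""
        return [k for k, p in self.parameters.items() if not p.degenerate]

    # -- mutation-by-copy ----------------------------------------------
    def override(self, name: str, value: float) -> "ParameterSet":
        """Return a copy with ``name`` set to ``value``.

        Siblings in the same declared probability group are rescaled
        proportionally so the group still sums to one.
        """
        if name not in self.parameters:
            raise KeyError(f"unknown parameter {name!r}")
        p = self.parameters[name]
        if p.role in ("probability", "utility") and not (0.0 <= value <= 1.0):
            raise ValueError(f"{name}: override {value} outside [0, 1]")
        if p.role == "cost" and value < 0:
            raise ValueError(f"{name}: cost override must be >= 0")

        new = copy.deepcopy(self)
        new.parameters[name] = _rebase(p, value)
        group = self.group_of(name)
        if group is not None:
            others = [g for g in group if g != name]
            rest_old = sum(self.parameters[g].baseline for g in others)
            rest_new = 1.0 - value
            if rest_new < -GROUP_TOL:
                raise ValueError(f"{name}: override {value} leaves group sum > 1")
            for g in others:
                if rest_old > 0:
                    v = self.parameters[g].baseline * rest_new / rest_old
                else:  # degenerate: split the remainder evenly
                    v = rest_new / len(others)
                new.parameters[g] = _rebase(self.parameters[g], max(v, 0.0))
        new._validate()
        return new

    def with_values(self, values: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with baselines replaced wholesale (no renormalization).

        Used by the probabilistic sensitivity analysis after it has already
        renormalized sampled probability groups itself.
        """
        new = copy.deepcopy(self)
        for name, v in values.items():
            if name not in new.parameters:
                raise KeyError(f"unknown parameter {name!r}")
            new.parameters[name] = _rebase(new.parameters[name], v)
        new._validate(check_groups=False)
        return new

    # -- validation -----------------------------------------------------
    def _validate(self, check_groups: bool = True):
        if self.cohort_size < 0:
            raise ConfigError("run.cohort_size must be >= 0")
        if self.horizon < 1:
            raise ConfigError("run.horizon must be >= 1")
        if self.discount_rate <= -1:
            raise ConfigError("run.discount_rate must exceed -1")
        if any(b > a for a, b in zip(self.wtp_grid[1:], self.wtp_grid[:-1])):
            raise ConfigError("run.wtp_grid must be ascending")
        seen: set[str] = set()
        for g in self.groups:
            for name in g:
                if name not in self.parameters:
                    raise ConfigError(f"probability_groups: unknown parameter {name!r}")
                if name in seen:
                    raise ConfigError(f"probability_groups: {name!r} in two groups")
                seen.add(name)
            if check_groups:
                s = sum(self.parameters[n].baseline for n in g)
                if abs(s - 1.0) > GROUP_TOL:
                    raise ConfigError(
                        f"probability group {g} sums to {s!r}, expected 1"
                    )

    def __eq__(self, other):
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return (
            self.parameters == other.parameters
            and self.groups == other.groups
            and self.cohort_size == other.cohort_size
            and self.horizon == other.horizon
            and self.discount_rate == other.discount_rate
            and self.wtp_grid == other.wtp_grid
        )


def _rebase(p: Parameter, value: float) -> Parameter:
    low = min(p.low, value)
    high = max(p.high, value)
    return Parameter(p.name, p.role, value, low, high, p.psa_dist, p.units)


# ---------------------------------------------------------------------------
# serialization


def default_config_path() -> Path:
    return Path(resources.files("hearscreen").joinpath("data/default_config.yaml"))


def _parse_parameter(name: str, raw) -> Parameter:
    if not isinstance(raw, Mapping):
        raise ConfigError(f"parameters.{name}: expected a mapping")
    unknown = set(raw) - {"role", "baseline", "low", "high", "pct_range", "dist", "units"}
    if unknown:
        raise ConfigError(f"parameters.{name}: unknown keys {sorted(unknown)}")
    try:
        role = raw["role"]
        baseline = float(raw["baseline"])
    except KeyError as e:
        raise ConfigError(f"parameters.{name}: missing required key {e.args[0]!r}") from None
    dist = raw.get("dist", "fixed")
    units = raw.get("units", "USD" if role == "cost" else "")
    if "pct_range" in raw:
        if "low" in raw or "high" in raw:
            raise ConfigError(f"parameters.{name}: give pct_range or low/high, not both")
        low, high = apply_percent_range(
            baseline, float(raw["pct_range"]), clamp_unit=role in ("probability", "utility")
        )
    else:
        try:
            low, high = float(raw["low"]), float(raw["high"])
        except KeyError as e:
            raise ConfigError(
                f"parameters.{name}: missing required key {e.args[0]!r}"
            ) from None
    return Parameter(name, role, baseline, low, high, dist, units)


def load_parameters(config_path: str | Path | None = None) -> ParameterSet:
    """Load and validate a model configuration.

    With no argument, the bundled default configuration (the published
    baseline parameter table) is used.
    """
    path = Path(config_path) if config_path is not None else default_config_path()
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"malformed YAML in {path}: {e}") from e
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(doc) - {"run", "parameters", "probability_groups"}
    if unknown:
        raise ConfigError(f"unknown top-level sections {sorted(unknown)}")
    raw_params = doc.get("parameters")
    if not isinstance(raw_params, Mapping) or not raw_params:
        raise ConfigError("missing or empty 'parameters' section")
    parameters = {name: _parse_parameter(name, raw) for name, raw in raw_params.items()}
    groups = [list(g) for g in doc.get("probability_groups", [])]
    run = doc.get("run", {})
    if not isinstance(run, Mapping):
        raise ConfigError("'run' section must be a mapping")
    return ParameterSet(
        parameters=parameters,
        groups=groups,
        cohort_size=int(run.get("cohort_size", 9_560_000)),
        horizon=int(run.get("horizon", 78)),
        discount_rate=float(run.get("discount_rate", 0.03)),
        wtp_grid=[float(w) for w in run.get("wtp_grid", [])],
    )


def write_parameters(params: ParameterSet, path: str | Path) -> None:
    """Serialize a ParameterSet so that ``load_parameters`` round-trips it."""
    doc = {
        "run": {
            "cohort_size": params.cohort_size,
            "horizon": params.horizon,
            "discount_rate": params.discount_rate,
            "wtp_grid": list(params.wtp_grid),
        },
        "parameters": {
            p.name: {
                "role": p.role,
                "baseline": p.baseline,
                "low": p.low,
                "high": p.high,
                "dist": p.psa_dist,
                **({"units": p.units} if p.units else {}),
            }
            for p in params.parameters.values()
        },
        "probability_groups": [list(g) for g in params.groups],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
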
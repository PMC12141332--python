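"""Synthetic annual life table (Gompertz–Makeham with an infant-mortality term).

The cohort model needs one input the parameter table cannot supply: the
probability of dying within each year of age, q(a).  The published analysis
took these from a national census yearbook; here an equivalent table is
generated parametrically and shipped as a CSV fixture so the model runs
self-contained.  Age-1+ hazard is Makeham's ``c + b*exp(g*a)``; age 0 gets
its own infant-mortality probability.  The bundled defaults are calibrated
so life expectancy at birth is ≈78 years, matching the statistical-yearbook
figure that motivates the 78-year simulation horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DEFAULTS",
    "LifeTable",
    "life_expectancy",
    "load_life_table",
    "make_life_table",
    "write_life_table",
]

#: Frozen generator defaults; chosen once so that e0(make_life_table(**DEFAULTS))
#: falls in [77, 79] years.
DEFAULTS = dict(
    infant_q=0.005,
    makeham_c=0.0003,
    gompertz_b=2e-5,
    gompertz_g=0.101,
    horizon=110,
)


@dataclass(frozen=True)
class LifeTable:
    """Annual probabilities of death q[a], a = 0..len-1, conditional on
    being alive at exact age a."""

    q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 1 or q.size < 1:
            raise ValueError("life table must be a non-empty 1-D array")
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("all q must lie in [0, 1]")
        object.__setattr__(self, "q", q)

    def __len__(self) -> int:
        return self.q.size

    def survival(self) -> np.ndarray:
        """S(a) = probability of surviving to exact age a (S(0) = 1)."""
        return np.concatenate([[1.0], np.cumprod(1.0 - self.q)[:-1]])

    def truncate(self, horizon: int) -> "LifeTable":
        if horizon > len(self):
            raise ValueError(
                f"life table has {len(self)} ages, cannot truncate to {horizon}"
            )
        return LifeTable(self.q[:horizon])


def make_life_table(
    infant_q: float = DEFAULTS["infant_q"],
    makeham_c: float = DEFAULTS["makeham_c"],
    gompertz_b: float = DEFAULTS["gompertz_b"],
    gompertz_g: float = DEFAULTS["gompertz_g"],
    horizon: int = DEFAULTS["horizon"],
) -> LifeTable:
    """Build q(a): q[0] = infant_q, q[a>=1] = 1 - exp(-(c + b*e^{g a}))."""
    if min(infant_q, makeham_c, gompertz_b, gompertz_g) < 0:
        raise ValueError("all rate parameters must be >= 0")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    a = np.arange(horizon, dtype=float)
    with np.errstate(over="ignore"):
        hazard = makeham_c + gompertz_b * np.exp(gompertz_g * a)
        q = 1.0 - np.exp(-hazard)
    q[0] = infant_q
    return LifeTable(np.clip(q, 0.0, 1.0))


def life_expectancy(lt: LifeTable) -> float:
    """Expected person-years lived within the table, sum_a S(a)."""
    return float(lt.survival().sum())


def write_life_table(lt: LifeTable, path: str | Path) -> None:
    lines = ["age,qx"] + [f"{a},{float(q)!r}" for a, q in enumerate(lt.q)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_life_table(path: str | Path) -> LifeTable:
    """Read an ``age,qx`` CSV; ages must be contiguous from 0."""
    path = Path(path)
    rows = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not rows or rows[0].strip().lower() != "age,qx":
        raise ValueError(f"{path}: expected header 'age,qx'")
    ages, qs = [], []
    for ln in rows[1:]:
        a_s, q_s = ln.split(",")
        ages.append(int(a_s))
        qs.append(float(q_s))
    if ages != list(range(len(ages))):
        raise ValueError(f"{path}: ages must be contiguous from 0")
    q = np.array(qs, dtype=float)
    if np.any(q < 0) or np.any(q > 1) or np.any(~np.isfinite(q)):
        raise ValueError(f"{path}: qx values must lie in [0, 1]")
    return LifeTable(q)


def default_life_table_path() -> Path:
    from importlib import resources

    return Path(resources.files("hearscreen").joinpath("data/lifetable.csv"))


def default_life_table() -> LifeTable:
    """The bundled calibrated fixture (regenerable via ``make_life_table``)."""
    path = default_life_table_path()
    if path.exists():
        return load_life_table(path)
    return make_life_table()
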
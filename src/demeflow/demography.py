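"""Age-structured mortality, fertility and founder age distributions.

Mortality follows a Siler hazard (infant + background + senescent
terms) fitted on a 0-108 year axis, compressed onto 0-55 years and
doubled, mimicking the short lifespans of Neolithic farming
communities. Defaults were calibrated so that discrete life expectancy
at birth is ~28 years and the implied stationary age structure is close
to 40% children (0-15), 25% youth (16-25), 25% prime (26-35) and 10%
middle age (36-50).

Fertility is a natural-fertility (pre-birth-control) curve of annual
birth probabilities for married women aged 18-45, peaking in the early
twenties; its sum (a completed-fertility proxy) is ~6.5 births.

Both schedules are proxies for poorly known prehistoric values and can
be overridden from two-column CSV files (``age,probability``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MAX_AGE",
    "DEFAULT_SILER_PARAMS",
    "MortalitySchedule",
    "FertilitySchedule",
    "AgeClassSpec",
    "DEFAULT_AGE_CLASSES",
    "FECUNDITY_RANGE",
    "build_mortality_schedule",
    "build_fertility_schedule",
    "load_schedule_csv",
    "init_ages",
    "sample_max_children",
]

MAX_AGE = 55
_BASE_AGE_SPAN = 108  # age axis of the modern source life table

# Siler hazard a1*exp(-b1*a) + a2 + a3*exp(b3*a) on the 0-108 axis.
DEFAULT_SILER_PARAMS = (0.11, 1.0, 0.001, 5e-5, 0.095)

#: Poisson fecundity means considered plausible for Neolithic groups.
FECUNDITY_RANGE = (3.5, 7.0)

FERTILE_AGE_MIN = 18
FERTILE_AGE_MAX = 45

# Annual birth probabilities for married women, ages 18..45.
_DEFAULT_FERTILITY = np.array(
    [0.24, 0.29, 0.34, 0.35, 0.37, 0.37, 0.37, 0.35, 0.35, 0.34,
     0.34, 0.32, 0.30, 0.29, 0.27, 0.26, 0.24, 0.22, 0.19, 0.18,
     0.14, 0.13, 0.10, 0.08, 0.05, 0.03, 0.02, 0.01]
)


@dataclass(frozen=True)
class MortalitySchedule:
    """Per-age annual death probabilities for ages 0..max_age."""

    hazard: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.hazard, dtype=float)
        object.__setattr__(self, "hazard", h)
        if ((h < 0) | (h > 1)).any():
            raise ValueError("death probabilities must lie in [0, 1]")
        if h[-1] != 1.0:
            raise ValueError("hazard at the maximum age must be 1")
        if (np.diff(h[30:]) < -1e-12).any():
            raise ValueError("hazard must be non-decreasing after age 30")

    @property
    def max_age(self) -> int:
        return len(self.hazard) - 1

    def at(self, ages) -> np.ndarray:
        """Hazard for (an array of) ages; ages beyond the table die surely."""
        a = np.minimum(np.asarray(ages), self.max_age)
        return self.hazard[a]

    def survivorship(self) -> np.ndarray:
        """l(a): probability of being alive at the start of age a."""
        return np.concatenate([[1.0], np.cumprod(1.0 - self.hazard)[:-1]])

    def life_expectancy(self) -> float:
        return float(self.survivorship().sum())


@dataclass(frozen=True)
class FertilitySchedule:
    """Annual birth probability by maternal age, zero outside 18-45."""

    rate: np.ndarray  # indexed by age 0..max_age

    def __post_init__(self):
        r = np.asarray(self.rate, dtype=float)
        object.__setattr__(self, "rate", r)
        if ((r < 0) | (r > 1)).any():
            raise ValueError("birth probabilities must lie in [0, 1]")

    def at(self, ages) -> np.ndarray:
        a = np.clip(np.asarray(ages), 0, len(self.rate) - 1)
        return self.rate[a]

    def completed_fertility_proxy(self) -> float:
        """Sum of annual rates: expected births if married the whole window."""
        return float(self.rate.sum())


def _siler(ages: np.ndarray, params) -> np.ndarray:
    a1, b1, a2, a3, b3 = params
    return a1 * np.exp(-b1 * ages) + a2 + a3 * np.exp(b3 * ages)


def build_mortality_schedule(
    max_age: int = MAX_AGE,
    doubling: float = 2.0,
    siler_params=DEFAULT_SILER_PARAMS,
    base_span: int = _BASE_AGE_SPAN,
) -> MortalitySchedule:
    """Compressed, scaled Siler mortality.

    The baseline hazard is evaluated on the 0..base_span axis, the age
    axis is compressed to 0..max_age, hazards are multiplied by
    ``doubling`` and clipped to [0, 1], and the terminal hazard is set
    to 1 so no agent outlives ``max_age``.
    """
    if max_age < 50:
        raise ValueError("max_age must be at least 50")
    if not doubling > 0:
        raise ValueError("doubling factor must be positive")
    ages = np.arange(max_age + 1) * (base_span / max_age)
    hazard = np.clip(doubling * _siler(ages, siler_params), 0.0, 1.0)
    hazard[-1] = 1.0
    return MortalitySchedule(hazard)


def build_fertility_schedule(
    table: pd.DataFrame | None = None, max_age: int = MAX_AGE
) -> FertilitySchedule:
    """Default natural-fertility curve, or one loaded from a table.

    ``table`` must have columns ``age`` and ``probability``; ages not
    listed get probability 0.
    """
    rate = np.zeros(max_age + 1)
    if table is None:
        rate[FERTILE_AGE_MIN : FERTILE_AGE_MAX + 1] = _DEFAULT_FERTILITY
    else:
        _check_columns(table, ("age", "probability"), "fertility table")
        ages = table["age"].to_numpy(dtype=int)
        probs = table["probability"].to_numpy(dtype=float)
        if ((probs < 0) | (probs > 1)).any():
            raise ValueError("fertility probabilities must lie in [0, 1]")
        if (ages < 0).any() or (ages > max_age).any():
            raise ValueError("fertility ages outside 0..max_age")
        rate[ages] = probs
    return FertilitySchedule(rate)


def _check_columns(df: pd.DataFrame, expected: tuple[str, ...], what: str):
    if tuple(df.columns) != expected:
        raise ValueError(
            f"{what} must have exactly the columns {list(expected)}, "
            f"got {list(df.columns)}"
        )


def load_schedule_csv(path, kind: str):
    """Load a mortality or fertility override from a strict two-column CSV."""
    df = pd.read_csv(path)
    _check_columns(df, ("age", "probability"), f"{kind} schedule {path}")
    if kind == "mortality":
        ages = df["age"].to_numpy(dtype=int)
        if not np.array_equal(ages, np.arange(len(ages))):
            raise ValueError("mortality schedule must list every age from 0")
        return MortalitySchedule(df["probability"].to_numpy(dtype=float))
    if kind == "fertility":
        return build_fertility_schedule(df)
    raise ValueError(f"unknown schedule kind {kind!r}")


@dataclass(frozen=True)
class AgeClassSpec:
    """Founding age brackets with their population proportions."""

    brackets: tuple[tuple[int, int], ...] = ((0, 15), (16, 25), (26, 35), (36, 50))
    proportions: tuple[float, ...] = (0.3, 0.3, 0.3, 0.1)

    def __post_init__(self):
        if len(self.brackets) != len(self.proportions):
            raise ValueError("one proportion per bracket required")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("age-class proportions must sum to 1")


DEFAULT_AGE_CLASSES = AgeClassSpec()


def allocate_counts(n: int, proportions) -> np.ndarray:
    """Largest-remainder allocation of n individuals to classes."""
    props = np.asarray(proportions, dtype=float)
    raw = n * props
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    if remainder:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def init_ages(n: int, spec: AgeClassSpec = DEFAULT_AGE_CLASSES, rng=None) -> np.ndarray:
    """Founding ages: deterministic class counts, uniform ages within class."""
    if n <= 0:
        raise ValueError("n must be positive")
    if rng is None:
        rng = np.random.default_rng()
    counts = allocate_counts(n, spec.proportions)
    ages = np.concatenate(
        [
            rng.integers(lo, hi + 1, size=c)
            for (lo, hi), c in zip(spec.brackets, counts)
        ]
    )
    return ages.astype(np.int16)


def sample_max_children(fecundity_mean: float, rng, size=None):
    """Poisson family-size quota; warns outside the plausible prior range."""
    lo, hi = FECUNDITY_RANGE
    if not lo <= fecundity_mean <= hi:
        warnings.warn(
            f"fecundity mean {fecundity_mean} outside the plausible "
            f"range [{lo}, {hi}]",
            stacklevel=2,
        )
    return rng.poisson(fecundity_mean, size=size)
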
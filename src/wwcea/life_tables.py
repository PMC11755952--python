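"""Age-specific background mortality and synthetic test inputs.

The model needs an annual all-cause death probability q(age) for every age
the cohort passes through. A bundled pediatric-range table is provided, as
well as generators of synthetic life tables and synthetic-but-valid
parameter sets so that every downstream stage can be exercised without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .params import (
    ModelParameters,
    ParamDistribution,
    ParameterError,
    default_parameters,
)

_BUNDLED_RESOURCE = "canada_2022_synthetic_life_table.csv"


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probabilities indexed by integer age.

    Ages must be contiguous; probabilities need not be monotone (infant
    mortality exceeds childhood mortality).
    """

    ages: tuple[int, ...]
    q_annual: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.q_annual):
            raise ParameterError("ages and q_annual must have equal length")
        if len(self.ages) == 0:
            raise ParameterError("life table must not be empty")
        if list(self.ages) != list(range(self.ages[0], self.ages[0] + len(self.ages))):
            raise ParameterError("life-table ages must be contiguous integers")
        for q in self.q_annual:
            if not 0.0 <= q <= 1.0:
                raise ParameterError(f"q_annual out of [0, 1]: {q}")

    @property
    def min_age(self) -> int:
        return self.ages[0]

    @property
    def max_age(self) -> int:
        return self.ages[-1]

    def lookup(self, age: int) -> float:
        """Annual death probability at integer ``age``."""
        if not self.min_age <= age <= self.max_age:
            raise ParameterError(
                f"age {age} outside life-table coverage [{self.min_age}, {self.max_age}]"
            )
        return self.q_annual[age - self.min_age]

    def covers(self, start_age: int, horizon_years: int) -> bool:
        return self.min_age <= start_age and start_age + horizon_years - 1 <= self.max_age

    # -- CSV round trip ------------------------------------------------

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "q_annual": self.q_annual}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        if list(df.columns) != ["age", "q_annual"]:
            raise ParameterError(
                f"life-table CSV must have columns ['age', 'q_annual'], got {list(df.columns)}"
            )
        ages = pd.to_numeric(df["age"], errors="coerce")
        qs = pd.to_numeric(df["q_annual"], errors="coerce")
        if ages.isna().any() or qs.isna().any():
            raise ParameterError("non-numeric entry in life-table CSV")
        if not (ages == ages.astype(int)).all():
            raise ParameterError("ages must be integers")
        return cls(tuple(int(a) for a in ages), tuple(float(q) for q in qs))


def bundled_life_table() -> LifeTable:
    """The life table shipped with the package (ages 0-25).

    Synthetic stand-in for the Statistics Canada 2022 both-sexes life table
    (catalogue 84-537-X): values are plausible pediatric-range annual death
    probabilities of the right order of magnitude, not transcribed official
    figures. Background mortality is nearly identical between the two
    management strategies, so model increments are insensitive to the exact
    values.
    """
    ref = resources.files("wwcea.data").joinpath(_BUNDLED_RESOURCE)
    with resources.as_file(ref) as path:
        return LifeTable.from_csv(path)


def synthetic_life_table(
    seed: int, base_q: float, growth: float = 0.0, max_age: int = 25
) -> LifeTable:
    """Deterministic geometric life table q(age) = min(1, base_q*(1+growth)^age).

    ``seed`` is accepted for interface symmetry with the other generators;
    the table is a deterministic function of its arguments.
    """
    if not 0.0 <= base_q < 1.0:
        raise ParameterError(f"base_q must be in [0, 1), got {base_q}")
    if growth < 0:
        raise ParameterError("growth must be >= 0")
    ages = tuple(range(0, max_age + 1))
    qs = tuple(min(1.0, base_q * (1.0 + growth) ** a) for a in ages)
    return LifeTable(ages, qs)


def synthetic_parameters(seed: int) -> ModelParameters:
    """A random but valid parameter set with the base case's distributional
    structure (beta-distributed probabilities and utilities, gamma costs).

    Reproducible by seed; satisfies every container invariant, so it can
    drive property tests of the downstream stages.
    """
    rng = np.random.default_rng(seed)
    params = default_parameters()

    draws = {
        "epi.p_severe_annual": ParamDistribution("beta", 66, 696),
        "epi.p_biphasic": ParamDistribution("beta", 184, 3806),
        "epi.p_fatal_overall_annual": ParamDistribution("beta", 100, 1.4e8),
        "epi.p_fatal_hosp": ParamDistribution("beta", 46, 1.0e4),
        "epi.p_remission_annual": ParamDistribution("beta", 47, 771),
        "cost.p_eai_before_ed": ParamDistribution("beta", 7.6, 6.5),
        "cost.ambulance_cost": ParamDistribution("gamma", 100, 8.5),
        "cost.ed_visit_medical_cost": ParamDistribution("gamma", 100, 3.0),
        "cost.ed_oop_cost": ParamDistribution("gamma", 100, 0.89),
        "cost.annual_fa_medical_cost": ParamDistribution("gamma", 100, 14),
        "cost.annual_fa_oop_cost": ParamDistribution("gamma", 100, 24),
        "cost.annual_fa_indirect_cost": ParamDistribution("gamma", 100, 42),
        "util.u_food_allergy": ParamDistribution("beta", 7.1, 0.62),
        "util.u_remission": ParamDistribution("beta", 8.8, 0.66),
    }
    for path, dist in draws.items():
        params.set_path(path, dist.sample(rng))
    # p_no_eai is the complement of a beta-distributed possession probability
    params.epi.p_no_eai = 1.0 - ParamDistribution("beta", 8.5, 0.88).sample(rng)
    # disutility cannot exceed the food-allergy utility (reaction-day
    # utility is floored at zero)
    d = ParamDistribution("beta", 0.17, 1.7).sample(rng)
    params.util.disutility_reaction = min(d, params.util.u_food_allergy)
    params = params.refresh_derived()
    params.validate()
    return params
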
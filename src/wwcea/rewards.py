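"""Costs, utilities, discounting and incremental cost-effectiveness.

Rewards attach to the cohort trace in two ways: daily state rewards
(annual background costs spread uniformly over 365 days; utilities scaled
to per-day QALY fractions) and per-entry event costs on the one-day
reaction states (replacement autoinjector, ambulance + ED bundle,
hospital day extras). Because the reaction-day states last exactly one
cycle, entry flow equals state occupancy and both kinds can be folded into
a single per-cycle reward vector.

Discounting is continuous per cycle at ``(1 + r)^(-t/365)`` from day 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .markov import ACD, ED, FD, HOSP, NR, N_STATES, REM, WW, CohortTrace
from .params import (
    IMMEDIATE_ED,
    PERSPECTIVES,
    STRATEGIES,
    WATCHFUL_WAITING,
    EconSettings,
    ModelParameters,
    ParameterError,
)

CURRENCY = "CAD2022"

#: states that last exactly one cycle, so entry costs can be charged
#: against occupancy
_ONE_DAY_STATES = (WW, ED, HOSP)


@dataclass(frozen=True)
class RewardSpec:
    """Per-cycle rewards for one strategy under one perspective."""

    daily_cost: np.ndarray     # (7,) CAD accrued per day in each state
    daily_utility: np.ndarray  # (7,) QALY accrued per day in each state
    entry_cost: np.ndarray     # (7,) CAD charged on entering a state
    strategy: str = WATCHFUL_WAITING
    perspective: str = "healthcare"

    def __post_init__(self) -> None:
        for name in ("daily_cost", "daily_utility", "entry_cost"):
            arr = getattr(self, name)
            if arr.shape != (N_STATES,):
                raise ParameterError(f"{name} must have shape (7,)")
        if np.any(self.daily_cost < 0) or np.any(self.entry_cost < 0):
            raise ParameterError("costs must be non-negative")
        if np.any(self.daily_utility < 0) or np.any(self.daily_utility > 1 / 365):
            raise ParameterError("daily utility must lie in [0, 1/365]")
        bad = [i for i in range(N_STATES)
               if self.entry_cost[i] != 0 and i not in _ONE_DAY_STATES]
        if bad:
            raise ParameterError(
                "entry costs are only supported on one-day states"
            )

    @property
    def cycle_cost_vector(self) -> np.ndarray:
        """Effective per-cycle cost vector (entry costs folded in)."""
        return self.daily_cost + self.entry_cost

    @property
    def cycle_utility_vector(self) -> np.ndarray:
        return self.daily_utility


def ww_ed_epinephrine_cost(params: ModelParameters) -> float:
    """Expected epinephrine cost per ED transfer in the watchful-waiting arm.

    Transfers are a mixture of patients without an autoinjector (in-ED
    injection only) and patients with a biphasic recurrence after home
    autoinjector use (replacement device plus in-ED injection), weighted by
    their shares of the transferred fraction.
    """
    epi, cost = params.epi, params.cost
    total = epi.p_no_eai + epi.p_biphasic
    if total == 0.0:
        return cost.ed_injection_cost
    w_no_eai = epi.p_no_eai / total
    w_biphasic = epi.p_biphasic / total
    return (w_no_eai * cost.ed_injection_cost
            + w_biphasic * (cost.eai_unit_cost + cost.ed_injection_cost))


def cycle_rewards(
    strategy: str, perspective: str, params: ModelParameters
) -> RewardSpec:
    """Reward specification for a strategy under a costing perspective.

    Healthcare perspective: background food-allergy medical costs while
    alive and allergic, remission medical costs after remission, the
    replacement autoinjector on watchful-waiting days, the ambulance +
    ED-visit + epinephrine bundle on ED days, and the daily hospital cost.
    The societal perspective adds out-of-pocket and productivity costs.
    Reaction-day utility is the food-allergy utility minus the reaction
    disutility, floored at zero.
    """
    if strategy not in STRATEGIES:
        raise ParameterError(f"unknown strategy {strategy!r}")
    if perspective not in PERSPECTIVES:
        raise ParameterError(f"unknown perspective {perspective!r}")
    cost, util = params.cost, params.util
    dpy = params.settings.days_per_year

    daily_cost = np.zeros(N_STATES)
    daily_cost[NR] = cost.annual_fa_medical_cost / dpy
    daily_cost[REM] = cost.annual_remission_medical_cost / dpy
    daily_cost[HOSP] = cost.hosp_daily_cost

    entry = np.zeros(N_STATES)
    if strategy == WATCHFUL_WAITING:
        entry[WW] = cost.eai_unit_cost
        epi_component = ww_ed_epinephrine_cost(params)
    else:
        epi_component = cost.epi_cost_immediate_ed
    entry[ED] = cost.ambulance_cost + cost.ed_visit_medical_cost + epi_component

    if perspective == "societal":
        daily_cost[NR] += (cost.annual_fa_oop_cost + cost.annual_fa_indirect_cost) / dpy
        entry[ED] += cost.ed_oop_cost + cost.ed_indirect_cost
        entry[HOSP] += cost.hosp_indirect_cost

    daily_u = np.zeros(N_STATES)
    daily_u[NR] = util.u_food_allergy / dpy
    daily_u[REM] = util.u_remission / dpy
    reaction_day = max(util.u_food_allergy - util.disutility_reaction, 0.0) / dpy
    daily_u[WW] = daily_u[ED] = daily_u[HOSP] = reaction_day

    return RewardSpec(
        daily_cost=daily_cost,
        daily_utility=daily_u,
        entry_cost=entry,
        strategy=strategy,
        perspective=perspective,
    )


def discount_factor(cycle_index: int, annual_rate: float, days_per_year: int = 365) -> float:
    """Discount factor for a reward accrued at the end of ``cycle_index`` days."""
    if annual_rate < 0:
        raise ParameterError("annual_rate must be >= 0")
    return (1.0 + annual_rate) ** (-cycle_index / days_per_year)


@dataclass(frozen=True)
class StrategyResult:
    """Aggregate economic outcomes of one strategy over the horizon."""

    strategy: str
    total_cost_discounted: float
    total_qaly_discounted: float
    total_cost_undiscounted: float
    total_qaly_undiscounted: float
    fa_death_risk: float
    perspective: str = "healthcare"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fa_death_risk <= 1.0:
            raise ParameterError("fa_death_risk must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "perspective": self.perspective,
            "total_cost_discounted": self.total_cost_discounted,
            "total_qaly_discounted": self.total_qaly_discounted,
            "total_cost_undiscounted": self.total_cost_undiscounted,
            "total_qaly_undiscounted": self.total_qaly_undiscounted,
            "fa_death_risk": self.fa_death_risk,
            "currency": CURRENCY,
        }


def accumulate(
    trace: CohortTrace, rewards: RewardSpec, settings: EconSettings
) -> StrategyResult:
    """Fold rewards over a cohort trace into totals.

    Reward at cycle t is the occupancy after t transitions dotted with the
    per-cycle reward vectors and discounted at ``(1+r)^(-t/365)``; no
    half-cycle correction is applied (cycles are one day).
    """
    if trace.strategy != rewards.strategy:
        raise ParameterError(
            f"trace strategy {trace.strategy!r} != rewards strategy {rewards.strategy!r}"
        )
    occ = trace.occupancy[1:]  # (T, 7)
    if occ.shape[0] != settings.n_cycles:
        raise ParameterError(
            f"trace has {occ.shape[0]} cycles, settings expect {settings.n_cycles}"
        )
    t = np.arange(1, settings.n_cycles + 1)
    disc = (1.0 + settings.discount_rate_annual) ** (-t / settings.days_per_year)
    c = occ @ rewards.cycle_cost_vector
    u = occ @ rewards.cycle_utility_vector
    return StrategyResult(
        strategy=trace.strategy,
        total_cost_discounted=float(disc @ c),
        total_qaly_discounted=float(disc @ u),
        total_cost_undiscounted=float(c.sum()),
        total_qaly_undiscounted=float(u.sum()),
        fa_death_risk=float(trace.occupancy[-1, FD]),
        perspective=rewards.perspective,
    )


@dataclass(frozen=True)
class CEComparison:
    """Incremental outcomes of watchful waiting versus immediate transfer.

    Deltas are comparator minus reference (watchful waiting minus immediate
    ED transfer), so negative ``delta_cost`` means watchful waiting saves
    money and negative ``delta_qaly`` means it loses health. The ICER is
    then the incremental cost per QALY gained through immediate transfer.
    """

    delta_cost: float
    delta_qaly: float
    icer: float               # NaN when delta_qaly == 0 (dominance-undefined)
    inmb: float
    delta_fa_death_risk: float
    cost_per_death_prevented: float  # NaN when no mortality difference
    wtp: float

    @property
    def icer_defined(self) -> bool:
        return not math.isnan(self.icer)

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": None if math.isnan(self.icer) else self.icer,
            "inmb": self.inmb,
            "delta_fa_death_risk": self.delta_fa_death_risk,
            "cost_per_death_prevented": (
                None if math.isnan(self.cost_per_death_prevented)
                else self.cost_per_death_prevented
            ),
            "wtp": self.wtp,
            "currency": CURRENCY,
        }


def compare(
    reference: StrategyResult, comparator: StrategyResult, wtp: float
) -> CEComparison:
    """Incremental comparison of two strategy results at a WTP threshold.

    ``reference`` is conventionally the immediate-ED-transfer arm and
    ``comparator`` watchful waiting. INMB = WTP x dQALY - dCost, so cost
    savings enter positively.
    """
    if reference.perspective != comparator.perspective:
        raise ParameterError("results computed under different perspectives")
    d_cost = comparator.total_cost_discounted - reference.total_cost_discounted
    d_qaly = comparator.total_qaly_discounted - reference.total_qaly_discounted
    d_risk = comparator.fa_death_risk - reference.fa_death_risk
    icer = d_cost / d_qaly if d_qaly != 0.0 else math.nan
    inmb = wtp * d_qaly - d_cost
    cpdp = abs(d_cost) / abs(d_risk) if d_risk != 0.0 else math.nan
    return CEComparison(
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        icer=icer,
        inmb=inmb,
        delta_fa_death_risk=d_risk,
        cost_per_death_prevented=cpdp,
        wtp=wtp,
    )
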
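"""Analysis orchestration: base case, DSA, PSA, CEAC and scenarios.

The deterministic base case runs both strategies at the point estimates.
One-way deterministic sensitivity analysis (DSA) sweeps each parameter
across its range (default +/-20% of the base value, with the explicit
ranges used for utilities and the in-ED epinephrine cost), re-deriving
dependent quantities, and records the ICER at both bounds. Probabilistic
sensitivity analysis (PSA) resamples parameters from their assigned
distributions and summarises the cost-effectiveness plane and
acceptability curve. Scenario analyses rerun the PSA under setting
overrides (discount rate, perspective, fatality multiplier, start age).

PSA point estimates use the ratio of mean deltas (ICER of means), the
standard construction for summarising Monte Carlo CEA output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .life_tables import LifeTable
from .markov import accumulate_batch, run_cohort
from .params import (
    IMMEDIATE_ED,
    WATCHFUL_WAITING,
    ModelParameters,
    ParamDistribution,
    ParameterError,
)
from .rewards import CEComparison, StrategyResult, accumulate, compare, cycle_rewards

_DERIVED_FIELDS = {
    "epi.p_ed_ww",
    "cost.epi_cost_immediate_ed",
    "cost.ed_indirect_cost",
    "cost.hosp_indirect_cost",
}


# ---------------------------------------------------------------------------
# deterministic evaluation
# ---------------------------------------------------------------------------

def evaluate_strategies(
    params: ModelParameters, life_table: LifeTable
) -> tuple[StrategyResult, StrategyResult]:
    """Run both strategies deterministically; returns (watchful, immediate)."""
    results = []
    for strategy in (WATCHFUL_WAITING, IMMEDIATE_ED):
        trace = run_cohort(strategy, params, life_table)
        rewards = cycle_rewards(strategy, params.settings.perspective, params)
        results.append(accumulate(trace, rewards, params.settings))
    return results[0], results[1]


def base_case(params: ModelParameters, life_table: LifeTable) -> CEComparison:
    """Deterministic comparison of watchful waiting versus immediate transfer."""
    ww, ied = evaluate_strategies(params, life_table)
    return compare(ied, ww, params.settings.wtp)


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DsaParameter:
    """One swept parameter with its low/high bounds."""

    path: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ParameterError(f"DSA bounds must satisfy low < high for {self.path}")


@dataclass(frozen=True)
class DsaRow:
    """ICERs at the two bounds of one swept parameter."""

    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def icer_range(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def default_dsa_spec(params: ModelParameters | None = None) -> list[DsaParameter]:
    """The swept parameters of the one-way sensitivity analysis.

    Ranges are +/-20% of the base value except where an explicit range
    applies: the in-ED epinephrine cost spans its logical extremes ($0.80,
    nobody used a home device, to $95, everybody did) and the state
    utilities span 0.74-1.0.
    """
    if params is None:
        from .params import default_parameters
        params = default_parameters()

    def pm20(path: str) -> DsaParameter:
        base = params.get_path(path)
        return DsaParameter(path, 0.8 * base, 1.2 * base)

    return [
        DsaParameter("epi.p_severe_annual", 0.070, 0.104),
        pm20("epi.p_remission_annual"),
        pm20("epi.p_hosp_given_ed"),
        pm20("epi.p_biphasic"),
        pm20("epi.p_fatal_hosp"),
        pm20("cost.eai_unit_cost"),
        DsaParameter("cost.epi_cost_immediate_ed", 0.80, 95.0),
        pm20("cost.ambulance_cost"),
        pm20("cost.ed_visit_medical_cost"),
        pm20("cost.hosp_daily_cost"),
        pm20("cost.annual_fa_medical_cost"),
        pm20("cost.annual_remission_medical_cost"),
        DsaParameter("util.u_food_allergy", 0.74, 1.0),
        DsaParameter("util.u_remission", 0.74, 1.0),
        pm20("util.disutility_reaction"),
    ]


def with_override(params: ModelParameters, path: str, value: float) -> ModelParameters:
    """Set one (possibly derived) parameter and re-derive dependents.

    Probabilities are clamped to [0, 1] if the requested value falls
    outside the valid domain.
    """
    out = params.copy()
    current = out.get_path(path)
    if isinstance(current, float) and path.split(".")[1].startswith(("p_", "u_")):
        value = min(max(value, 0.0), 1.0)
    out.set_path(path, value)
    preserve = {path} & _DERIVED_FIELDS
    out = out.refresh_derived(preserve=preserve)
    out.validate()
    return out


def one_way_dsa(
    params: ModelParameters,
    life_table: LifeTable,
    spec: list[DsaParameter] | None = None,
) -> list[DsaRow]:
    """One-way DSA; rows come back in tornado order (widest ICER range first)."""
    if spec is None:
        spec = default_dsa_spec(params)
    rows = []
    for item in spec:
        icers = []
        for bound in (item.low, item.high):
            p = with_override(params, item.path, bound)
            icers.append(base_case(p, life_table).icer)
        rows.append(DsaRow(item.path, item.low, item.high, icers[0], icers[1]))
    rows.sort(key=lambda r: r.icer_range, reverse=True)
    return rows


def dsa_to_dataframe(rows: list[DsaRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "low": r.low,
                "high": r.high,
                "icer_at_low": r.icer_at_low,
                "icer_at_high": r.icer_at_high,
                "icer_range": r.icer_range,
            }
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def psa_distributions() -> dict[str, ParamDistribution]:
    """Sampling distributions of the probabilistic analysis.

    Keys are parameter paths, with three indirections: ``epi.p_has_eai``
    samples autoinjector possession (its complement is the no-device
    probability), and ``cost.hosp_total_cost`` / ``cost.hosp_los_days``
    sample total hospitalization cost and length of stay whose ratio gives
    the daily hospital cost. Parameters marked fixed in the base case are
    simply absent. Gamma is (shape, scale); lognormal is (meanlog, sdlog).
    """
    return {
        "epi.p_severe_annual": ParamDistribution("beta", 66, 696),
        "epi.p_has_eai": ParamDistribution("beta", 8.5, 0.88),
        "epi.p_biphasic": ParamDistribution("beta", 184, 3806),
        "epi.p_fatal_overall_annual": ParamDistribution("beta", 100, 1.4e8),
        "epi.p_fatal_hosp": ParamDistribution("beta", 46, 1.0e4),
        "epi.p_remission_annual": ParamDistribution("beta", 47, 771),
        "cost.p_eai_before_ed": ParamDistribution("beta", 7.6, 6.5),
        "cost.ambulance_cost": ParamDistribution("gamma", 100, 8.5),
        "cost.ed_visit_medical_cost": ParamDistribution("gamma", 100, 3.0),
        "cost.ed_wait_hours": ParamDistribution("gamma", 0.27, 13),
        "cost.ed_oop_cost": ParamDistribution("gamma", 100, 0.89),
        "cost.hosp_total_cost": ParamDistribution("gamma", 100, 37),
        "cost.hosp_los_days": ParamDistribution("lognormal", 0.25, 0.99),
        "cost.annual_fa_medical_cost": ParamDistribution("gamma", 100, 14),
        "cost.annual_fa_oop_cost": ParamDistribution("gamma", 100, 24),
        "cost.annual_fa_indirect_cost": ParamDistribution("gamma", 100, 42),
        "util.u_food_allergy": ParamDistribution("beta", 7.1, 0.62),
        "util.disutility_reaction": ParamDistribution("beta", 0.17, 1.7),
        "util.u_remission": ParamDistribution("beta", 8.8, 0.66),
    }


def sample_psa_draw(
    distributions: dict[str, ParamDistribution],
    rng: np.random.Generator,
    base: ModelParameters | None = None,
) -> ModelParameters:
    """Draw one parameter set; fixed parameters keep their base values.

    Draws are independent across parameters and consumed in the mapping's
    iteration order, so a given generator state yields a reproducible set.
    Derived fields are re-derived after sampling; the reaction disutility
    is clamped so reaction-day utility stays non-negative.
    """
    if base is None:
        from .params import default_parameters
        base = default_parameters()
    params = base.copy()
    hosp_total = hosp_los = None
    for key, dist in distributions.items():
        value = dist.sample(rng)
        if key == "epi.p_has_eai":
            params.epi.p_no_eai = 1.0 - value
        elif key == "cost.hosp_total_cost":
            hosp_total = value
        elif key == "cost.hosp_los_days":
            hosp_los = value
        else:
            params.set_path(key, value)
    if (hosp_total is None) != (hosp_los is None):
        raise ParameterError(
            "hospital total cost and length of stay must be sampled together"
        )
    if hosp_total is not None:
        if hosp_los <= 0:
            raise ParameterError("length-of-stay draw must be positive")
        params.cost.hosp_daily_cost = hosp_total / hosp_los
    params.util.disutility_reaction = min(
        params.util.disutility_reaction, params.util.u_food_allergy
    )
    params = params.refresh_derived()
    params.validate()
    return params


@dataclass(frozen=True)
class PsaResult:
    """Iteration-level PSA output (the cost-effectiveness plane)."""

    wtp: float
    ww_cost: np.ndarray
    ww_qaly: np.ndarray
    ied_cost: np.ndarray
    ied_qaly: np.ndarray
    delta_fa_death_risk: np.ndarray

    @property
    def n_iterations(self) -> int:
        return self.ww_cost.shape[0]

    @property
    def delta_cost(self) -> np.ndarray:
        return self.ww_cost - self.ied_cost

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.ww_qaly - self.ied_qaly

    @property
    def inmb(self) -> np.ndarray:
        return self.wtp * self.delta_qaly - self.delta_cost

    @property
    def fraction_cost_effective(self) -> float:
        """Fraction of iterations in which watchful waiting has INMB > 0."""
        return float(np.mean(self.inmb > 0.0))

    @property
    def icer_of_means(self) -> float:
        dq = float(self.delta_qaly.mean())
        return float(self.delta_cost.mean()) / dq if dq != 0.0 else math.nan

    @property
    def inmb_of_means(self) -> float:
        return self.wtp * float(self.delta_qaly.mean()) - float(self.delta_cost.mean())

    def to_dataframe(self) -> pd.DataFrame:
        """CE-plane table, one row per iteration."""
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iterations),
                "ww_cost": self.ww_cost,
                "ww_qaly": self.ww_qaly,
                "ied_cost": self.ied_cost,
                "ied_qaly": self.ied_qaly,
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
                "delta_fa_death_risk": self.delta_fa_death_risk,
                "inmb": self.inmb,
            }
        )

    def summary(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "wtp": self.wtp,
            "mean_ww_cost": float(self.ww_cost.mean()),
            "mean_ied_cost": float(self.ied_cost.mean()),
            "mean_ww_qaly": float(self.ww_qaly.mean()),
            "mean_ied_qaly": float(self.ied_qaly.mean()),
            "mean_delta_cost": float(self.delta_cost.mean()),
            "mean_delta_qaly": float(self.delta_qaly.mean()),
            "icer_of_means": self.icer_of_means,
            "inmb_of_means": self.inmb_of_means,
            "fraction_cost_effective": self.fraction_cost_effective,
        }


def run_psa(
    params: ModelParameters,
    life_table: LifeTable,
    n: int,
    seed,
    wtp: float | None = None,
    distributions: dict[str, ParamDistribution] | None = None,
) -> PsaResult:
    """Monte Carlo PSA: n joint parameter draws through both strategies.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``. Settings
    (perspective, discounting, horizon, start age) are taken from
    ``params`` and held fixed across iterations.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if distributions is None:
        distributions = psa_distributions()
    if wtp is None:
        wtp = params.settings.wtp
    rng = np.random.default_rng(seed)
    draws = [sample_psa_draw(distributions, rng, base=params) for _ in range(n)]
    perspective = params.settings.perspective

    out: dict[str, dict[str, np.ndarray]] = {}
    for strategy in (WATCHFUL_WAITING, IMMEDIATE_ED):
        cost_vecs = np.stack([
            cycle_rewards(strategy, perspective, p).cycle_cost_vector for p in draws
        ])
        util_vecs = np.stack([
            cycle_rewards(strategy, perspective, p).cycle_utility_vector for p in draws
        ])
        out[strategy] = accumulate_batch(strategy, draws, life_table, cost_vecs, util_vecs)

    ww, ied = out[WATCHFUL_WAITING], out[IMMEDIATE_ED]
    return PsaResult(
        wtp=wtp,
        ww_cost=ww["cost"],
        ww_qaly=ww["qaly"],
        ied_cost=ied["cost"],
        ied_qaly=ied["qaly"],
        delta_fa_death_risk=ww["fa_death_risk"] - ied["fa_death_risk"],
    )


# ---------------------------------------------------------------------------
# cost-effectiveness acceptability curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CEACCurve:
    """Probability that watchful waiting is cost-effective per WTP value."""

    wtp: np.ndarray
    probability: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def ceac(psa: PsaResult, wtp_grid) -> CEACCurve:
    """Fraction of PSA iterations with positive INMB at each WTP value."""
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        return CEACCurve(wtp=wtp_grid, probability=np.array([]))
    dq = psa.delta_qaly
    dc = psa.delta_cost
    prob = np.array([
        float(np.mean(w * dq - dc > 0.0)) for w in wtp_grid
    ])
    return CEACCurve(wtp=wtp_grid, probability=prob)


DEFAULT_WTP_GRID = tuple(range(0, 150_001, 10_000))


# ---------------------------------------------------------------------------
# scenario analyses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """A named set of parameter/setting overrides."""

    name: str
    overrides: dict = field(default_factory=dict)

    def apply(self, params: ModelParameters) -> ModelParameters:
        out = params.copy()
        for path, value in self.overrides.items():
            out.set_path(path, value)  # raises on unknown key
        out = out.refresh_derived()
        out.validate()
        return out


def scenario_specs() -> list[ScenarioSpec]:
    """The standard scenario battery around the base case."""
    return [
        ScenarioSpec("discount_0pct", {"settings.discount_rate_annual": 0.0}),
        ScenarioSpec("discount_3pct", {"settings.discount_rate_annual": 0.03}),
        ScenarioSpec("societal_perspective", {"settings.perspective": "societal"}),
        ScenarioSpec("fatality_100x", {"epi.ww_fatality_multiplier": 100.0}),
        ScenarioSpec("fatality_500x", {"epi.ww_fatality_multiplier": 500.0}),
        ScenarioSpec("fatality_1000x", {"epi.ww_fatality_multiplier": 1000.0}),
        ScenarioSpec("start_age_0", {"settings.start_age_years": 0}),
    ]


def run_scenarios(
    params: ModelParameters,
    life_table: LifeTable,
    specs: list[ScenarioSpec] | None = None,
    n: int = 1000,
    seed: int = 0,
    wtp: float | None = None,
) -> pd.DataFrame:
    """PSA-based scenario table (mean totals, ICER and INMB per scenario).

    Each scenario reruns the PSA under its overrides with an independent
    child seed derived from ``seed``; ICER and INMB are computed from mean
    deltas.
    """
    if specs is None:
        specs = scenario_specs()
    if wtp is None:
        wtp = params.settings.wtp
    children = np.random.SeedSequence(seed).spawn(len(specs))
    rows = []
    for spec, child in zip(specs, children):
        scen_params = spec.apply(params)
        psa = run_psa(scen_params, life_table, n=n, seed=child, wtp=wtp)
        s = psa.summary()
        rows.append(
            {
                "scenario": spec.name,
                "ww_cost": s["mean_ww_cost"],
                "ied_cost": s["mean_ied_cost"],
                "ww_qaly": s["mean_ww_qaly"],
                "ied_qaly": s["mean_ied_qaly"],
                "delta_cost": s["mean_delta_cost"],
                "delta_qaly": s["mean_delta_qaly"],
                "icer": s["icer_of_means"],
                "inmb": s["inmb_of_means"],
                "fraction_cost_effective": s["fraction_cost_effective"],
                "n_iterations": n,
            }
        )
    return pd.DataFrame(rows)
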
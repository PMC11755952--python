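"""Daily-cycle Markov cohort engine.

Seven health states; two management strategies that differ only in where a
severe-reaction day routes: under immediate ED transfer every reaction day
goes to the ED, under watchful waiting only the fraction without an
autoinjector or with a biphasic recurrence does, the rest spend the day in
home observation (the watchful-waiting state) with an elevated
out-of-hospital fatality risk.

Reaction-day states (watchful waiting, ED transfer, hospitalization) last
exactly one cycle; survivors return to the no-reaction state, except that
an ED visit can admit to hospital for one additional day. Death states are
absorbing. Competing risks within a day are resolved fatality-first: the
state-specific fatality (if any) claims its mass, all-cause mortality
applies to the remainder, and the surviving mass is split across the
non-fatal destinations. At the daily probabilities involved the ordering
is numerically irrelevant, but it keeps every row exactly stochastic.

A vectorised batch path (used by the probabilistic analyses) propagates
many parameter sets at once and accumulates discounted rewards on the fly
without storing traces; it is tested for exact agreement with the
single-cohort trace path. A microsimulation oracle re-implements the
transition rules by individual-level random draws for validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .life_tables import LifeTable
from .params import (
    IMMEDIATE_ED,
    STRATEGIES,
    WATCHFUL_WAITING,
    ModelParameters,
    ParameterError,
    annual_to_cycle_prob,
    derive_ww_out_of_hospital_fatality,
)

STATES = (
    "no_reaction",
    "ww_reaction",
    "ed_transfer",
    "hospitalization",
    "fa_death",
    "remission",
    "all_cause_death",
)
N_STATES = len(STATES)
NR, WW, ED, HOSP, FD, REM, ACD = range(N_STATES)
ABSORBING = (FD, ACD)

_ROW_TOL = 1e-9


class ModelConsistencyError(RuntimeError):
    """Raised when an internal stochasticity/conservation check fails."""


@dataclass(frozen=True)
class TransitionMatrix:
    """Per-cycle transition probabilities at one integer age."""

    matrix: np.ndarray  # (7, 7)
    age_years: int
    strategy: str

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (N_STATES, N_STATES):
            raise ModelConsistencyError(f"matrix shape {m.shape} != (7, 7)")
        if np.any(m < -_ROW_TOL) or np.any(m > 1 + _ROW_TOL):
            raise ModelConsistencyError("transition entries outside [0, 1]")
        rows = m.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > _ROW_TOL):
            raise ModelConsistencyError(f"rows not stochastic: sums {rows}")
        for s in ABSORBING:
            if m[s, s] != 1.0:
                raise ModelConsistencyError(f"state {STATES[s]} must be absorbing")


@dataclass(frozen=True)
class CohortTrace:
    """State occupancancy of one strategy over the full horizon.

    ``occupancy[t]`` is the cohort distribution after t daily transitions;
    row 0 is the initial distribution.
    """

    occupancy: np.ndarray  # (cycles + 1, 7)
    strategy: str

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# transition-matrix construction
# ---------------------------------------------------------------------------

def _daily_rates(params: ModelParameters, strategy: str) -> dict[str, float]:
    """Strategy-level per-day event probabilities (age-independent part)."""
    epi = params.epi
    dpy = params.settings.days_per_year
    p_react = annual_to_cycle_prob(epi.p_severe_annual, dpy)
    p_rem = annual_to_cycle_prob(epi.p_remission_annual, dpy)
    if strategy == WATCHFUL_WAITING:
        f_ed = epi.p_ed_ww
        q_ww = derive_ww_out_of_hospital_fatality(params)
    else:
        f_ed = 1.0
        q_ww = 0.0  # watchful-waiting state is unreachable in this arm
    return {
        "p_react": p_react,
        "p_rem": p_rem,
        "f_ed": f_ed,
        "q_ww": q_ww,
        "p_hosp": epi.p_hosp_given_ed,
        "p_fatal_hosp": epi.p_fatal_hosp,
    }


def _assemble(
    p_acd, p_react, p_rem, f_ed, q_ww, p_hosp, p_fatal_hosp
) -> np.ndarray:
    """Build (..., 7, 7) transition matrices from broadcastable daily rates."""
    args = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in
          (p_acd, p_react, p_rem, f_ed, q_ww, p_hosp, p_fatal_hosp))
    )
    p_acd, p_react, p_rem, f_ed, q_ww, p_hosp, p_fatal_hosp = args
    shape = p_acd.shape
    m = np.zeros(shape + (N_STATES, N_STATES))

    # from no_reaction: all-cause death first, then reaction / remission
    # among survivors (event probabilities renormalised if they exceed 1)
    ev = p_react + p_rem
    scale = np.where(ev > 1.0, 1.0 / np.maximum(ev, 1e-300), 1.0)
    pr = p_react * scale
    pm = p_rem * scale
    s = 1.0 - p_acd
    m[..., NR, ACD] = p_acd
    m[..., NR, ED] = s * pr * f_ed
    m[..., NR, WW] = s * pr * (1.0 - f_ed)
    m[..., NR, REM] = s * pm
    m[..., NR, NR] = s * (1.0 - pr - pm)

    # watchful-waiting day: out-of-hospital fatality first
    m[..., WW, FD] = q_ww
    m[..., WW, ACD] = (1.0 - q_ww) * p_acd
    m[..., WW, NR] = (1.0 - q_ww) * (1.0 - p_acd)

    # ED day: admit or return home
    m[..., ED, ACD] = p_acd
    m[..., ED, HOSP] = (1.0 - p_acd) * p_hosp
    m[..., ED, NR] = (1.0 - p_acd) * (1.0 - p_hosp)

    # hospital day: in-hospital fatality first
    m[..., HOSP, FD] = p_fatal_hosp
    m[..., HOSP, ACD] = (1.0 - p_fatal_hosp) * p_acd
    m[..., HOSP, NR] = (1.0 - p_fatal_hosp) * (1.0 - p_acd)

    # remission: food allergy never returns; background mortality only
    m[..., REM, ACD] = p_acd
    m[..., REM, REM] = 1.0 - p_acd

    m[..., FD, FD] = 1.0
    m[..., ACD, ACD] = 1.0

    rows = m.sum(axis=-1)
    if np.any(np.abs(rows - 1.0) > _ROW_TOL):
        raise ModelConsistencyError("assembled transition rows not stochastic")
    return m


def build_transition_matrix(
    strategy: str,
    age_years: int,
    params: ModelParameters,
    life_table: LifeTable,
) -> TransitionMatrix:
    """Per-cycle transition matrix for one strategy at one integer age."""
    if strategy not in STRATEGIES:
        raise ParameterError(f"unknown strategy {strategy!r}")
    r = _daily_rates(params, strategy)
    dpy = params.settings.days_per_year
    p_acd = annual_to_cycle_prob(life_table.lookup(age_years), dpy)
    epi = params.epi
    in_window = epi.remission_min_age <= age_years <= epi.remission_max_age
    p_rem = r["p_rem"] if in_window else 0.0
    m = _assemble(p_acd, r["p_react"], p_rem, r["f_ed"], r["q_ww"],
                  r["p_hosp"], r["p_fatal_hosp"])
    return TransitionMatrix(matrix=m, age_years=age_years, strategy=strategy)


def yearly_matrices(
    strategy: str, params: ModelParameters, life_table: LifeTable
) -> np.ndarray:
    """Stack of (horizon_years, 7, 7) matrices, one per simulated year."""
    st = params.settings
    if not life_table.covers(st.start_age_years, st.horizon_years):
        raise ParameterError(
            f"life table covers ages [{life_table.min_age}, {life_table.max_age}]; "
            f"need [{st.start_age_years}, {st.start_age_years + st.horizon_years - 1}]"
        )
    return np.stack([
        build_transition_matrix(strategy, st.start_age_years + y, params, life_table).matrix
        for y in range(st.horizon_years)
    ])


# ---------------------------------------------------------------------------
# cohort propagation
# ---------------------------------------------------------------------------

def run_cohort(
    strategy: str, params: ModelParameters, life_table: LifeTable
) -> CohortTrace:
    """Propagate the full cohort through the horizon, returning the trace.

    The cohort starts with all mass in the no-reaction state at the start
    age; the transition matrix switches every 365 cycles as the cohort ages.
    """
    st = params.settings
    mats = yearly_matrices(strategy, params, life_table)
    n_cycles = st.n_cycles
    occ = np.zeros((n_cycles + 1, N_STATES))
    occ[0, NR] = 1.0
    dpy = st.days_per_year
    for t in range(1, n_cycles + 1):
        occ[t] = occ[t - 1] @ mats[(t - 1) // dpy]
    if np.any(occ < -1e-12):
        raise ModelConsistencyError("negative occupancy produced")
    if np.any(np.abs(occ.sum(axis=1) - 1.0) > 1e-10):
        raise ModelConsistencyError("cohort mass not conserved")
    return CohortTrace(occupancy=occ, strategy=strategy)


def accumulate_batch(
    strategy: str,
    params_list: Sequence[ModelParameters],
    life_table: LifeTable,
    cost_vecs: np.ndarray,
    util_vecs: np.ndarray,
) -> dict[str, np.ndarray]:
    """Propagate many parameter sets at once, accumulating rewards on the fly.

    ``cost_vecs`` / ``util_vecs`` are (B, 7) per-cycle reward vectors (state
    daily rewards with entry costs already folded into the one-day states).
    All parameter sets must share the same economic settings. Returns
    discounted and undiscounted totals and the terminal food-allergy death
    risk, each of shape (B,).
    """
    B = len(params_list)
    if cost_vecs.shape != (B, N_STATES) or util_vecs.shape != (B, N_STATES):
        raise ParameterError("reward vectors must have shape (n_params, 7)")
    st = params_list[0].settings
    dpy = st.days_per_year

    # (years, B, 7, 7)
    mats = np.stack([
        yearly_matrices(strategy, p, life_table) for p in params_list
    ], axis=1)

    disc = (1.0 + st.discount_rate_annual) ** (-np.arange(1, st.n_cycles + 1) / dpy)
    occ = np.zeros((B, N_STATES))
    occ[:, NR] = 1.0
    cost = np.zeros(B)
    qaly = np.zeros(B)
    cost_undisc = np.zeros(B)
    qaly_undisc = np.zeros(B)
    for y in range(st.horizon_years):
        M = mats[y]
        for d in range(dpy):
            t = y * dpy + d
            occ = np.einsum("bi,bij->bj", occ, M)
            c = np.einsum("bi,bi->b", occ, cost_vecs)
            u = np.einsum("bi,bi->b", occ, util_vecs)
            cost += disc[t] * c
            qaly += disc[t] * u
            cost_undisc += c
            qaly_undisc += u
    return {
        "cost": cost,
        "qaly": qaly,
        "cost_undiscounted": cost_undisc,
        "qaly_undiscounted": qaly_undisc,
        "fa_death_risk": occ[:, FD].copy(),
    }


# ---------------------------------------------------------------------------
# microsimulation oracle
# ---------------------------------------------------------------------------

def microsim_oracle(
    strategy: str,
    params: ModelParameters,
    life_table: LifeTable,
    n_individuals: int,
    seed: int,
    horizon_years: int | None = None,
) -> CohortTrace:
    """Individual-level simulation of the same transition rules.

    Draws each person's path day by day from the per-age transition rows
    and returns the empirical occupancy trace. Intended as an independent
    validation oracle for :func:`run_cohort`, not for production runs.
    """
    if n_individuals < 1:
        raise ParameterError("n_individuals must be >= 1")
    st = params.settings
    years = st.horizon_years if horizon_years is None else horizon_years
    rng = np.random.default_rng(seed)
    dpy = st.days_per_year

    states = np.full(n_individuals, NR, dtype=np.int64)
    occ = np.zeros((years * dpy + 1, N_STATES))
    occ[0] = np.bincount(states, minlength=N_STATES) / n_individuals
    for y in range(years):
        m = build_transition_matrix(
            strategy, st.start_age_years + y, params, life_table
        ).matrix
        cum = np.cumsum(m, axis=1)
        cum[:, -1] = 1.0  # guard against rounding in searchsorted
        for d in range(dpy):
            u = rng.random(n_individuals)
            new = np.empty_like(states)
            for s in range(N_STATES):
                mask = states == s
                if mask.any():
                    new[mask] = np.searchsorted(cum[s], u[mask], side="right")
            states = new
            occ[y * dpy + d + 1] = np.bincount(states, minlength=N_STATES) / n_individuals
    return CohortTrace(occupancy=occ, strategy=strategy)
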
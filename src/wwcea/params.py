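"""Model parameters and derived-parameter arithmetic.

All inputs of the decision model live here: epidemiological probabilities,
2022-CAD costs, health-state utilities and economic settings, together with
the small set of arithmetic derivations that tie them together (ED-visit
probability under watchful waiting, the immediate-arm epinephrine cost,
indirect visit costs, annual-to-daily probability conversion, the
hospitalization calibration, and the out-of-hospital fatality risk in the
watchful-waiting state).

Conventions
-----------
* Probabilities are per the time unit stated in the field name; ``annual``
  probabilities are converted to the 1-day cycle with the constant-rate
  compound formula ``1 - (1 - p)**(1/365)``.
* Costs are 2022 Canadian dollars.
* ``strategy`` is one of ``"watchful_waiting"`` / ``"immediate_ed"``;
  ``perspective`` is ``"healthcare"`` / ``"societal"``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import yaml

WATCHFUL_WAITING = "watchful_waiting"
IMMEDIATE_ED = "immediate_ed"
STRATEGIES = (WATCHFUL_WAITING, IMMEDIATE_ED)
PERSPECTIVES = ("healthcare", "societal")

DAYS_PER_YEAR = 365


class ParameterError(ValueError):
    """Raised when a parameter value or configuration violates its domain."""


# ---------------------------------------------------------------------------
# elementary derivations
# ---------------------------------------------------------------------------

def derive_ed_visit_prob(p_no_eai: float, p_biphasic: float) -> float:
    """Probability of ED transfer on a reaction day under watchful waiting.

    Patients without an autoinjector and patients whose reaction recurs
    within 72 h (biphasic) are transferred; the probability is the capped
    sum of the two proportions.
    """
    for name, p in (("p_no_eai", p_no_eai), ("p_biphasic", p_biphasic)):
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1], got {p}")
    return min(1.0, p_no_eai + p_biphasic)


def derive_epi_cost_immediate(
    ed_injection_cost: float, eai_unit_cost: float, p_eai_before_ed: float
) -> float:
    """Expected epinephrine cost per ED visit in the immediate-transfer arm.

    Everyone receives an in-ED injection; the fraction who used (and must
    replace) a home autoinjector before arrival adds its unit cost.
    """
    if ed_injection_cost < 0 or eai_unit_cost < 0:
        raise ParameterError("costs must be non-negative")
    if not 0.0 <= p_eai_before_ed <= 1.0:
        raise ParameterError("p_eai_before_ed must be in [0, 1]")
    return ed_injection_cost + p_eai_before_ed * eai_unit_cost


def derive_indirect_visit_cost(hours: float, wage: float) -> float:
    """Productivity loss of a visit: hours of lost time x hourly wage.

    Reported values are conventionally rounded to the dollar; this returns
    the unrounded product (round for display).
    """
    if hours < 0 or wage < 0:
        raise ParameterError("hours and wage must be non-negative")
    return hours * wage


def annual_to_cycle_prob(p_annual: float, days_per_year: int = DAYS_PER_YEAR) -> float:
    """Convert an annual probability to a per-day probability.

    Uses the constant-hazard compound formula ``1 - (1-p)**(1/n)`` so that
    n independent daily draws reproduce the annual probability exactly.
    ``p_annual = 1`` has no finite daily hazard and is rejected.
    """
    if not 0.0 <= p_annual < 1.0:
        raise ParameterError(f"p_annual must be in [0, 1), got {p_annual}")
    return 1.0 - (1.0 - p_annual) ** (1.0 / days_per_year)


def cycle_to_annual_prob(p_cycle: float, days_per_year: int = DAYS_PER_YEAR) -> float:
    """Inverse of :func:`annual_to_cycle_prob`."""
    if not 0.0 <= p_cycle <= 1.0:
        raise ParameterError(f"p_cycle must be in [0, 1], got {p_cycle}")
    return 1.0 - (1.0 - p_cycle) ** days_per_year


def calibrate_hospitalization_prob(
    p_severe_annual: float,
    p_fatal_overall_annual: float,
    p_fatal_hosp: float,
) -> float:
    """Solve for the ED-to-hospital admission probability.

    The admission probability is not observed directly; it is calibrated so
    that, with every severe reaction presenting to the ED (the
    immediate-transfer arm), the chain

        annual reaction incidence x P(admit | ED) x P(death | admitted)

    reproduces the overall annual food-allergy fatality probability.
    """
    if p_severe_annual <= 0 or p_fatal_hosp <= 0:
        raise ParameterError("p_severe_annual and p_fatal_hosp must be positive")
    if p_fatal_overall_annual < 0:
        raise ParameterError("p_fatal_overall_annual must be non-negative")
    return p_fatal_overall_annual / (p_severe_annual * p_fatal_hosp)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class EpidemiologyParams:
    """Event probabilities of the natural-history and management model."""

    p_severe_annual: float = 0.087
    p_no_eai: float = 0.094
    p_biphasic: float = 0.046
    p_ed_ww: float = 0.14            # derived: min(1, p_no_eai + p_biphasic)
    p_hosp_given_ed: float = 1.68e-3
    p_fatal_hosp: float = 4.5e-3
    p_fatal_overall_annual: float = 6.9e-7
    ww_fatality_multiplier: float = 10.0
    p_remission_annual: float = 0.058
    remission_min_age: int = 1
    remission_max_age: int = 6

    def validate(self) -> None:
        probs = {
            "p_severe_annual": self.p_severe_annual,
            "p_no_eai": self.p_no_eai,
            "p_biphasic": self.p_biphasic,
            "p_ed_ww": self.p_ed_ww,
            "p_hosp_given_ed": self.p_hosp_given_ed,
            "p_fatal_hosp": self.p_fatal_hosp,
            "p_fatal_overall_annual": self.p_fatal_overall_annual,
            "p_remission_annual": self.p_remission_annual,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {p}")
        if self.ww_fatality_multiplier < 1.0:
            raise ParameterError("ww_fatality_multiplier must be >= 1")
        if not self.remission_min_age < self.remission_max_age:
            raise ParameterError("remission_min_age must be < remission_max_age")


@dataclass
class CostParams:
    """Unit costs in 2022 CAD and the quantities used to derive them."""

    eai_unit_cost: float = 95.0
    ed_injection_cost: float = 0.80
    p_eai_before_ed: float = 0.54
    epi_cost_immediate_ed: float = 52.1   # derived
    ambulance_cost: float = 848.0
    ed_visit_medical_cost: float = 331.0
    hosp_daily_cost: float = 1866.0
    annual_fa_medical_cost: float = 1388.0
    annual_remission_medical_cost: float = 569.0
    ed_oop_cost: float = 95.0
    annual_fa_oop_cost: float = 2577.0
    annual_fa_indirect_cost: float = 4421.0
    hourly_wage: float = 31.37
    ed_wait_hours: float = 3.6
    hosp_workday_hours: float = 8.0
    ed_indirect_cost: float = 112.932     # derived
    hosp_indirect_cost: float = 250.96    # derived

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "p_eai_before_ed":
                if not 0.0 <= v <= 1.0:
                    raise ParameterError("p_eai_before_ed must be in [0, 1]")
            elif v < 0:
                raise ParameterError(f"{f.name} must be non-negative, got {v}")


@dataclass
class UtilityParams:
    """Health-state utilities on the 0-1 dead/full-health scale."""

    u_food_allergy: float = 0.92
    disutility_reaction: float = 0.09
    u_remission: float = 0.93

    def validate(self) -> None:
        for name, u in (("u_food_allergy", self.u_food_allergy),
                        ("u_remission", self.u_remission)):
            if not 0.0 <= u <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {u}")
        if self.disutility_reaction < 0:
            raise ParameterError("disutility_reaction must be >= 0")
        if self.u_food_allergy - self.disutility_reaction < 0:
            raise ParameterError("reaction-day utility u - d must be >= 0")


@dataclass
class EconSettings:
    """Economic evaluation settings."""

    discount_rate_annual: float = 0.015
    wtp: float = 50_000.0
    horizon_years: int = 20
    cycle_days: int = 1
    days_per_year: int = DAYS_PER_YEAR
    start_age_years: int = 1
    perspective: str = "healthcare"

    @property
    def n_cycles(self) -> int:
        return self.horizon_years * self.days_per_year

    def validate(self) -> None:
        if self.discount_rate_annual < 0:
            raise ParameterError("discount_rate_annual must be >= 0")
        if self.horizon_years <= 0:
            raise ParameterError("horizon_years must be positive")
        if self.cycle_days != 1:
            raise ParameterError("cycle_days is fixed at 1")
        if self.days_per_year != DAYS_PER_YEAR:
            raise ParameterError(f"days_per_year is fixed at {DAYS_PER_YEAR}")
        if self.start_age_years < 0:
            raise ParameterError("start_age_years must be >= 0")
        if self.perspective not in PERSPECTIVES:
            raise ParameterError(f"perspective must be one of {PERSPECTIVES}")


@dataclass
class ModelParameters:
    """Complete parameter set of the model."""

    epi: EpidemiologyParams = field(default_factory=EpidemiologyParams)
    cost: CostParams = field(default_factory=CostParams)
    util: UtilityParams = field(default_factory=UtilityParams)
    settings: EconSettings = field(default_factory=EconSettings)

    def validate(self) -> None:
        self.epi.validate()
        self.cost.validate()
        self.util.validate()
        self.settings.validate()

    # -- derived-field maintenance ------------------------------------

    def refresh_derived(self, preserve: Iterable[str] = ()) -> "ModelParameters":
        """Recompute derived fields from their defining base fields.

        ``preserve`` names derived fields (dotted, e.g.
        ``"cost.epi_cost_immediate_ed"``) whose current value should be
        kept — used when a sensitivity analysis varies a derived quantity
        directly.
        """
        preserve = set(preserve)
        p = self.copy()
        if "epi.p_ed_ww" not in preserve:
            p.epi.p_ed_ww = derive_ed_visit_prob(p.epi.p_no_eai, p.epi.p_biphasic)
        if "cost.epi_cost_immediate_ed" not in preserve:
            p.cost.epi_cost_immediate_ed = derive_epi_cost_immediate(
                p.cost.ed_injection_cost, p.cost.eai_unit_cost, p.cost.p_eai_before_ed
            )
        if "cost.ed_indirect_cost" not in preserve:
            p.cost.ed_indirect_cost = derive_indirect_visit_cost(
                p.cost.ed_wait_hours, p.cost.hourly_wage
            )
        if "cost.hosp_indirect_cost" not in preserve:
            p.cost.hosp_indirect_cost = derive_indirect_visit_cost(
                p.cost.hosp_workday_hours, p.cost.hourly_wage
            )
        return p

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            epi=dataclasses.replace(self.epi),
            cost=dataclasses.replace(self.cost),
            util=dataclasses.replace(self.util),
            settings=dataclasses.replace(self.settings),
        )

    # -- dotted-path access (used by DSA / config overrides) ----------

    _GROUPS = ("epi", "cost", "util", "settings")

    def get_path(self, path: str) -> Any:
        group, name = self._split(path)
        return getattr(getattr(self, group), name)

    def set_path(self, path: str, value: Any) -> None:
        group, name = self._split(path)
        setattr(getattr(self, group), name, value)

    def _split(self, path: str) -> tuple[str, str]:
        try:
            group, name = path.split(".")
        except ValueError as exc:
            raise ParameterError(f"parameter path must be 'group.field': {path!r}") from exc
        if group not in self._GROUPS:
            raise ParameterError(f"unknown parameter group {group!r} in {path!r}")
        if not any(f.name == name for f in dataclasses.fields(getattr(self, group))):
            raise ParameterError(f"unknown parameter {path!r}")
        return group, name

    # -- flat serialization -------------------------------------------

    def to_flat_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for group in self._GROUPS:
            obj = getattr(self, group)
            for f in dataclasses.fields(obj):
                out[f"{group}.{f.name}"] = getattr(obj, f.name)
        return out

    @classmethod
    def from_flat_dict(cls, data: Mapping[str, Any]) -> "ModelParameters":
        """Build parameters from a flat ``group.field`` mapping.

        Unspecified fields take their base-case defaults; unknown keys are
        rejected. Derived fields absent from the mapping are recomputed,
        present ones are kept verbatim.
        """
        params = default_parameters()
        derived = {"epi.p_ed_ww", "cost.epi_cost_immediate_ed",
                   "cost.ed_indirect_cost", "cost.hosp_indirect_cost"}
        preserve = derived & set(data)
        for key, value in data.items():
            params.set_path(key, value)  # raises ParameterError on unknown key
        params = params.refresh_derived(preserve=preserve)
        params.validate()
        return params

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ParameterError("parameter file must contain a mapping")
        return cls.from_flat_dict(data)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_flat_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            data = json.load(fh)
        return cls.from_flat_dict(data)


@dataclass(frozen=True)
class ParamDistribution:
    """A sampling distribution for probabilistic sensitivity analysis.

    ``gamma`` is parameterised as (shape, scale); ``lognormal`` as
    (meanlog, sdlog); ``beta`` as (alpha, beta); ``fixed`` keeps shape1 as
    the point value.
    """

    family: str
    shape1: float
    shape2: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "lognormal", "fixed"):
            raise ParameterError(f"unknown distribution family {self.family!r}")
        if self.family in ("beta", "gamma") and (self.shape1 <= 0 or self.shape2 <= 0):
            raise ParameterError(f"{self.family} requires positive shape parameters")

    @property
    def mean(self) -> float:
        if self.family == "beta":
            return self.shape1 / (self.shape1 + self.shape2)
        if self.family == "gamma":
            return self.shape1 * self.shape2
        if self.family == "lognormal":
            import math
            return math.exp(self.shape1 + self.shape2 ** 2 / 2.0)
        return self.shape1

    def sample(self, rng) -> float:
        if self.family == "beta":
            return float(rng.beta(self.shape1, self.shape2))
        if self.family == "gamma":
            return float(rng.gamma(self.shape1, self.shape2))
        if self.family == "lognormal":
            return float(rng.lognormal(self.shape1, self.shape2))
        return self.shape1


# ---------------------------------------------------------------------------
# base case and compound derivations
# ---------------------------------------------------------------------------

def default_parameters() -> ModelParameters:
    """The base-case parameter set with derived fields populated."""
    params = ModelParameters().refresh_derived()
    params.validate()
    return params


def derive_ww_out_of_hospital_fatality(
    params: ModelParameters, *, annualized: bool = False
) -> float:
    """Fatality probability per day spent in the watchful-waiting state.

    Watchful waiting is assumed to multiply the overall annual food-allergy
    fatality probability by ``ww_fatality_multiplier``. Part of that target
    is realised in hospital (reactions that are transferred, admitted and
    die there); the remainder must occur out of hospital, during home
    observation. This solves for the per-day conditional probability ``q``:

        target   = multiplier x p_fatal_overall_annual
        in_hosp  = p_severe_annual x p_ed_ww x p_hosp_given_ed x p_fatal_hosp
        ww_days  = 365 x daily reaction probability x (1 - p_ed_ww)
        q        = (target - in_hosp) / ww_days

    where ``ww_days`` is the expected number of watchful-waiting state-days
    per person-year. With ``annualized=True`` returns ``1 - (1-q)**365``,
    the annualized conditional risk as conventionally reported.
    """
    epi = params.epi
    target = epi.ww_fatality_multiplier * epi.p_fatal_overall_annual
    in_hosp = (epi.p_severe_annual * epi.p_ed_ww
               * epi.p_hosp_given_ed * epi.p_fatal_hosp)
    if in_hosp > target:
        raise ParameterError(
            "in-hospital fatality component exceeds the multiplier-scaled "
            f"overall target ({in_hosp:.3g} > {target:.3g})"
        )
    p_react_daily = annual_to_cycle_prob(epi.p_severe_annual,
                                         params.settings.days_per_year)
    ww_days = params.settings.days_per_year * p_react_daily * (1.0 - epi.p_ed_ww)
    if ww_days == 0.0:
        # the watchful-waiting state is never occupied (everyone transfers);
        # no out-of-hospital fatality can or need be realised
        q = 0.0
    else:
        q = (target - in_hosp) / ww_days
    if q > 1.0:
        raise ParameterError(f"derived per-day fatality {q} exceeds 1")
    if annualized:
        return 1.0 - (1.0 - q) ** params.settings.days_per_year
    return q


def apply_fatality_multiplier(params: ModelParameters, k: float) -> ModelParameters:
    """Return a parameter set with the watchful-waiting fatality multiplier k.

    The out-of-hospital fatality is re-derived from k at matrix-build time;
    the immediate-ED arm is unaffected (its fatality is entirely
    in-hospital).
    """
    if k < 1.0:
        raise ParameterError(f"fatality multiplier must be >= 1, got {k}")
    out = params.copy()
    out.epi.ww_fatality_multiplier = float(k)
    # fail fast if the configuration cannot realise the target
    derive_ww_out_of_hospital_fatality(out)
    return out
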
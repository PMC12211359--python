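"""Costs and utility weights per health state and stage.

The analysis takes a societal perspective: direct medical costs (statin
therapy, risk-assessment visits, hospitalizations, chronic-stage care) plus
indirect costs estimated by the human-capital approach (wage loss of the
patient and one caregiver during hospitalization, and the discounted wage
stream lost to premature ASCVD death before retirement).

Non-fatal events are split into an acute stage — the hospitalization window
of the event-entry cycle, valued at the acute utility weight — and a
chronic stage covering the rest of that cycle and all later cycles in the
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping

import numpy as np

from .markov import DiscountSpec, HealthState, N_STATES, STATE_INDEX

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class CostSet:
    """Annual and per-episode costs in 2019 USD."""

    statin_annual: float = 61.43
    registration_annual: float = 52.17
    exam_per_visit: float = 4.35
    hosp_cost: Mapping[str, float] = field(default_factory=lambda: {
        "acute_MI": 4401.23, "other_IHD": 2037.71, "IS": 1421.91,
        "diabetes": 1149.70, "myopathy": 1793.36,
    })
    chronic_annual: Mapping[str, float] = field(default_factory=lambda: {
        "IHD": 427.04, "IS": 242.38, "diabetes": 835.87,
    })
    hosp_days: Mapping[str, float] = field(default_factory=lambda: {
        "acute_MI": 8.05, "other_IHD": 7.79, "IS": 10.01,
        "diabetes": 9.39, "myopathy": 9.21,
    })
    salary_annual: float = 13116.09
    unemployment: float = 0.052

    def __post_init__(self) -> None:
        scalars = [self.statin_annual, self.registration_annual,
                   self.exam_per_visit, self.salary_annual, self.unemployment]
        if any(v < 0 for v in scalars):
            raise ValueError("costs must be non-negative")
        if any(v < 0 for v in self.hosp_cost.values()):
            raise ValueError("hospitalization costs must be non-negative")
        if any(not 0 <= d < DAYS_PER_YEAR for d in self.hosp_days.values()):
            raise ValueError("hospitalization durations must be in [0, 365)")

    @classmethod
    def from_mapping(cls, params: Mapping[str, float]) -> "CostSet":
        """Build from a flat parameter mapping (manifest keys)."""
        return cls(
            statin_annual=params["statin_annual"],
            registration_annual=params["registration_annual"],
            exam_per_visit=params["exam_per_visit"],
            hosp_cost={
                "acute_MI": params["hosp_acute_mi"],
                "other_IHD": params["hosp_other_ihd"],
                "IS": params["hosp_is"],
                "diabetes": params["hosp_diabetes"],
                "myopathy": params["hosp_myopathy"],
            },
            chronic_annual={
                "IHD": params["chronic_ihd_annual"],
                "IS": params["chronic_is_annual"],
                "diabetes": params["chronic_diabetes_annual"],
            },
            hosp_days={
                "acute_MI": params["days_acute_mi"],
                "other_IHD": params["days_other_ihd"],
                "IS": params["days_is"],
                "diabetes": params["days_diabetes"],
                "myopathy": params["days_myopathy"],
            },
            salary_annual=params["salary_annual"],
            unemployment=params["unemployment"],
        )


@dataclass(frozen=True)
class UtilitySet:
    """Utility weights per health state (1 = full health, 0 = death)."""

    disease_free_untreated: float = 1.0
    disease_free_on_statin: float = 0.999
    acute_event: float = 0.50
    chronic: Mapping[str, float] = field(default_factory=lambda: {
        "IHD": 0.87, "IS": 0.90, "diabetes": 0.84,
    })
    myopathy_episode: float = 0.56
    death: float = 0.0

    def __post_init__(self) -> None:
        values = [self.disease_free_untreated, self.disease_free_on_statin,
                  self.acute_event, self.myopathy_episode, self.death,
                  *self.chronic.values()]
        if any(not 0 <= u <= 1 for u in values):
            raise ValueError("utilities must lie in [0, 1]")
        if self.death != 0:
            raise ValueError("death utility must be 0")
        if self.disease_free_untreated != 1:
            raise ValueError("untreated disease-free utility must be 1")

    @classmethod
    def from_mapping(cls, params: Mapping[str, float]) -> "UtilitySet":
        return cls(
            disease_free_untreated=params["u_disease_free"],
            disease_free_on_statin=params["u_statin"],
            acute_event=params["u_acute"],
            chronic={
                "IHD": params["u_chronic_ihd"],
                "IS": params["u_chronic_is"],
                "diabetes": params["u_diabetes"],
            },
            myopathy_episode=params["u_myopathy"],
        )


# event key and chronic key per state
_EVENT_KEY = {
    HealthState.NONFATAL_ACUTE_MI: ("acute_MI", "IHD"),
    HealthState.NONFATAL_OTHER_IHD: ("other_IHD", "IHD"),
    HealthState.NONFATAL_IS: ("IS", "IS"),
    HealthState.ADVERSE_DIABETES: ("diabetes", "diabetes"),
}


def annual_direct_cost(state: HealthState, stage: str | None,
                       on_statin: bool, costs: CostSet) -> float:
    """Direct medical cost accrued by one person-year in ``state``.

    ``stage`` is ``"acute"`` for the event-entry cycle of a non-fatal state
    (admission cost plus the chronic cost pro-rated over the out-of-hospital
    remainder of the year) and ``"chronic"`` for later cycles.  Statin-treated
    disease-free years accrue drug, registration and one risk-assessment
    visit; untreated disease-free years and dead states accrue nothing.
    """
    if not isinstance(state, HealthState):
        raise ValueError(f"unknown state {state!r}")
    if state in (HealthState.DISEASE_FREE_UNTREATED,
                 HealthState.DISEASE_FREE_ON_STATIN):
        if on_statin:
            return (costs.statin_annual + costs.registration_annual
                    + costs.exam_per_visit)
        return 0.0
    if state in _EVENT_KEY:
        event, chronic = _EVENT_KEY[state]
        chronic_cost = costs.chronic_annual.get(chronic, 0.0)
        if stage == "acute":
            frac_out = 1.0 - costs.hosp_days[event] / DAYS_PER_YEAR
            return costs.hosp_cost[event] + frac_out * chronic_cost
        return chronic_cost
    if state is HealthState.ADVERSE_MYOPATHY_RECOVERED:
        return costs.hosp_cost["myopathy"] if stage == "acute" else 0.0
    return 0.0  # fatal states


def indirect_hospitalization_cost(days: float, salary_annual: float,
                                  unemployment: float, *,
                                  caregivers: int = 1,
                                  day_denominator: float = DAYS_PER_YEAR) -> float:
    """Human-capital wage loss of one admission.

    The patient plus ``caregivers`` family members each lose ``days`` of
    production valued at the average daily wage, scaled by the employment
    rate: ``(salary / denominator) * days * (1 + caregivers) * (1 - u)``.
    """
    if days < 0:
        raise ValueError("hospitalization days must be non-negative")
    daily = salary_annual / day_denominator
    return daily * days * (1 + caregivers) * (1.0 - unemployment)


def premature_death_productivity_loss(age_at_death: float,
                                      salary_annual: float,
                                      unemployment: float,
                                      retirement_age: float = 60,
                                      discount: DiscountSpec | None = None) -> float:
    """Discounted wage stream lost between death and retirement.

    Sums ``salary * (1 - unemployment)`` for each whole year from
    ``age_at_death`` up to ``retirement_age`` (exclusive), discounted from
    the year of death; zero at or beyond retirement.
    """
    if discount is None:
        discount = DiscountSpec()
    years = int(np.ceil(retirement_age - age_at_death))
    if years <= 0:
        return 0.0
    annual = salary_annual * (1.0 - unemployment)
    return float(annual * discount.factors(years).sum())


def annual_utility(state: HealthState, stage: str | None, on_statin: bool,
                   hosp_days: float, utilities: UtilitySet) -> float:
    """QALY weight of one person-year in ``state``.

    Event-entry cycles mix the acute weight over the hospitalization window
    with the chronic weight over the remainder:
    ``(d/365) * u_acute + (1 - d/365) * u_chronic``.
    """
    if not isinstance(state, HealthState):
        raise ValueError(f"unknown state {state!r}")
    if state is HealthState.DISEASE_FREE_UNTREATED:
        return utilities.disease_free_on_statin if on_statin else \
            utilities.disease_free_untreated
    if state is HealthState.DISEASE_FREE_ON_STATIN:
        return utilities.disease_free_on_statin
    frac_in = hosp_days / DAYS_PER_YEAR
    if state in (HealthState.NONFATAL_ACUTE_MI, HealthState.NONFATAL_OTHER_IHD,
                 HealthState.NONFATAL_IS):
        chronic = utilities.chronic["IHD" if state is not
                                    HealthState.NONFATAL_IS else "IS"]
        if stage == "acute":
            return frac_in * utilities.acute_event + (1 - frac_in) * chronic
        return chronic
    if state is HealthState.ADVERSE_DIABETES:
        # no separate acute disutility is attached to diabetes onset
        return utilities.chronic["diabetes"]
    if state is HealthState.ADVERSE_MYOPATHY_RECOVERED:
        return (frac_in * utilities.myopathy_episode
                + (1 - frac_in) * utilities.disease_free_untreated)
    return utilities.death


# ---------------------------------------------------------------------------
# vectorized per-state values for the cohort engine
# ---------------------------------------------------------------------------

def state_value_vectors(costs: CostSet, utilities: UtilitySet
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-state value vectors consumed by the strategy engine.

    Returns ``(cost_occupancy, utility_occupancy, cost_inflow,
    utility_inflow_delta)``:

    * ``cost_occupancy`` / ``utility_occupancy`` apply to all occupants of a
      state each cycle (chronic-stage values; statin-year values for the
      treated disease-free state).
    * ``cost_inflow`` is the extra cost charged to mass entering a state
      that cycle: admission cost plus the caregiver/patient wage loss,
      minus the in-hospital share of the chronic cost already charged via
      occupancy.
    * ``utility_inflow_delta`` shifts entrants from the chronic to the acute
      weight over the hospitalization window.

    Productivity loss from premature ASCVD death is age-dependent and is
    handled separately (see :func:`productivity_loss_by_age`).
    """
    c_occ = np.zeros(N_STATES)
    u_occ = np.zeros(N_STATES)
    c_in = np.zeros(N_STATES)
    u_delta = np.zeros(N_STATES)

    for state in HealthState:
        i = STATE_INDEX[state]
        on_statin = state is HealthState.DISEASE_FREE_ON_STATIN
        c_occ[i] = annual_direct_cost(state, "chronic", on_statin, costs)
        days = 0.0
        if state in _EVENT_KEY:
            days = costs.hosp_days[_EVENT_KEY[state][0]]
        elif state is HealthState.ADVERSE_MYOPATHY_RECOVERED:
            days = costs.hosp_days["myopathy"]
        u_occ[i] = annual_utility(state, "chronic", on_statin, days, utilities)

    for state, (event, _) in _EVENT_KEY.items():
        i = STATE_INDEX[state]
        days = costs.hosp_days[event]
        c_in[i] = (costs.hosp_cost[event]
                   + indirect_hospitalization_cost(days, costs.salary_annual,
                                                   costs.unemployment)
                   - (days / DAYS_PER_YEAR) * c_occ[i])
        u_delta[i] = (annual_utility(state, "acute", False, days, utilities)
                      - u_occ[i])

    # myopathy is transient: its occupancy equals its inflow, so the episode
    # utility sits on occupancy and only the admission costs ride on inflow
    i_myo = STATE_INDEX[HealthState.ADVERSE_MYOPATHY_RECOVERED]
    days_myo = costs.hosp_days["myopathy"]
    c_in[i_myo] = (costs.hosp_cost["myopathy"]
                   + indirect_hospitalization_cost(days_myo,
                                                   costs.salary_annual,
                                                   costs.unemployment))
    u_occ[i_myo] = annual_utility(HealthState.ADVERSE_MYOPATHY_RECOVERED,
                                  "acute", False, days_myo, utilities)
    return c_occ, u_occ, c_in, u_delta


def productivity_loss_by_age(costs: CostSet, discount: DiscountSpec,
                             retirement_age: float = 60,
                             min_age: int = 30, max_age: int = 101) -> np.ndarray:
    """Premature-death wage loss indexed by integer age at death.

    ``out[age - min_age]`` is the loss charged once when mass enters the
    fatal ASCVD state at that age.
    """
    ages = np.arange(min_age, max_age + 1)
    return np.array([
        premature_death_productivity_loss(a, costs.salary_annual,
                                          costs.unemployment, retirement_age,
                                          discount)
        for a in ages
    ])
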
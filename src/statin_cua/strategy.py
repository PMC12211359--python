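"""Threshold policies and population-level strategy evaluation.

A strategy screens everyone once at model entry with a 10-year ASCVD risk
score (soft or hard outcome definition) and starts statin therapy for
those at or above the threshold.  The population result is a census-weighted
mixture over (sex, 5-year age band) sub-cohorts, each split into a treated
eligible stratum (statin-modified hazards, treatment costs, adverse-event
and discontinuation pathways) and an untreated non-eligible stratum, run
through the Markov engine to age 100.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import econ
from .markov import (AGE_BANDS, BAND_MIDPOINTS, DiscountSpec, HealthState,
                     N_STATES, STATE_INDEX, TransitionTable, ValidationError,
                     band_for_age, build_transition_matrix,
                     lifetime_ascvd_fraction, run_cohort)
from .params import default_parameters
from .population import SEXES, default_census_weights, weight_lookup

MAX_AGE = 100
#: Threshold grids (percent) by risk-score model.
THRESHOLD_GRID = {
    "soft": tuple(float(t) for t in range(10, 21)),
    "hard": (7.5,) + tuple(float(t) for t in range(5, 16)),
}

_I_UNTREATED = STATE_INDEX[HealthState.DISEASE_FREE_UNTREATED]
_I_STATIN = STATE_INDEX[HealthState.DISEASE_FREE_ON_STATIN]
_I_FATAL_ASCVD = STATE_INDEX[HealthState.FATAL_ASCVD]


@dataclass(frozen=True)
class Strategy:
    """A screening policy: risk model plus threshold (percent).

    ``threshold=None`` denotes the no-treatment comparator.
    """

    model: str = "soft"
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.model not in THRESHOLD_GRID:
            raise ValueError(f"unknown risk model {self.model!r}")

    @property
    def is_no_treatment(self) -> bool:
        return self.threshold is None

    @property
    def label(self) -> str:
        if self.is_no_treatment:
            return "No treatment"
        t = self.threshold
        return f"{t:g}%"


@dataclass(frozen=True)
class TreatmentEffects:
    """Statin efficacy and on-treatment risks.

    Relative risks apply to the disease-free exit hazards while on statin;
    adverse-event probabilities are per cycle and move the individual off
    statin permanently (diabetes is lifelong; myopathy resolves after one
    episode).  Discontinuation for other reasons is a trial-level overall
    rate applied once in the first treated cycle by default; set
    ``annual_discontinuation`` for a per-cycle variant.
    """

    rr_nonfatal_ihd: float = 0.67
    rr_nonfatal_is: float = 0.69
    rr_fatal_ascvd: float = 0.83
    p_adverse_diabetes: float = 0.0030
    p_adverse_myopathy: float = 0.0024
    p_discontinue_other: float = 0.1186
    annual_discontinuation: bool = False

    def __post_init__(self) -> None:
        if min(self.rr_nonfatal_ihd, self.rr_nonfatal_is,
               self.rr_fatal_ascvd) <= 0:
            raise ValueError("relative risks must be positive")
        for p in (self.p_adverse_diabetes, self.p_adverse_myopathy,
                  self.p_discontinue_other):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def from_mapping(cls, params: Mapping[str, float],
                     annual_discontinuation: bool = False) -> "TreatmentEffects":
        return cls(
            rr_nonfatal_ihd=params["rr_nonfatal_ihd"],
            rr_nonfatal_is=params["rr_nonfatal_is"],
            rr_fatal_ascvd=params["rr_fatal_ascvd"],
            p_adverse_diabetes=params["p_adverse_diabetes"],
            p_adverse_myopathy=params["p_adverse_myopathy"],
            p_discontinue_other=params["p_discontinue_other"],
            annual_discontinuation=annual_discontinuation,
        )


@dataclass(frozen=True)
class StrategyOutcome:
    """Per-person expected results of one strategy."""

    strategy: Strategy
    eligible_pct: float
    events_pct: float | None
    cost: float
    qalys: float

    @property
    def label(self) -> str:
        return self.strategy.label


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def stratify_by_threshold(risks, threshold: float,
                          census_weights: pd.DataFrame | None = None,
                          *, sex=None, age_group=None
                          ) -> tuple[float, np.ndarray]:
    """Split a cohort at a risk threshold.

    ``risks`` and ``threshold`` are fractions.  Ties count as eligible
    (treatment at exactly the threshold risk).  Returns the population
    eligible fraction and the per-individual membership mask.  When ``sex``
    and ``age_group`` arrays are provided together with census weights, the
    fraction is the census-weighted mean of cell-level eligible fractions;
    otherwise it is the simple mean.
    """
    risks = np.asarray(risks, dtype=float)
    if risks.size == 0:
        raise ValueError("cannot stratify an empty cohort")
    eligible = risks >= threshold
    if sex is None or age_group is None:
        return float(eligible.mean()), eligible
    weights = default_census_weights() if census_weights is None \
        else census_weights
    cells = pd.DataFrame({"sex": np.asarray(sex),
                          "age_group": np.asarray(age_group),
                          "eligible": eligible})
    cell_frac = cells.groupby(["sex", "age_group"])["eligible"].mean()
    wl = weight_lookup(weights)
    total_w = sum(wl.get(cell, 0.0) for cell in cell_frac.index)
    if total_w <= 0:
        return float(eligible.mean()), eligible
    frac = sum(wl.get(cell, 0.0) * f for cell, f in cell_frac.items()) / total_w
    return float(frac), eligible


def eligibility_table(cohort: pd.DataFrame, model: str,
                      threshold_pct: float) -> pd.DataFrame:
    """Cell-level eligible fractions of a cohort at a threshold (percent)."""
    df = cohort.copy()
    df["age_group"] = [band_for_age(a) for a in df["age"]]
    df["eligible"] = df[f"risk_{model}"] >= threshold_pct / 100.0
    out = (df.groupby(["sex", "age_group"], sort=False)["eligible"]
             .mean().rename("eligible_fraction").reset_index())
    return out


def apply_statin_effects(matrix: np.ndarray,
                         effects: TreatmentEffects) -> np.ndarray:
    """Return a matrix whose on-statin row reflects treatment.

    Starts from the untreated disease-free hazards of ``matrix``, scales
    them by the relative risks, and adds the per-cycle adverse-event exits
    (plus discontinuation if the annual variant is enabled).
    """
    out = matrix.copy()
    row = matrix[_I_UNTREATED].copy()
    row[_I_UNTREATED] = 0.0
    row[STATE_INDEX[HealthState.NONFATAL_ACUTE_MI]] *= effects.rr_nonfatal_ihd
    row[STATE_INDEX[HealthState.NONFATAL_OTHER_IHD]] *= effects.rr_nonfatal_ihd
    row[STATE_INDEX[HealthState.NONFATAL_IS]] *= effects.rr_nonfatal_is
    row[_I_FATAL_ASCVD] *= effects.rr_fatal_ascvd
    row[STATE_INDEX[HealthState.ADVERSE_DIABETES]] += effects.p_adverse_diabetes
    row[STATE_INDEX[HealthState.ADVERSE_MYOPATHY_RECOVERED]] += (
        effects.p_adverse_myopathy)
    if effects.annual_discontinuation:
        # discontinuation competes with events: it applies to the residual
        event_mass = row.sum() - row[_I_STATIN] - row[_I_UNTREATED]
        row[_I_UNTREATED] += effects.p_discontinue_other * \
            max(1.0 - event_mass, 0.0)
    total = row.sum() - row[_I_STATIN]
    if total > 1.0 + 1e-12:
        raise ValidationError(
            f"treated transition row sums to {total:.6f} > 1")
    row[_I_STATIN] = max(1.0 - total, 0.0)
    out[_I_STATIN] = row
    return out


# ---------------------------------------------------------------------------
# arm simulation
# ---------------------------------------------------------------------------

@dataclass
class _ArmResult:
    cost: float
    qalys: float
    events: float


def _baseline_risk_ratio(table: TransitionTable, sex: str, band: str,
                         risk_group: str) -> dict[str, float]:
    """Disease-free hazard ratio of a baseline risk stratum vs overall.

    Eligibility is decided once at model entry, so the ratio between a
    stratum's first-event hazards and the whole population's, observed in
    the entry age band, is carried forward as the sub-cohort ages (the
    later bands' stratified rows describe cohorts screened at those ages,
    not this one).
    """
    strat = table.annual_probs(sex, band, risk_group, "disease_free")
    overall = table.annual_probs(sex, band, "overall", "disease_free")
    ratio = {}
    for target, p_overall in overall.items():
        p_strat = strat.get(target, 0.0)
        ratio[target] = p_strat / p_overall if p_overall > 0 else 1.0
    return ratio


def _matrix_provider(table: TransitionTable, sex: str, start_age: int,
                     risk_group: str, effects: TreatmentEffects | None,
                     elderly_multiplier: float):
    """Per-cycle matrices as the sub-cohort ages through bands.

    Risk-stratified arms use the whole-population age-specific hazards
    scaled by the baseline band's stratum-vs-overall ratio, so the
    eligible/non-eligible mixture stays consistent with the overall
    population at every age.
    """
    cache: dict[tuple[str, float], np.ndarray] = {}
    multipliers = None
    if risk_group != "overall":
        multipliers = _baseline_risk_ratio(table, sex,
                                           band_for_age(start_age), risk_group)

    def get(t: int) -> np.ndarray:
        age = start_age + t
        band = band_for_age(age)
        mult = elderly_multiplier if age > 75 else 1.0
        key = (band, mult)
        if key not in cache:
            base = build_transition_matrix(table, sex, band, "overall",
                                           event_multiplier=mult,
                                           df_multipliers=multipliers)
            cache[key] = apply_statin_effects(base, effects) \
                if effects is not None else base
        return cache[key]

    return get


def _run_arm(table: TransitionTable, sex: str, start_age: int,
             risk_group: str, init: np.ndarray,
             effects: TreatmentEffects | None,
             values: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
             death_loss: np.ndarray, discount: DiscountSpec,
             elderly_multiplier: float,
             loss_on_non_ascvd_death: bool = False) -> _ArmResult:
    horizon = MAX_AGE - start_age
    get_matrix = _matrix_provider(table, sex, start_age, risk_group, effects,
                                  elderly_multiplier)
    trace = run_cohort(get_matrix, init, horizon, start_age=start_age)
    c_occ, u_occ, c_in, u_delta = values
    d = discount.factors(trace.n_cycles)
    cost_t = (trace.occupancy @ c_occ) + (trace.inflow @ c_in)
    death_inflow = trace.inflow[:, _I_FATAL_ASCVD]
    if loss_on_non_ascvd_death:
        death_inflow = death_inflow + \
            trace.inflow[:, STATE_INDEX[HealthState.FATAL_NON_ASCVD]]
    cost_t += death_inflow * \
        death_loss[start_age - 30: start_age - 30 + trace.n_cycles]
    qaly_t = (trace.occupancy @ u_occ) + (trace.inflow @ u_delta)
    return _ArmResult(cost=float(d @ cost_t), qalys=float(d @ qaly_t),
                      events=lifetime_ascvd_fraction(trace))


def _init_untreated() -> np.ndarray:
    init = np.zeros(N_STATES)
    init[_I_UNTREATED] = 1.0
    return init


def _init_treated(effects: TreatmentEffects) -> np.ndarray:
    init = np.zeros(N_STATES)
    if effects.annual_discontinuation:
        init[_I_STATIN] = 1.0
    else:
        # one-time discontinuation for other reasons at treatment start
        init[_I_UNTREATED] = effects.p_discontinue_other
        init[_I_STATIN] = 1.0 - effects.p_discontinue_other
    return init


# ---------------------------------------------------------------------------
# strategy evaluation
# ---------------------------------------------------------------------------

def evaluate_strategy(strategy: Strategy, table: TransitionTable,
                      params: Mapping[str, float] | None = None,
                      census_weights: pd.DataFrame | None = None,
                      eligibility: pd.DataFrame | None = None,
                      *,
                      effects: TreatmentEffects | None = None,
                      untreated_stratified: bool = False,
                      elderly_multiplier: float = 1.0,
                      retirement_age: float = 60.0,
                      productivity_loss_non_ascvd: bool = False
                      ) -> StrategyOutcome:
    """Expected per-person cost, QALYs and lifetime event fraction.

    Threshold strategies require ``eligibility`` (cell-level eligible
    fractions, from :func:`eligibility_table`) and a table with
    ``eligible`` / ``non_eligible`` disease-free rows.  The no-treatment
    comparator uses the whole-population (``overall``) rows, unless
    ``untreated_stratified`` is set, in which case it is run on the same
    eligible/non-eligible split with treatment switched off — the
    comparability convention for pairing the highest threshold against no
    treatment.
    """
    p = dict(default_parameters())
    if params:
        p.update(params)
    costs = econ.CostSet.from_mapping(p)
    utilities = econ.UtilitySet.from_mapping(p)
    if effects is None:
        effects = TreatmentEffects.from_mapping(p)
    discount = DiscountSpec(p["discount_rate"])
    weights = default_census_weights() if census_weights is None \
        else census_weights
    values = econ.state_value_vectors(costs, utilities)
    death_loss = econ.productivity_loss_by_age(costs, discount,
                                               retirement_age,
                                               max_age=MAX_AGE + 1)

    needs_split = (not strategy.is_no_treatment) or untreated_stratified
    if needs_split and eligibility is None:
        raise ValidationError(
            f"strategy {strategy.label}: cell-level eligibility required")
    frac_of = {}
    if eligibility is not None:
        frac_of = {(r.sex, r.age_group): float(r.eligible_fraction)
                   for r in eligibility.itertuples(index=False)}

    total_w = cost = qalys = events = eligible = 0.0
    for sex in SEXES:
        for band, mid in zip(AGE_BANDS, BAND_MIDPOINTS):
            w = _cell_weight(weights, sex, band)
            if w <= 0:
                continue
            total_w += w
            if not needs_split:
                arm = _run_arm(table, sex, mid, "overall", _init_untreated(),
                               None, values, death_loss, discount,
                               elderly_multiplier,
                               productivity_loss_non_ascvd)
                cell_cost, cell_q, cell_e, f = arm.cost, arm.qalys, arm.events, 0.0
            else:
                f = frac_of.get((sex, band), 0.0)
                treated_effects = None if strategy.is_no_treatment else effects
                cell_cost = cell_q = cell_e = 0.0
                if f > 0:
                    if not table.has_row(sex, band, "eligible", "disease_free"):
                        raise ValidationError(
                            f"missing eligible rows for (sex={sex}, "
                            f"age_group={band}) with eligible fraction {f:.4f}")
                    init = _init_treated(effects) if treated_effects is not None \
                        else _init_untreated()
                    arm = _run_arm(table, sex, mid, "eligible", init,
                                   treated_effects, values, death_loss,
                                   discount, elderly_multiplier,
                                   productivity_loss_non_ascvd)
                    cell_cost += f * arm.cost
                    cell_q += f * arm.qalys
                    cell_e += f * arm.events
                if f < 1:
                    arm = _run_arm(table, sex, mid, "non_eligible",
                                   _init_untreated(), None, values,
                                   death_loss, discount, elderly_multiplier,
                                   productivity_loss_non_ascvd)
                    cell_cost += (1 - f) * arm.cost
                    cell_q += (1 - f) * arm.qalys
                    cell_e += (1 - f) * arm.events
                if strategy.is_no_treatment:
                    f = 0.0
            cost += w * cell_cost
            qalys += w * cell_q
            events += w * cell_e
            eligible += w * f
    if total_w <= 0:
        raise ValidationError("census weights sum to zero over modeled cells")
    return StrategyOutcome(
        strategy=strategy,
        eligible_pct=100.0 * eligible / total_w,
        events_pct=100.0 * events / total_w,
        cost=cost / total_w,
        qalys=qalys / total_w,
    )


def _cell_weight(weights: pd.DataFrame, sex: str, band: str) -> float:
    sel = weights[(weights["sex"] == sex) & (weights["age_group"] == band)]
    return float(sel["weight"].sum())


def evaluate_threshold_grid(model: str, thresholds,
                            tables: Mapping[float, TransitionTable],
                            eligibility: Mapping[float, pd.DataFrame],
                            params: Mapping[str, float] | None = None,
                            census_weights: pd.DataFrame | None = None,
                            *,
                            include_no_treatment: bool = True,
                            no_treatment_comparability: bool = True,
                            effects: TreatmentEffects | None = None
                            ) -> list[StrategyOutcome]:
    """Evaluate a full threshold grid plus the no-treatment comparator.

    Output is ordered no-treatment first, then thresholds descending (the
    least-treatment-first ladder layout).  The no-treatment arm is run on
    the highest threshold's stratified table with treatment off when
    ``no_treatment_comparability`` is set (the default), making it directly
    comparable to the highest-threshold strategy; otherwise it uses the
    whole-population rows.
    """
    ts = [float(t) for t in thresholds]
    if len(set(ts)) != len(ts):
        raise ValueError("duplicate thresholds in grid")
    if not ts:
        raise ValueError("threshold grid is empty")
    ts_sorted = sorted(ts, reverse=True)
    outcomes: list[StrategyOutcome] = []
    if include_no_treatment:
        t_hi = ts_sorted[0]
        if no_treatment_comparability:
            outcomes.append(evaluate_strategy(
                Strategy(model, None), tables[t_hi], params, census_weights,
                eligibility[t_hi], untreated_stratified=True,
                effects=effects))
        else:
            outcomes.append(evaluate_strategy(
                Strategy(model, None), tables[t_hi], params, census_weights,
                effects=effects))
    for t in ts_sorted:
        outcomes.append(evaluate_strategy(
            Strategy(model, t), tables[t], params, census_weights,
            eligibility[t], effects=effects))
    elig = [o.eligible_pct for o in outcomes[1 if include_no_treatment else 0:]]
    if any(b < a - 1e-9 for a, b in zip(elig, elig[1:])):
        warnings.warn("eligible fraction is not monotone in threshold")
    return outcomes
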
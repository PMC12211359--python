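"""Markov cohort state-transition engine.

The disease process is a discrete-time Markov chain over nine health states
with a one-year cycle.  A cohort is represented by its probability mass per
state; one cycle multiplies the occupancy row vector by an annual transition
matrix.  Two states (fatal ASCVD, fatal non-ASCVD) are absorbing; the three
non-fatal ASCVD states are mutually reachable.

This module owns the state space, probability/rate conversions, transition
matrix construction from a stratified probability table, cohort trace
propagation, and present-value totals.
"""

from __future__ import annotations

import math
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """A transition table or matrix violates a structural constraint."""


class HealthState(str, Enum):
    """Health states of the cohort model.

    The disease-free state is split by statin status so that treatment
    costs, the small statin disutility, and the treated transition hazards
    can be attached to state occupancy directly.  Non-fatal acute myocardial
    infarction is kept separate from other ischemic heart disease because
    their hospitalization costs differ several-fold.
    """

    DISEASE_FREE_UNTREATED = "disease_free_untreated"
    DISEASE_FREE_ON_STATIN = "disease_free_on_statin"
    NONFATAL_ACUTE_MI = "nonfatal_acute_MI"
    NONFATAL_OTHER_IHD = "nonfatal_other_IHD"
    NONFATAL_IS = "nonfatal_IS"
    ADVERSE_DIABETES = "adverse_diabetes"
    ADVERSE_MYOPATHY_RECOVERED = "adverse_myopathy_recovered"
    FATAL_ASCVD = "fatal_ASCVD"
    FATAL_NON_ASCVD = "fatal_non_ASCVD"


STATES: tuple[HealthState, ...] = tuple(HealthState)
N_STATES = len(STATES)
STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(STATES)}

NONFATAL_ASCVD = (
    HealthState.NONFATAL_ACUTE_MI,
    HealthState.NONFATAL_OTHER_IHD,
    HealthState.NONFATAL_IS,
)
#: States that count as "has experienced an ASCVD event".
ASCVD_STATES = NONFATAL_ASCVD + (HealthState.FATAL_ASCVD,)
ABSORBING = (HealthState.FATAL_ASCVD, HealthState.FATAL_NON_ASCVD)
#: States from which a first ASCVD event can still occur.
NON_ASCVD_STATES = tuple(s for s in STATES if s not in ASCVD_STATES)

_ASCVD_IDX = np.array([STATE_INDEX[s] for s in ASCVD_STATES])
_NON_ASCVD_IDX = np.array([STATE_INDEX[s] for s in NON_ASCVD_STATES])

#: Five-year age bands of the transition inputs; the last band covers six
#: years (70-75 inclusive) and is carried forward for older ages.
AGE_BANDS: tuple[str, ...] = (
    "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-75",
)
_BAND_STARTS = np.array([30, 35, 40, 45, 50, 55, 60, 65, 70])
#: Integer mid-band entry ages used for band-level sub-cohorts.
BAND_MIDPOINTS: tuple[int, ...] = (32, 37, 42, 47, 52, 57, 62, 67, 72)

#: Wildcard stratum labels for rows that are pooled over sex and age
#: (post-first-event transitions, which use whole-population averages).
POOLED = "all"


def band_for_age(age: float) -> str:
    """Map an age in years to its 5-year band; ages >= 70 map to '70-75'."""
    if age < 30:
        raise ValueError(f"age {age} below the modeled range (30+)")
    idx = int(np.searchsorted(_BAND_STARTS, age, side="right")) - 1
    return AGE_BANDS[min(idx, len(AGE_BANDS) - 1)]


# ---------------------------------------------------------------------------
# probability conversions
# ---------------------------------------------------------------------------

def annualize_probability(p10):
    """Convert a 10-year cumulative probability to an annual probability.

    Uses the constant-hazard conversion ``r = 1 - exp(ln(1 - p) / 10)``.
    Accepts scalars or arrays; the input must lie in ``[0, 1)``.
    """
    arr = np.asarray(p10, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1):
        raise ValueError("10-year probability must lie in [0, 1)")
    out = -np.expm1(np.log1p(-arr) / 10.0)
    return float(out) if np.isscalar(p10) or arr.ndim == 0 else out

def compound_probability(p1, years):
    """Cumulative probability of at least one event in ``years`` cycles.

    Inverse of :func:`annualize_probability` when ``years = 10``:
    ``1 - (1 - p1) ** years``.
    """
    if years < 0:
        raise ValueError("years must be non-negative")
    arr = np.asarray(p1, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("annual probability must lie in [0, 1]")
    out = 1.0 - (1.0 - arr) ** years
    return float(out) if np.isscalar(p1) or arr.ndim == 0 else out


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discounting with cycle 0 undiscounted.

    ``rate`` is the per-year discount fraction (base case 0.05; sensitivity
    range 0 to 0.08).
    """

    rate: float = 0.05

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("discount rate must be non-negative")

    def factors(self, n_cycles: int) -> np.ndarray:
        """Discount factor per cycle index 0..n_cycles-1."""
        return (1.0 + self.rate) ** -np.arange(n_cycles)


# ---------------------------------------------------------------------------
# transition table
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["sex", "age_group", "risk_group", "from_state", "to_state",
                  "horizon", "value"]
#: Token used in tables for the disease-free origin (both statin strata
#: share the same underlying hazards; treatment modifies them downstream).
DISEASE_FREE = "disease_free"


class TransitionTable:
    """Stratified annual transition probabilities.

    Rows are keyed by ``(sex, age_group, risk_group, from_state)`` and map
    destination states to annual probabilities.  On construction, rows
    flagged as 10-year cumulative probabilities (``horizon == "p10"``) are
    annualized: the total exit probability of the row is converted with the
    constant-hazard formula and allocated to destinations in proportion to
    their cumulative incidences.  (Converting each destination separately
    would shrink the total — cause-specific cumulative incidences compete,
    so their marginal annualizations do not add up — and the ten-cycle
    cumulative incidence would no longer reproduce the input.)
    Post-first-event rows may be pooled over sex and age using the wildcard
    label ``"all"``; lookups fall back to the pooled row when a stratified
    one is absent.

    The on-disk form is a CSV with columns
    ``sex, age_group, risk_group, from_state, to_state, horizon, value``
    where ``horizon`` is ``p10`` or ``p1``.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _TABLE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"transition table missing columns {missing}")
        df = frame.loc[:, _TABLE_COLUMNS].copy()
        bad_horizon = set(df["horizon"].unique()) - {"p10", "p1"}
        if bad_horizon:
            raise ValidationError(f"unknown horizon flags {sorted(bad_horizon)}")
        bad_bands = set(df["age_group"].unique()) - set(AGE_BANDS) - {POOLED}
        if bad_bands:
            raise ValidationError(f"unknown age groups {sorted(bad_bands)}")
        is_p10 = (df["horizon"] == "p10").to_numpy()
        values = df["value"].to_numpy(dtype=float)
        if np.any(values < 0) or np.any(values > 1):
            raise ValidationError("transition probabilities must lie in [0, 1]")
        if np.any(values[is_p10] >= 1):
            raise ValidationError("10-year probabilities must be < 1")
        annual = values.copy()
        if is_p10.any():
            key_cols = ["sex", "age_group", "risk_group", "from_state"]
            if (df.groupby(key_cols)["horizon"].nunique() > 1).any():
                raise ValidationError(
                    "a transition row mixes p10 and p1 horizons")
            totals = df.groupby(key_cols)["value"].transform("sum").to_numpy()
            if np.any(totals[is_p10] >= 1):
                raise ValidationError(
                    "10-year exit probabilities of a row must sum to < 1")
            with np.errstate(invalid="ignore", divide="ignore"):
                share = np.where(totals > 0, values / np.where(totals > 0,
                                                               totals, 1.0), 0.0)
            r_total = np.zeros_like(totals)
            r_total[is_p10] = annualize_probability(totals[is_p10])
            annual[is_p10] = (share * r_total)[is_p10]
        df["annual"] = annual
        self._frame = df
        self._rows: dict[tuple, dict[str, float]] = {}
        for key, grp in df.groupby(
            ["sex", "age_group", "risk_group", "from_state"], sort=False
        ):
            row = dict(zip(grp["to_state"], grp["annual"]))
            total = sum(row.values())
            if total > 1.0 + 1e-9:
                raise ValidationError(
                    f"outgoing annual probabilities sum to {total:.6f} > 1 "
                    f"for stratum {key}"
                )
            self._rows[tuple(key)] = row

    @property
    def frame(self) -> pd.DataFrame:
        """The validated table (with an ``annual`` column added)."""
        return self._frame

    @classmethod
    def from_csv(cls, path) -> "TransitionTable":
        return cls(pd.read_csv(path, dtype={"value": float}))

    def to_csv(self, path) -> None:
        self._frame.loc[:, _TABLE_COLUMNS].to_csv(path, index=False)

    def annual_probs(
        self, sex: str, age_group: str, risk_group: str, from_state: str
    ) -> dict[str, float]:
        """Annual probabilities out of ``from_state`` for one stratum.

        Falls back to the pooled ``("all", "all")`` row, then to a pooled
        row with risk group ``overall``, before failing.
        """
        for key in (
            (sex, age_group, risk_group, from_state),
            (POOLED, POOLED, risk_group, from_state),
            (POOLED, POOLED, "overall", from_state),
        ):
            if key in self._rows:
                return self._rows[key]
        raise ValidationError(
            f"transition table has no row for stratum "
            f"(sex={sex!r}, age_group={age_group!r}, risk_group={risk_group!r}, "
            f"from_state={from_state!r})"
        )

    def has_row(self, sex: str, age_group: str, risk_group: str,
                from_state: str) -> bool:
        try:
            self.annual_probs(sex, age_group, risk_group, from_state)
            return True
        except ValidationError:
            return False


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------

_DF_TARGETS = (
    HealthState.NONFATAL_ACUTE_MI,
    HealthState.NONFATAL_OTHER_IHD,
    HealthState.NONFATAL_IS,
    HealthState.FATAL_ASCVD,
    HealthState.FATAL_NON_ASCVD,
)
_POST_EVENT_TARGETS = {
    HealthState.NONFATAL_ACUTE_MI: (
        HealthState.NONFATAL_OTHER_IHD, HealthState.NONFATAL_IS,
        HealthState.FATAL_ASCVD, HealthState.FATAL_NON_ASCVD),
    HealthState.NONFATAL_OTHER_IHD: (
        HealthState.NONFATAL_ACUTE_MI, HealthState.NONFATAL_IS,
        HealthState.FATAL_ASCVD, HealthState.FATAL_NON_ASCVD),
    HealthState.NONFATAL_IS: (
        HealthState.NONFATAL_ACUTE_MI, HealthState.NONFATAL_OTHER_IHD,
        HealthState.FATAL_ASCVD, HealthState.FATAL_NON_ASCVD),
}


def _fill_row(matrix: np.ndarray, row_state: HealthState,
              probs: Mapping[HealthState, float], stratum: str) -> None:
    i = STATE_INDEX[row_state]
    total = 0.0
    for to_state, p in probs.items():
        matrix[i, STATE_INDEX[to_state]] = p
        total += p
    if total > 1.0 + 1e-12:
        raise ValidationError(
            f"row {row_state.value} for {stratum} sums to {total:.6f} > 1"
        )
    # clip sub-epsilon overshoot, residual mass stays in place
    matrix[i, i] = max(1.0 - total, 0.0)


def build_transition_matrix(
    table: TransitionTable,
    sex: str,
    age_group: str,
    risk_group: str,
    treatment=None,
    *,
    post_event_group: str = "overall",
    event_multiplier: float = 1.0,
    df_multipliers: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Assemble the annual transition matrix for one stratum.

    Disease-free hazards come from the requested ``risk_group`` rows;
    post-first-event hazards use the whole-population (``overall``) rows,
    reflecting the pooling of sparse post-event transitions.  If
    ``treatment`` is given (an object with ``rr_nonfatal_ihd``,
    ``rr_nonfatal_is``, ``rr_fatal_ascvd``, ``p_adverse_diabetes``,
    ``p_adverse_myopathy``, ``p_discontinue_other`` and
    ``annual_discontinuation`` attributes), the on-statin disease-free row
    gets the relative risks applied plus per-cycle adverse-event exits.
    ``event_multiplier`` scales all event hazards (used for carrying the last
    age band beyond its range); ``df_multipliers`` scales individual
    disease-free exit probabilities by destination state value (used to
    carry a baseline risk-stratum ratio across age bands).

    Rows sum to exactly 1 (residual mass stays in the origin state);
    absorbing rows are unit vectors.
    """
    stratum = f"(sex={sex}, age_group={age_group}, risk_group={risk_group})"
    m = np.zeros((N_STATES, N_STATES))

    df_raw = table.annual_probs(sex, age_group, risk_group, DISEASE_FREE)
    df_probs = {
        t: event_multiplier * df_raw.get(t.value, 0.0) for t in _DF_TARGETS
    }
    if df_multipliers is not None:
        df_probs = {
            t: min(p * df_multipliers.get(t.value, 1.0), 1.0)
            for t, p in df_probs.items()
        }
    _fill_row(m, HealthState.DISEASE_FREE_UNTREATED, df_probs, stratum)

    # on-statin row: same underlying hazards, modified by treatment
    statin_probs = dict(df_probs)
    if treatment is not None:
        statin_probs[HealthState.NONFATAL_ACUTE_MI] *= treatment.rr_nonfatal_ihd
        statin_probs[HealthState.NONFATAL_OTHER_IHD] *= treatment.rr_nonfatal_ihd
        statin_probs[HealthState.NONFATAL_IS] *= treatment.rr_nonfatal_is
        statin_probs[HealthState.FATAL_ASCVD] *= treatment.rr_fatal_ascvd
        statin_probs[HealthState.ADVERSE_DIABETES] = treatment.p_adverse_diabetes
        statin_probs[HealthState.ADVERSE_MYOPATHY_RECOVERED] = (
            treatment.p_adverse_myopathy
        )
        if getattr(treatment, "annual_discontinuation", False):
            # applied to the event-free residual (competing exits)
            statin_probs[HealthState.DISEASE_FREE_UNTREATED] = (
                treatment.p_discontinue_other
                * max(1.0 - sum(statin_probs.values()), 0.0)
            )
    _fill_row(m, HealthState.DISEASE_FREE_ON_STATIN, statin_probs, stratum)

    for from_state, targets in _POST_EVENT_TARGETS.items():
        raw = table.annual_probs(sex, age_group, post_event_group,
                                 from_state.value)
        probs = {t: event_multiplier * raw.get(t.value, 0.0) for t in targets}
        _fill_row(m, from_state, probs, stratum)

    # diabetes keeps the untreated disease-free ASCVD hazards of its stratum
    _fill_row(m, HealthState.ADVERSE_DIABETES, df_probs, stratum)
    # recovered myopathy is a one-cycle episode, then disease-free off statin
    m[STATE_INDEX[HealthState.ADVERSE_MYOPATHY_RECOVERED],
      STATE_INDEX[HealthState.DISEASE_FREE_UNTREATED]] = 1.0
    for s in ABSORBING:
        m[STATE_INDEX[s], STATE_INDEX[s]] = 1.0
    return m


# ---------------------------------------------------------------------------
# cohort propagation
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Occupancy history of a cohort.

    ``occupancy[t]`` is the state distribution at cycle ``t`` (cycle 0 is
    model entry); ``inflow[t]`` is the mass that arrived in each state
    during the transition into cycle ``t`` (zero at cycle 0), used to charge
    event-entry (acute-stage) costs and disutilities; ``first_ascvd[t]`` is
    the mass experiencing its first ASCVD event at cycle ``t``.
    """

    occupancy: np.ndarray
    inflow: np.ndarray
    first_ascvd: np.ndarray
    start_age: float
    cycle_length: float = 1.0

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    def validate(self, atol: float = 1e-9) -> None:
        sums = self.occupancy.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=atol):
            raise ValidationError("occupancy rows must each sum to 1")
        for s in ABSORBING:
            col = self.occupancy[:, STATE_INDEX[s]]
            if np.any(np.diff(col) < -atol):
                raise ValidationError(f"absorbing state {s.value} lost mass")


def run_cohort(
    matrices: Sequence[np.ndarray] | Callable[[int], np.ndarray],
    initial_distribution: np.ndarray,
    horizon_cycles: int,
    *,
    start_age: float = 0.0,
) -> CohortTrace:
    """Propagate a cohort through ``horizon_cycles`` annual transitions.

    ``matrices`` is either a sequence of per-cycle matrices or a callable
    mapping cycle index to a matrix (so the cohort can age through bands).
    """
    if horizon_cycles <= 0:
        raise ValueError("horizon must be a positive number of cycles")
    init = np.asarray(initial_distribution, dtype=float)
    if init.shape != (N_STATES,) or not math.isclose(init.sum(), 1.0,
                                                     abs_tol=1e-9):
        raise ValueError("initial distribution must be a length-9 simplex "
                         "vector summing to 1")
    get = matrices if callable(matrices) else matrices.__getitem__

    occ = np.empty((horizon_cycles + 1, N_STATES))
    inflow = np.zeros_like(occ)
    first = np.zeros(horizon_cycles + 1)
    occ[0] = init
    for t in range(horizon_cycles):
        m = get(t)
        nxt = occ[t] @ m
        inflow[t + 1] = nxt - occ[t] * np.diag(m)
        first[t + 1] = occ[t, _NON_ASCVD_IDX] @ m[np.ix_(_NON_ASCVD_IDX,
                                                         _ASCVD_IDX)].sum(axis=1)
        occ[t + 1] = nxt
    return CohortTrace(occupancy=occ, inflow=inflow, first_ascvd=first,
                       start_age=start_age)


def discounted_totals(
    trace: CohortTrace,
    per_state_annual_cost: np.ndarray,
    per_state_annual_utility: np.ndarray,
    spec: DiscountSpec,
    *,
    half_cycle_correction: bool = False,
) -> tuple[float, float]:
    """Present-value cost and QALY totals of a trace.

    ``PV = sum_t w_t (occupancy[t] . values) / (1 + rate)^t`` with cycle 0
    undiscounted.  The optional half-cycle correction halves the weight of
    the first and last cycles (off by default).
    """
    costs = np.asarray(per_state_annual_cost, dtype=float)
    utils = np.asarray(per_state_annual_utility, dtype=float)
    d = spec.factors(trace.n_cycles)
    w = np.ones(trace.n_cycles)
    if half_cycle_correction and trace.n_cycles > 1:
        w[0] = w[-1] = 0.5
    dw = d * w
    return (float(dw @ (trace.occupancy @ costs)),
            float(dw @ (trace.occupancy @ utils)))


def lifetime_ascvd_fraction(trace: CohortTrace) -> float:
    """Probability of ever experiencing an ASCVD event over the trace.

    Accumulated from first-entry mass, not point-in-time occupancy, so
    individuals who move between ASCVD states or die are counted once.
    """
    return float(trace.occupancy[0, _ASCVD_IDX].sum() + trace.first_ascvd.sum())
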
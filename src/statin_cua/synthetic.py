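"""Synthetic cohort generator and transition-table estimator.

The real study population behind this model is a restricted-access Chinese
biobank cohort.  This module emulates its published summary features so the
entire pipeline is exercisable end to end without any data download:

* adults aged 30-75, two sexes, ten regions (5 urban, 5 rural);
* 10-year predicted ASCVD risk scores for a "soft" outcome definition (all
  fatal/non-fatal IHD and ischemic stroke) and a "hard" one (MI, fatal IHD,
  ischemic stroke), with the soft score always at least the hard score and
  cohort medians calibrated to 9.8% / 5.2%;
* time-to-event follow-up whose 12-year soft/hard cumulative event
  fractions calibrate to 16.9% / 11.4%.

Latent hazards are individual-level constant (exponential) hazards on a
log-linear age/sex/region structure with a log-normal frailty.  Calibration
is deterministic given the realized cohort: risk-score scales are solved on
the log-cumulative-hazard scale to match the target medians exactly, and a
single hazard multiplier is solved (Brent root-finding on the analytic
expectation, accounting for competing non-ASCVD death) to match the target
12-year event fraction in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .markov import (AGE_BANDS, DISEASE_FREE, POOLED, TransitionTable,
                     band_for_age)
from .population import default_census_weights, weight_lookup

REGIONS = tuple(f"urban_{i}" for i in range(1, 6)) + \
    tuple(f"rural_{i}" for i in range(1, 6))

#: Fixed region effects on the log hazard (urban areas a little lower).
_REGION_EFFECT = {r: (-0.10 if r.startswith("urban") else 0.10)
                  + 0.05 * (int(r[-1]) - 3) for r in REGIONS}

# log-linear hazard structure: doubling of ASCVD hazard roughly every nine
# years of age, moderately higher hazards in men, individual frailty
_AGE_SLOPE = 0.08          # per year of age on the log hazard
_MALE_EFFECT = 0.35
_FRAILTY_SD = 0.50
_MALE_FRACTION = 0.42      # cohort is majority women, as in large CN cohorts

#: First-event type split conditional on a hard vs soft-only event.
#: Within hard events: acute MI / ischemic stroke / fatal ASCVD.
_HARD_TYPE_SHARES = {"acute_MI": 0.22, "IS": 0.55, "fatal_ASCVD": 0.23}

#: Annual post-first-event hazards, pooled over the population (subsequent
#: events are too sparse to stratify, so the cohort model also pools them).
POST_EVENT_HAZARDS: dict[str, dict[str, float]] = {
    "nonfatal_acute_MI": {"other_IHD": 0.012, "IS": 0.008,
                          "fatal_ASCVD": 0.035, "fatal_non_ASCVD": 0.030},
    "nonfatal_other_IHD": {"acute_MI": 0.010, "IS": 0.008,
                           "fatal_ASCVD": 0.020, "fatal_non_ASCVD": 0.028},
    "nonfatal_IS": {"acute_MI": 0.008, "other_IHD": 0.010,
                    "fatal_ASCVD": 0.030, "fatal_non_ASCVD": 0.032},
}

_EVENT_TO_STATE = {"acute_MI": "nonfatal_acute_MI",
                   "other_IHD": "nonfatal_other_IHD",
                   "IS": "nonfatal_IS"}

EVENT_TYPES = ("acute_MI", "other_IHD", "IS", "fatal_ASCVD", "fatal_non_ASCVD")


@dataclass(frozen=True)
class CalibrationTargets:
    """Published cohort anchors the generator reproduces."""

    median_soft: float = 0.098
    median_hard: float = 0.052
    frac12_soft: float = 0.169
    frac12_hard: float = 0.114
    followup_years: float = 12.0

    def __post_init__(self) -> None:
        probs = [self.median_soft, self.median_hard,
                 self.frac12_soft, self.frac12_hard]
        if any(not 0 < p < 1 for p in probs):
            raise ValueError("calibration targets must lie in (0, 1)")
        if self.median_hard >= self.median_soft:
            raise ValueError("hard-outcome median must be below the soft one")
        if self.frac12_hard >= self.frac12_soft:
            raise ValueError("hard-event fraction must be below the soft one")


def _gompertz_death_hazard(age: np.ndarray) -> np.ndarray:
    """Annual non-ASCVD death hazard, Gompertz in age."""
    return 0.004 * np.exp(0.09 * (age - 50.0))


def generate_cohort(n: int, seed: int,
                    calibration_targets: CalibrationTargets | None = None,
                    census_weights: pd.DataFrame | None = None) -> pd.DataFrame:
    """Draw a synthetic screening cohort of ``n`` individuals.

    Returns a data frame with columns ``id, age, sex, region, risk_soft,
    risk_hard`` plus the latent columns ``hazard_soft`` (calibrated annual
    first-ASCVD-event hazard), ``hazard_death`` (annual non-ASCVD death
    hazard) and ``hard_share`` (probability a first soft event is also a
    hard event).  Reproducible by seed.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    targets = calibration_targets or CalibrationTargets()
    weights = default_census_weights() if census_weights is None \
        else census_weights
    rng = np.random.default_rng(seed)

    band_probs = weights.groupby("age_group", sort=False)["weight"].sum()
    band_probs = band_probs.reindex(AGE_BANDS).fillna(0.0)
    band_idx = rng.choice(len(AGE_BANDS), size=n,
                          p=band_probs.to_numpy() / band_probs.sum())
    starts = np.array([int(b.split("-")[0]) for b in AGE_BANDS])
    widths = np.array([int(b.split("-")[1]) - int(b.split("-")[0]) + 1
                       for b in AGE_BANDS])
    age = starts[band_idx] + rng.random(n) * widths[band_idx]
    age = np.clip(age, 30.0, 75.0)

    male = rng.random(n) < _MALE_FRACTION
    sex = np.where(male, "male", "female")
    region = rng.choice(REGIONS, size=n)
    region_eff = np.array([_REGION_EFFECT[r] for r in region])

    log_raw = (_AGE_SLOPE * (age - 52.5) + _MALE_EFFECT * male
               + region_eff + _FRAILTY_SD * rng.standard_normal(n))
    lam_raw = np.exp(log_raw)
    med_raw = float(np.median(lam_raw))

    # predicted risk scores: uniform rescaling on the cumulative-hazard
    # scale pins the cohort median at the target exactly
    c_soft = -np.log1p(-targets.median_soft) / 10.0 / med_raw
    c_hard = -np.log1p(-targets.median_hard) / 10.0 / med_raw
    risk_soft = -np.expm1(-10.0 * c_soft * lam_raw)
    risk_hard = -np.expm1(-10.0 * c_hard * lam_raw)

    # true event hazards: one multiplier matches the expected soft-event
    # fraction at the follow-up horizon under competing non-ASCVD death
    lam_death = _gompertz_death_hazard(age)
    years = targets.followup_years

    def expected_soft_fraction(c: float) -> float:
        lam_s = c * lam_raw
        tot = lam_s + lam_death
        return float(np.mean(lam_s / tot * -np.expm1(-years * tot)))

    lo, hi = 1e-9, 1.0
    while expected_soft_fraction(hi) < targets.frac12_soft:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("unattainable soft-event calibration target")
    c_event = brentq(lambda c: expected_soft_fraction(c) - targets.frac12_soft,
                     lo, hi, xtol=1e-12)
    hazard_soft = c_event * lam_raw
    hard_share = targets.frac12_hard / targets.frac12_soft

    return pd.DataFrame({
        "id": np.arange(n),
        "age": age,
        "sex": sex,
        "region": region,
        "risk_soft": risk_soft,
        "risk_hard": risk_hard,
        "hazard_soft": hazard_soft,
        "hazard_death": lam_death,
        "hard_share": np.full(n, hard_share),
    })


def recalibrate_risk(risks: np.ndarray, regions: np.ndarray,
                     observed_by_region: dict[str, float]) -> np.ndarray:
    """Rescale predicted risks so regional means match observed risks.

    Within each region the risks are rescaled on the log-cumulative-hazard
    scale, ``r' = 1 - (1 - r)^c``, with ``c`` solved so the regional mean
    equals the observed 10-year risk.  The transform is strictly monotone,
    so within-region ordering is preserved.
    """
    risks = np.asarray(risks, dtype=float)
    regions = np.asarray(regions)
    out = risks.copy()
    for region, observed in observed_by_region.items():
        if not 0 < observed < 1:
            raise ValueError(
                f"observed risk for region {region!r} must be in (0, 1)")
        mask = regions == region
        if not mask.any():
            continue
        r = risks[mask]

        def mean_at(c: float) -> float:
            return float(np.mean(-np.expm1(c * np.log1p(-r))))

        lo, hi = 1e-9, 1.0
        while mean_at(hi) < observed:
            hi *= 2.0
            if hi > 1e9:
                raise ValueError(
                    f"cannot match observed risk {observed} in region {region!r}")
        c = brentq(lambda x: mean_at(x) - observed, lo, hi, xtol=1e-12)
        out[mask] = -np.expm1(c * np.log1p(-r))
    return out


def simulate_followup(cohort: pd.DataFrame, years: float = 12.0,
                      seed: int = 0) -> pd.DataFrame:
    """Simulate event histories under the cohort's latent hazards.

    First events are exponential competing risks between the soft-ASCVD
    hazard and non-ASCVD death; a first soft event is typed (acute MI /
    other IHD / IS / fatal ASCVD) by the cohort's hard-event share and the
    within-hard type split.  Survivors of a non-fatal first event accrue
    subsequent events from the pooled post-event hazards until death or
    censoring at ``years``.

    Returns records with columns ``id, event, time`` (years from entry);
    individuals without any event by the censor date produce no rows.
    """
    if years <= 0:
        raise ValueError("follow-up duration must be positive")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    lam_s = cohort["hazard_soft"].to_numpy(dtype=float)
    lam_d = cohort["hazard_death"].to_numpy(dtype=float)
    hard_share = cohort["hard_share"].to_numpy(dtype=float)
    ids = cohort["id"].to_numpy()

    tot = lam_s + lam_d
    with np.errstate(divide="ignore"):
        t_first = np.where(tot > 0, rng.exponential(1.0, n) / np.where(tot > 0, tot, 1.0), np.inf)
    observed = t_first <= years
    u_type = rng.random(n)
    is_soft = u_type < np.divide(lam_s, tot, out=np.zeros_like(lam_s),
                                 where=tot > 0)

    # type the soft events: hard sub-events then the soft-only remainder
    u_sub = rng.random(n)
    types = np.empty(n, dtype=object)
    mi_cut = hard_share * _HARD_TYPE_SHARES["acute_MI"]
    is_cut = mi_cut + hard_share * _HARD_TYPE_SHARES["IS"]
    fatal_cut = is_cut + hard_share * _HARD_TYPE_SHARES["fatal_ASCVD"]
    types[u_sub < mi_cut] = "acute_MI"
    types[(u_sub >= mi_cut) & (u_sub < is_cut)] = "IS"
    types[(u_sub >= is_cut) & (u_sub < fatal_cut)] = "fatal_ASCVD"
    types[u_sub >= fatal_cut] = "other_IHD"

    rows: list[tuple] = []
    followup_idx = []
    for i in np.flatnonzero(observed):
        if is_soft[i]:
            ev = types[i]
            rows.append((ids[i], ev, t_first[i]))
            if ev in _EVENT_TO_STATE:
                followup_idx.append((i, _EVENT_TO_STATE[ev], t_first[i]))
        else:
            rows.append((ids[i], "fatal_non_ASCVD", t_first[i]))

    # subsequent events for survivors of a non-fatal first event
    for i, state, t in followup_idx:
        while True:
            hazards = POST_EVENT_HAZARDS[state]
            targets = list(hazards)
            lam = np.array([hazards[k] for k in targets])
            total = lam.sum()
            t = t + rng.exponential(1.0 / total)
            if t > years:
                break
            ev = targets[rng.choice(len(targets), p=lam / total)]
            rows.append((ids[i], ev, t))
            if ev.startswith("fatal"):
                break
            state = _EVENT_TO_STATE[ev]

    return pd.DataFrame(rows, columns=["id", "event", "time"]).sort_values(
        ["id", "time"], kind="stable", ignore_index=True)


# ---------------------------------------------------------------------------
# transition-table estimation
# ---------------------------------------------------------------------------

def _first_events(events: pd.DataFrame) -> pd.DataFrame:
    if events.empty:
        return events
    return events.sort_values(["id", "time"], kind="stable").groupby(
        "id", as_index=False).first()


def estimate_transition_table(events: pd.DataFrame, cohort: pd.DataFrame,
                              census_weights: pd.DataFrame | None = None,
                              threshold: float | None = None,
                              model: str = "soft",
                              window: float = 10.0) -> TransitionTable:
    """Estimate a stratified transition table from simulated follow-up.

    Disease-free rows are 10-year cumulative first-event incidences per
    (sex, age band) and risk group: ``overall`` always, plus ``eligible`` /
    ``non_eligible`` split at ``threshold`` (a fraction) on the requested
    model's risk score.  Censoring before the window is treated as
    event-free (loss to follow-up in the emulated cohort is negligible).
    Post-first-event rows are pooled over sex and age (wildcard ``"all"``
    strata): census-weighted averages of cell-level estimates, where each
    cell is a (sex, band) group of first-event survivors.

    Empty strata are recorded as missing (with a warning), never as zero.
    """
    if model not in {"soft", "hard"}:
        raise ValueError("model must be 'soft' or 'hard'")
    weights = default_census_weights() if census_weights is None \
        else census_weights
    wl = weight_lookup(weights)

    cohort = cohort.copy()
    cohort["age_group"] = [band_for_age(a) for a in cohort["age"]]
    firsts = _first_events(events)
    first_by_id: dict = {}
    if not firsts.empty:
        in_window = firsts[firsts["time"] <= window]
        first_by_id = dict(zip(in_window["id"], in_window["event"]))

    groups: dict[str, np.ndarray] = {
        "overall": np.ones(len(cohort), dtype=bool)}
    if threshold is not None:
        score = cohort[f"risk_{model}"].to_numpy(dtype=float)
        eligible = score >= threshold
        groups["eligible"] = eligible
        groups["non_eligible"] = ~eligible

    for gname, gmask in groups.items():
        cohort[f"_member_{gname}"] = gmask

    rows: list[tuple] = []
    for (sex, band), cell in cohort.groupby(["sex", "age_group"], sort=False):
        for gname in groups:
            sub_ids = cell.loc[cell[f"_member_{gname}"], "id"].to_numpy()
            if len(sub_ids) == 0:
                warnings.warn(
                    f"empty stratum (sex={sex}, age_group={band}, "
                    f"risk_group={gname}); rows recorded as missing")
                continue
            counts = {ev: 0 for ev in EVENT_TYPES}
            for sid in sub_ids:
                ev = first_by_id.get(sid)
                if ev is not None:
                    counts[ev] += 1
            n_cell = len(sub_ids)
            probs = _cap_row({ev: counts[ev] / n_cell for ev in EVENT_TYPES},
                             f"(sex={sex}, age_group={band}, "
                             f"risk_group={gname})")
            for ev in EVENT_TYPES:
                rows.append((sex, band, gname, DISEASE_FREE,
                             _EVENT_TO_STATE.get(ev, ev), "p10", probs[ev]))

    rows.extend(_post_event_rows(events, cohort, wl, window))
    return TransitionTable(pd.DataFrame(
        rows, columns=["sex", "age_group", "risk_group", "from_state",
                       "to_state", "horizon", "value"]))


def _cap_row(probs: dict[str, float], stratum: str,
             limit: float = 1.0 - 1e-6) -> dict[str, float]:
    """Keep a row of 10-year exit probabilities strictly below 1.

    Degenerate strata (a handful of individuals, all with events) can
    produce empirical cumulative incidences of 1, which have no finite
    annual hazard; they are rescaled to just under 1 with a warning.
    """
    total = sum(probs.values())
    if total < limit:
        return probs
    warnings.warn(
        f"10-year exit probabilities sum to {total:.4f} in degenerate "
        f"stratum {stratum}; rescaled below 1")
    scale = limit / total
    return {k: v * scale for k, v in probs.items()}


def _post_event_rows(events: pd.DataFrame, cohort: pd.DataFrame,
                     wl: dict, window: float) -> list[tuple]:
    """Pooled post-first-event rows, census-weighted over (sex, band) cells."""
    rows: list[tuple] = []
    if events.empty:
        for state, hazards in POST_EVENT_HAZARDS.items():
            for target in hazards:
                rows.append((POOLED, POOLED, "overall", state,
                             _EVENT_TO_STATE.get(target, target), "p10", 0.0))
        return rows

    cell_of = dict(zip(cohort["id"], zip(cohort["sex"], cohort["age_group"])))
    ev_sorted = events.sort_values(["id", "time"], kind="stable")

    # per from-state, per cell: entrants and their next transition in-window
    for state in POST_EVENT_HAZARDS:
        targets = [_EVENT_TO_STATE.get(t, t) for t in POST_EVENT_HAZARDS[state]]
        per_cell: dict[tuple, dict] = {}
        for pid, grp in ev_sorted.groupby("id", sort=False):
            evs = grp["event"].tolist()
            times = grp["time"].tolist()
            for k, (ev, t) in enumerate(zip(evs, times)):
                if _EVENT_TO_STATE.get(ev) != state:
                    continue
                cell = cell_of[pid]
                tally = per_cell.setdefault(cell, {"n": 0, **{x: 0 for x in targets}})
                tally["n"] += 1
                if k + 1 < len(evs) and times[k + 1] - t <= window:
                    nxt = _EVENT_TO_STATE.get(evs[k + 1], evs[k + 1])
                    if nxt in tally:
                        tally[nxt] += 1
        if not per_cell:
            warnings.warn(f"no entrants into {state}; post-event rows "
                          f"recorded as missing")
            continue
        total_w = sum(wl.get(cell, 0.0) for cell in per_cell) or \
            float(len(per_cell))
        probs = {}
        for target in targets:
            value = 0.0
            for cell, tally in per_cell.items():
                w = wl.get(cell, 1.0) / total_w
                value += w * tally[target] / tally["n"]
            probs[target] = value
        probs = _cap_row(probs, f"(from_state={state}, pooled)")
        for target in targets:
            rows.append((POOLED, POOLED, "overall", state, target, "p10",
                         probs[target]))
    return rows
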
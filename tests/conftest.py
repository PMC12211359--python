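"""Shared fixtures: hand-built transition tables and a synthetic study.

The synthetic-study fixtures (cohort, follow-up, estimated tables) are
session-scoped because generating 50,000 individuals and estimating
stratified tables takes a few seconds and several test modules share them.
"""

from __future__ import annotations

import warnings

import pandas as pd
import pytest

from statin_cua.markov import AGE_BANDS, DISEASE_FREE, POOLED, TransitionTable
from statin_cua.population import SEXES
from statin_cua.strategy import eligibility_table
from statin_cua.synthetic import (estimate_transition_table, generate_cohort,
                                  simulate_followup)

COHORT_SEED = 20190101
COHORT_N = 50_000
SOFT_TEST_GRID = (20.0, 19.0, 18.0, 17.0)


def make_uniform_table(p_mi=0.002, p_ihd=0.006, p_is=0.004, p_fatal=0.002,
                       p_death=0.010, *, eligible_scale=1.0,
                       non_eligible_scale=1.0, post_fatal=0.03,
                       post_cross=0.01, post_death=0.03) -> TransitionTable:
    """A transition table with identical hazards in every (sex, band) cell.

    ``eligible_scale`` / ``non_eligible_scale`` scale the disease-free event
    probabilities of the stratified rows relative to the overall rows.
    """
    rows = []
    df_targets = {
        "nonfatal_acute_MI": p_mi, "nonfatal_other_IHD": p_ihd,
        "nonfatal_IS": p_is, "fatal_ASCVD": p_fatal,
        "fatal_non_ASCVD": p_death,
    }
    for sex in SEXES:
        for band in AGE_BANDS:
            for group, scale in (("overall", 1.0),
                                 ("eligible", eligible_scale),
                                 ("non_eligible", non_eligible_scale)):
                for target, p in df_targets.items():
                    value = p * scale if target != "fatal_non_ASCVD" else p
                    rows.append((sex, band, group, DISEASE_FREE, target,
                                 "p1", value))
    post = {
        "nonfatal_acute_MI": ["nonfatal_other_IHD", "nonfatal_IS"],
        "nonfatal_other_IHD": ["nonfatal_acute_MI", "nonfatal_IS"],
        "nonfatal_IS": ["nonfatal_acute_MI", "nonfatal_other_IHD"],
    }
    for state, targets in post.items():
        for target in targets:
            rows.append((POOLED, POOLED, "overall", state, target, "p1",
                         post_cross))
        rows.append((POOLED, POOLED, "overall", state, "fatal_ASCVD", "p1",
                     post_fatal))
        rows.append((POOLED, POOLED, "overall", state, "fatal_non_ASCVD",
                     "p1", post_death))
    return TransitionTable(pd.DataFrame(
        rows, columns=["sex", "age_group", "risk_group", "from_state",
                       "to_state", "horizon", "value"]))


def constant_eligibility(fraction: float) -> pd.DataFrame:
    rows = [(sex, band, fraction) for sex in SEXES for band in AGE_BANDS]
    return pd.DataFrame(rows, columns=["sex", "age_group",
                                       "eligible_fraction"])


@pytest.fixture(scope="session")
def uniform_table() -> TransitionTable:
    return make_uniform_table()


@pytest.fixture(scope="session")
def study_cohort() -> pd.DataFrame:
    return generate_cohort(COHORT_N, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def study_events(study_cohort) -> pd.DataFrame:
    return simulate_followup(study_cohort, years=12.0, seed=COHORT_SEED + 1)


@pytest.fixture(scope="session")
def study_tables(study_cohort, study_events):
    """Stratified tables and eligibility per soft-model test threshold."""
    tables, elig = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t in SOFT_TEST_GRID:
            tables[t] = estimate_transition_table(
                study_events, study_cohort, threshold=t / 100.0, model="soft")
            elig[t] = eligibility_table(study_cohort, "soft", t)
    return tables, elig
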
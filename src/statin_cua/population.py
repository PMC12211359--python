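"""Census weight tables (sex x 5-year age band).

Strategy-level results are population expectations: band-level sub-cohort
results are averaged with weights from a national population structure so
that the modeled cohort mirrors the screening-age population rather than
the study sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .markov import AGE_BANDS

# Approximate 2019 national population (millions) in the screening age
# range, by 5-year band, and the male share per band.  A synthetic
# smooth-round of published yearbook structure, adequate for weighting.
_BAND_POP = np.array([124.0, 99.0, 93.0, 114.0, 121.0, 99.0, 74.0, 74.0, 52.0])
_MALE_SHARE = np.array([0.510, 0.510, 0.508, 0.505, 0.502, 0.500,
                        0.496, 0.490, 0.482])

WEIGHT_COLUMNS = ["sex", "age_group", "weight"]
SEXES = ("female", "male")


def default_census_weights() -> pd.DataFrame:
    """Synthetic census-style weight table (sex x age band, sums to 1)."""
    rows = []
    for band, pop, male in zip(AGE_BANDS, _BAND_POP, _MALE_SHARE):
        rows.append(("female", band, pop * (1 - male)))
        rows.append(("male", band, pop * male))
    df = pd.DataFrame(rows, columns=WEIGHT_COLUMNS)
    df["weight"] /= df["weight"].sum()
    return df


def uniform_census_weights() -> pd.DataFrame:
    """Equal weight for every (sex, age band) cell."""
    rows = [(sex, band, 1.0) for band in AGE_BANDS for sex in SEXES]
    df = pd.DataFrame(rows, columns=WEIGHT_COLUMNS)
    df["weight"] /= df["weight"].sum()
    return df


def load_census_weights(path) -> pd.DataFrame:
    """Read a weight CSV (columns sex, age_group, weight) and normalize."""
    df = pd.read_csv(path)
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"census weight table missing columns {missing}")
    bad = set(df["age_group"]) - set(AGE_BANDS)
    if bad:
        raise ValueError(f"census weight table has unknown age groups {sorted(bad)}")
    if (df["weight"] < 0).any() or df["weight"].sum() <= 0:
        raise ValueError("census weights must be non-negative with positive sum")
    df = df.loc[:, WEIGHT_COLUMNS].copy()
    df["weight"] /= df["weight"].sum()
    return df


def weight_lookup(weights: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Index a weight table by (sex, age_group)."""
    return {(r.sex, r.age_group): float(r.weight)
            for r in weights.itertuples(index=False)}
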
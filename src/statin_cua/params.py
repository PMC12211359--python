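"""Model parameter manifest.

Every tunable quantity of the cost-utility model lives here with its
base-case value, one-way sensitivity bounds, and probabilistic-sensitivity
distribution family.  Monetary values are 2019 US dollars (converted from
RMB at the fixed 2019 rate of 6.9 RMB per USD); probabilities and rates are
annual fractions unless the name says otherwise.

Bound rules
-----------
``ci95``
    bounds are a published 95% confidence interval.
``pm15pct``
    bounds are +/-15% of the base-case value (used when no interval was
    published).
``urban_rural``
    bounds are the urban and rural values of a national yearbook quantity.
``stated``
    bounds as published by the primary source.
``none``
    the quantity is held fixed everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain model input.

    Attributes
    ----------
    name : str
        Manifest key, also used in config files.
    base, low, high : float
        Base-case value and one-way sensitivity bounds (low <= base <= high).
    distribution : {"lognormal", "beta", "gamma", "fixed"}
        Sampling family for probabilistic sensitivity analysis.  Relative
        risks are log-normal, proportions and utilities beta, costs and
        durations gamma; ``fixed`` parameters are never sampled.
    bound_rule : str
        Provenance of the bounds (see module docstring).
    """

    name: str
    base: float
    low: float
    high: float
    distribution: str
    bound_rule: str = "stated"

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"parameter {self.name!r}: bounds must satisfy "
                f"low <= base <= high, got {self.low}, {self.base}, {self.high}"
            )
        if self.distribution not in {"lognormal", "beta", "gamma", "fixed"}:
            raise ValueError(
                f"parameter {self.name!r}: unknown distribution "
                f"{self.distribution!r}"
            )


def _p(name, base, low, high, dist, rule="stated") -> ParameterSpec:
    return ParameterSpec(name, base, low, high, dist, rule)


#: The full base-case manifest.  Keys are stable API: config files, the PSA
#: sampler and the tornado analysis all address parameters by these names.
TABLE1: dict[str, ParameterSpec] = {
    s.name: s
    for s in [
        # -- statin efficacy (relative risks, 95% CI) and risks -------------
        _p("rr_nonfatal_ihd", 0.67, 0.59, 0.76, "lognormal", "ci95"),
        _p("rr_nonfatal_is", 0.69, 0.58, 0.83, "lognormal", "ci95"),
        _p("rr_fatal_ascvd", 0.83, 0.72, 0.96, "lognormal", "ci95"),
        # trial-observed discontinuation fractions (given as percentages in
        # the source; stored as probabilities)
        _p("p_adverse_diabetes", 0.0030, 0.0026, 0.0035, "beta", "pm15pct"),
        _p("p_adverse_myopathy", 0.0024, 0.0020, 0.0028, "beta", "pm15pct"),
        _p("p_discontinue_other", 0.1186, 0.1008, 0.1364, "beta", "pm15pct"),
        # -- direct costs, USD ----------------------------------------------
        _p("statin_annual", 61.43, 40.20, 112.07, "gamma"),
        _p("exam_per_visit", 4.35, 2.90, 7.25, "gamma"),
        _p("registration_annual", 52.17, 34.78, 86.96, "gamma"),
        _p("hosp_diabetes", 1149.70, 977.25, 1322.14, "gamma", "pm15pct"),
        _p("chronic_diabetes_annual", 835.87, 710.49, 961.25, "gamma", "pm15pct"),
        _p("hosp_myopathy", 1793.36, 1524.35, 2062.36, "gamma", "pm15pct"),
        _p("hosp_acute_mi", 4401.23, 2697.80, 4738.36, "gamma", "urban_rural"),
        _p("hosp_other_ihd", 2037.71, 1093.93, 2372.42, "gamma", "urban_rural"),
        _p("hosp_is", 1421.91, 944.87, 1830.20, "gamma", "urban_rural"),
        _p("chronic_ihd_annual", 427.04, 362.99, 491.10, "gamma", "pm15pct"),
        _p("chronic_is_annual", 242.38, 206.01, 278.74, "gamma", "pm15pct"),
        # -- indirect-cost inputs -------------------------------------------
        _p("days_acute_mi", 8.05, 7.59, 8.30, "gamma", "urban_rural"),
        _p("days_other_ihd", 7.79, 7.73, 7.85, "gamma", "urban_rural"),
        _p("days_is", 10.01, 9.50, 10.73, "gamma", "urban_rural"),
        _p("days_diabetes", 9.39, 8.83, 9.88, "gamma", "urban_rural"),
        _p("days_myopathy", 9.21, 9.03, 9.37, "gamma", "urban_rural"),
        _p("salary_annual", 13116.09, 11148.68, 15083.51, "gamma", "pm15pct"),
        _p("unemployment", 0.052, 0.044, 0.060, "beta", "pm15pct"),
        # -- utility weights -------------------------------------------------
        _p("u_disease_free", 1.0, 1.0, 1.0, "fixed", "none"),
        _p("u_statin", 0.999, 0.998, 1.000, "beta"),
        _p("u_acute", 0.50, 0.20, 0.80, "fixed"),
        _p("u_chronic_ihd", 0.87, 0.75, 0.90, "beta"),
        _p("u_chronic_is", 0.90, 0.90, 0.90, "fixed", "none"),
        _p("u_diabetes", 0.84, 0.79, 0.94, "beta"),
        _p("u_myopathy", 0.56, 0.56, 0.56, "fixed", "none"),
        # -- analysis settings -----------------------------------------------
        _p("discount_rate", 0.05, 0.0, 0.08, "fixed"),
    ]
}

#: Fixed RMB-per-USD conversion used for any optional RMB output column.
RMB_PER_USD = 6.9

#: Willingness-to-pay anchors: 2019 Chinese GDP per capita and three times it.
WTP_BASE = 10274.0
WTP_UPPER = 30823.0


def default_parameters() -> dict[str, float]:
    """Return the base-case parameter mapping ``{name: base value}``."""
    return {name: spec.base for name, spec in TABLE1.items()}


def validate_parameters(params: dict[str, float]) -> list[str]:
    """Return the manifest keys missing from ``params`` (empty if complete)."""
    return [name for name in TABLE1 if name not in params]
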
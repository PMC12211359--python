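"""Published base-case results bundled as worked-example inputs.

These are the strategy-level outcomes (statin-eligible %, lifetime ASCVD
event %, discounted cost in 2019 USD, discounted QALYs) of the published
Chinese cost-utility analysis of statin-initiation risk thresholds that
this package re-implements.  They serve two purposes: worked examples whose
ICER arithmetic, frontier classification and optimal-threshold selection
can be reproduced exactly from printed numbers, and regression anchors for
the analysis code, independent of any synthetic cohort.

The underlying cohort data are access-restricted, so the absolute values
cannot be recomputed here; they are inputs, not outputs, of this package.
"""

from __future__ import annotations

from .strategy import Strategy, StrategyOutcome

# threshold %, statin-eligible %, lifetime ASCVD events %, cost USD, QALYs
_SOFT_BASE = [
    (None, 0.0, 17.22, 2896.97, 13.9445),
    (20.0, 25.4, 15.49, 3058.69, 13.9995),
    (19.0, 26.9, 15.38, 3069.51, 14.0020),
    (18.0, 28.5, 15.29, 3082.78, 14.0039),
    (17.0, 30.2, 15.21, 3099.47, 14.0051),
    (16.0, 32.0, 15.15, 3118.27, 14.0059),
    (15.0, 33.9, 15.08, 3137.52, 14.0070),
    (14.0, 36.0, 15.00, 3160.65, 14.0078),
    (13.0, 38.3, 14.94, 3186.38, 14.0083),
    (12.0, 40.8, 14.89, 3216.52, 14.0080),
    (11.0, 43.6, 14.87, 3252.31, 14.0068),
    (10.0, 46.6, 14.85, 3292.01, 14.0054),
]

_HARD_BASE = [
    (None, 0.0, 17.42, 2904.86, 13.9412),
    (15.0, 19.6, 16.10, 3031.48, 13.9846),
    (14.0, 21.3, 15.92, 3038.66, 13.9893),
    (13.0, 23.1, 15.77, 3049.30, 13.9932),
    (12.0, 25.1, 15.61, 3061.80, 13.9974),
    (11.0, 27.3, 15.46, 3078.87, 14.0007),
    (10.0, 29.7, 15.32, 3099.32, 14.0038),
    (9.0, 32.6, 15.19, 3126.75, 14.0058),
    (8.0, 35.7, 15.08, 3160.21, 14.0071),
    (7.5, 37.5, 15.04, 3180.38, 14.0072),
    (7.0, 39.4, 15.00, 3203.11, 14.0071),
    (6.0, 43.6, 14.92, 3255.13, 14.0065),
    (5.0, 48.6, 14.91, 3322.82, 14.0034),
]

# soft model by age stratum: threshold %, eligible %, cost, QALYs
_SOFT_AGE_30_59 = [
    (None, 0.0, 2631.12, 15.3115),
    (20.0, 10.4, 2738.66, 15.3309),
    (19.0, 11.6, 2744.67, 15.3334),
    (18.0, 12.9, 2753.40, 15.3357),
    (17.0, 14.4, 2766.06, 15.3376),
    (16.0, 16.1, 2780.29, 15.3398),
    (15.0, 18.0, 2796.22, 15.3423),
    (14.0, 20.2, 2816.21, 15.3449),
    (13.0, 22.7, 2839.49, 15.3476),
    (12.0, 25.5, 2868.64, 15.3497),
    (11.0, 28.6, 2904.53, 15.3515),
    (10.0, 32.1, 2946.04, 15.3531),
]

_SOFT_AGE_60_75 = [
    (None, 0.0, 594.47, 7.7303),
    (20.0, 76.0, 1027.76, 7.7842),
    (19.0, 78.5, 1045.31, 7.7848),
    (18.0, 81.1, 1062.60, 7.7852),
    (17.0, 83.4, 1079.46, 7.7855),
    (16.0, 85.6, 1095.50, 7.7856),
    (15.0, 87.5, 1109.24, 7.7858),
    (14.0, 89.4, 1122.76, 7.7858),
    (13.0, 91.1, 1135.70, 7.7858),
    (12.0, 92.7, 1147.44, 7.7858),
    (11.0, 94.1, 1158.44, 7.7856),
    (10.0, 95.5, 1168.64, 7.7855),
]


def _build(model: str, rows, with_events: bool = True) -> list[StrategyOutcome]:
    out = []
    for row in rows:
        if with_events:
            threshold, eligible, events, cost, qalys = row
        else:
            threshold, eligible, cost, qalys = row
            events = None
        out.append(StrategyOutcome(
            strategy=Strategy(model=model, threshold=threshold),
            eligible_pct=eligible, events_pct=events,
            cost=cost, qalys=qalys))
    return out


def soft_outcomes() -> list[StrategyOutcome]:
    """Published base-case ladder of the soft-outcome risk model."""
    return _build("soft", _SOFT_BASE)


def hard_outcomes() -> list[StrategyOutcome]:
    """Published base-case ladder of the hard-outcome risk model."""
    return _build("hard", _HARD_BASE)


def soft_outcomes_by_age(group: str) -> list[StrategyOutcome]:
    """Published age-stratified soft-model ladders ('30-59' or '60-75')."""
    if group == "30-59":
        return _build("soft", _SOFT_AGE_30_59, with_events=False)
    if group == "60-75":
        return _build("soft", _SOFT_AGE_60_75, with_events=False)
    raise ValueError("age group must be '30-59' or '60-75'")
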
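"""Incremental cost-effectiveness analysis.

Strategies are ranked by effectiveness (QALYs); strictly dominated ones
(at least as many costs for no more QALYs) are removed, then adjacent
incremental cost-effectiveness ratios (ICERs) are computed and any strategy
whose ICER exceeds that of a more effective strategy is removed by extended
dominance, iterating until the ICER ladder is strictly increasing.  The
survivors form the efficiency frontier; the optimal strategy at a
willingness-to-pay (WTP) is the most effective frontier member whose ICER
does not exceed it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .strategy import StrategyOutcome

STATUS_REFERENCE = "reference"
STATUS_FRONTIER = "frontier"
STATUS_DOMINATED = "dominated"
STATUS_EXTENDED = "extended_dominance"


@dataclass(frozen=True)
class WTPSpec:
    """Willingness-to-pay anchors (USD per QALY)."""

    per_capita_gdp: float = 10274.0
    upper: float = 30823.0

    def __post_init__(self) -> None:
        if not 0 < self.per_capita_gdp <= self.upper:
            raise ValueError("need 0 < per_capita_gdp <= upper")


@dataclass(frozen=True)
class FrontierEntry:
    outcome: StrategyOutcome
    status: str
    icer: float | None  # vs the previous frontier strategy; None otherwise

    @property
    def label(self) -> str:
        return self.outcome.label


@dataclass(frozen=True)
class FrontierResult:
    """Classification of every strategy plus the ordered frontier."""

    entries: tuple[FrontierEntry, ...]

    @property
    def frontier(self) -> tuple[FrontierEntry, ...]:
        """Reference plus frontier strategies, ascending effectiveness."""
        kept = [e for e in self.entries
                if e.status in (STATUS_REFERENCE, STATUS_FRONTIER)]
        return tuple(sorted(kept, key=lambda e: e.outcome.qalys))

    def status_of(self, label: str) -> str:
        for e in self.entries:
            if e.label == label:
                return e.status
        raise KeyError(label)


def icer(a: StrategyOutcome, b: StrategyOutcome) -> float:
    """Incremental cost per QALY gained, more- vs less-effective strategy."""
    if a.qalys == b.qalys:
        raise ValueError(
            "strategies have equal QALYs; compare by cost (dominance) instead")
    hi, lo = (a, b) if a.qalys > b.qalys else (b, a)
    return (hi.cost - lo.cost) / (hi.qalys - lo.qalys)


def build_frontier(outcomes: list[StrategyOutcome]) -> FrontierResult:
    """Classify strategies into reference / frontier / dominated / extended.

    Duplicate (cost, QALY) pairs keep the first-listed strategy; the later
    copies are flagged dominated with a warning.
    """
    if len(outcomes) < 2:
        raise ValueError("frontier analysis needs at least two strategies")

    status: dict[int, str] = {}
    seen: dict[tuple[float, float], int] = {}
    for i, o in enumerate(outcomes):
        key = (o.cost, o.qalys)
        if key in seen:
            warnings.warn(
                f"strategies {outcomes[seen[key]].label!r} and {o.label!r} "
                f"have identical cost and QALYs; keeping the first")
            status[i] = STATUS_DOMINATED
        else:
            seen[key] = i

    # strict dominance: another strategy is at least as effective and at
    # least as cheap, strictly better on one axis
    for i, o in enumerate(outcomes):
        if i in status:
            continue
        for j, p in enumerate(outcomes):
            if i == j or j in status:
                continue
            if (p.cost <= o.cost and p.qalys >= o.qalys
                    and (p.cost < o.cost or p.qalys > o.qalys)):
                status[i] = STATUS_DOMINATED
                break

    remaining = sorted((i for i in range(len(outcomes)) if i not in status),
                       key=lambda i: (outcomes[i].qalys, outcomes[i].cost))

    # extended dominance: drop any strategy whose ICER exceeds that of the
    # next more effective one, recomputing until the ladder increases
    while True:
        icers = [icer(outcomes[remaining[k]], outcomes[remaining[k - 1]])
                 for k in range(1, len(remaining))]
        bad = next((k for k in range(len(icers) - 1)
                    if icers[k] > icers[k + 1]), None)
        if bad is None:
            break
        status[remaining[bad + 1]] = STATUS_EXTENDED
        del remaining[bad + 1]

    entries = []
    final_icer = {remaining[k]: icers[k - 1]
                  for k in range(1, len(remaining))}
    for i, o in enumerate(outcomes):
        if i == remaining[0]:
            entries.append(FrontierEntry(o, STATUS_REFERENCE, None))
        elif i in final_icer:
            entries.append(FrontierEntry(o, STATUS_FRONTIER, final_icer[i]))
        else:
            entries.append(FrontierEntry(o, status[i], None))
    return FrontierResult(entries=tuple(entries))


def select_optimal(frontier: FrontierResult, wtp: float) -> StrategyOutcome:
    """Most effective frontier strategy whose ICER is affordable at ``wtp``.

    Falls back to the reference strategy when no frontier ICER is below the
    willingness-to-pay.
    """
    best = None
    for entry in frontier.frontier:
        if entry.status == STATUS_REFERENCE:
            best = entry
        elif entry.icer is not None and entry.icer <= wtp:
            best = entry
        else:
            break
    if best is None:
        raise ValueError("frontier is empty")
    return best.outcome


# ---------------------------------------------------------------------------
# matched-proportion comparison of the two risk models
# ---------------------------------------------------------------------------

VERDICT_STRONGLY_DOMINANT = "strongly_dominant"
VERDICT_DOMINATED = "dominated"
VERDICT_ICER = "icer"


@dataclass(frozen=True)
class PairVerdict:
    soft: StrategyOutcome
    hard: StrategyOutcome
    verdict: str
    icer: float | None


def classify_pair(soft: StrategyOutcome, hard: StrategyOutcome) -> PairVerdict:
    """Compare a soft-model strategy against a hard-model comparator."""
    if soft.cost <= hard.cost and soft.qalys >= hard.qalys and \
            (soft.cost < hard.cost or soft.qalys > hard.qalys):
        return PairVerdict(soft, hard, VERDICT_STRONGLY_DOMINANT, None)
    if soft.cost >= hard.cost and soft.qalys <= hard.qalys and \
            (soft.cost > hard.cost or soft.qalys < hard.qalys):
        return PairVerdict(soft, hard, VERDICT_DOMINATED, None)
    if soft.qalys == hard.qalys:
        return PairVerdict(soft, hard, VERDICT_ICER, None)
    return PairVerdict(soft, hard, VERDICT_ICER, icer(soft, hard))


def matched_proportion_comparison(soft_outcomes: list[StrategyOutcome],
                                  hard_outcomes: list[StrategyOutcome],
                                  pairing_tolerance: float = 1.0
                                  ) -> list[PairVerdict]:
    """Pair strategies treating similar population shares and compare them.

    Each soft-model strategy is matched to the hard-model strategy with the
    nearest eligible fraction; pairs further apart than
    ``pairing_tolerance`` percentage points are skipped with a warning.
    """
    verdicts = []
    for soft in soft_outcomes:
        if soft.strategy.is_no_treatment:
            continue
        candidates = [h for h in hard_outcomes
                      if not h.strategy.is_no_treatment]
        if not candidates:
            break
        hard = min(candidates,
                   key=lambda h: abs(h.eligible_pct - soft.eligible_pct))
        gap = abs(hard.eligible_pct - soft.eligible_pct)
        if gap > pairing_tolerance:
            warnings.warn(
                f"no hard-model match within {pairing_tolerance} pp for "
                f"{soft.label} (closest gap {gap:.2f} pp); pair skipped")
            continue
        verdicts.append(classify_pair(soft, hard))
    return verdicts
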
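"""One-way (tornado) and probabilistic sensitivity analysis.

One-way analysis re-runs an evaluation twice with a single parameter at
its bounds.  Probabilistic sensitivity analysis (PSA) jointly samples every
uncertain parameter from its manifest distribution — log-normal for
relative risks, beta for proportions and utilities, gamma for costs and
durations, all moment-matched to the base value and the 95% bound range —
and re-evaluates the strategy set per draw.  Cost-effectiveness
acceptability curves report, per willingness-to-pay, the fraction of draws
in which each strategy has the highest net monetary benefit
(QALYs x WTP - cost).
"""

from __future__ import annotations

from collections.abc import Callable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import TABLE1, ParameterSpec, default_parameters

__all__ = [
    "ParameterSpec", "OneWayResult", "PSAResult", "one_way_sensitivity",
    "tornado", "sample_parameters", "run_psa", "acceptability_curve",
    "default_wtp_grid",
]

#: Normal-range convention: a 95% interval spans 2 x 1.96 standard deviations.
_Z_RANGE = 3.92


@dataclass(frozen=True)
class OneWayResult:
    """ICERs with one parameter at its lower and upper bound."""

    name: str
    low: float
    high: float

    @property
    def swing(self) -> float:
        return abs(self.high - self.low)


def one_way_sensitivity(evaluate: Callable[[Mapping[str, float]], float],
                        param: ParameterSpec,
                        base_params: Mapping[str, float] | None = None
                        ) -> OneWayResult:
    """Evaluate a scalar figure of merit at one parameter's bounds.

    ``evaluate`` maps a full parameter dictionary to the quantity of
    interest (typically the ICER of a strategy pair); all other parameters
    stay at base.
    """
    base = dict(default_parameters())
    if base_params:
        base.update(base_params)
    results = []
    for bound in (param.low, param.high):
        p = dict(base)
        p[param.name] = bound
        results.append(float(evaluate(p)))
    return OneWayResult(name=param.name, low=results[0], high=results[1])


def tornado(evaluate: Callable[[Mapping[str, float]], float],
            specs: Mapping[str, ParameterSpec] | None = None,
            base_params: Mapping[str, float] | None = None) -> pd.DataFrame:
    """One-way results for every parameter, sorted by swing (widest first)."""
    specs = dict(TABLE1) if specs is None else dict(specs)
    rows = []
    for spec in specs.values():
        r = one_way_sensitivity(evaluate, spec, base_params)
        rows.append((r.name, spec.base, spec.low, spec.high,
                     r.low, r.high, r.swing))
    df = pd.DataFrame(rows, columns=["parameter", "base", "low_bound",
                                     "high_bound", "value_at_low",
                                     "value_at_high", "swing"])
    return df.sort_values("swing", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------

def _sd_from_bounds(spec: ParameterSpec) -> float:
    return (spec.high - spec.low) / _Z_RANGE


def sample_parameters(specs: Mapping[str, ParameterSpec],
                      seed) -> dict[str, float]:
    """One joint draw of the uncertain parameters.

    Log-normal parameters use ``meanlog = ln(base)`` and
    ``sdlog = (ln(high) - ln(low)) / 3.92``; beta and gamma parameters are
    moment-matched to mean = base and sd = (high - low) / 3.92; ``fixed``
    parameters return their base value.  Reproducible given ``seed`` (an
    int or a ``numpy.random.Generator``).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    draw: dict[str, float] = {}
    for name, spec in specs.items():
        if spec.distribution == "fixed" or spec.high == spec.low:
            draw[name] = spec.base
            continue
        sd = _sd_from_bounds(spec)
        if spec.distribution == "lognormal":
            sdlog = (np.log(spec.high) - np.log(spec.low)) / _Z_RANGE
            draw[name] = float(stats.lognorm.rvs(
                s=sdlog, scale=spec.base, random_state=rng))
        elif spec.distribution == "gamma":
            var = sd ** 2
            shape = spec.base ** 2 / var
            scale = var / spec.base
            draw[name] = float(stats.gamma.rvs(
                a=shape, scale=scale, random_state=rng))
        elif spec.distribution == "beta":
            m, var = spec.base, sd ** 2
            if var >= m * (1 - m):
                raise ValueError(
                    f"parameter {name!r}: bound spread too wide for a beta "
                    f"distribution with mean {m}")
            nu = m * (1 - m) / var - 1.0
            draw[name] = float(stats.beta.rvs(
                a=m * nu, b=(1 - m) * nu, random_state=rng))
        else:  # pragma: no cover - guarded by ParameterSpec validation
            raise ValueError(f"unknown distribution {spec.distribution!r}")
    return draw


@dataclass
class PSAResult:
    """Stored per-iteration draws and strategy results."""

    params: pd.DataFrame          # one row per iteration
    costs: pd.DataFrame           # iterations x strategies
    qalys: pd.DataFrame           # iterations x strategies
    seed: int
    redraws: int = 0

    @property
    def n_iterations(self) -> int:
        return len(self.costs)

    @property
    def strategies(self) -> list[str]:
        return list(self.costs.columns)


def run_psa(evaluate: Callable[[Mapping[str, float]],
                               Mapping[str, tuple[float, float]]],
            specs: Mapping[str, ParameterSpec] | None = None,
            n_iterations: int = 1000, seed: int = 0,
            max_redraws_per_iteration: int = 10) -> PSAResult:
    """Monte-Carlo re-evaluation of the strategy set.

    ``evaluate`` maps a sampled parameter dictionary to
    ``{strategy label: (cost, qalys)}``.  Each iteration uses an independent
    substream keyed by ``(seed, iteration)`` so results do not depend on
    execution order, and doubling ``n_iterations`` reproduces the first
    draws exactly.  Draws that make the model infeasible (a transition row
    exceeding probability 1) are re-drawn and counted.
    """
    if n_iterations < 1:
        raise ValueError("PSA needs at least one iteration")
    specs = dict(TABLE1) if specs is None else dict(specs)
    param_rows, cost_rows, qaly_rows = [], [], []
    redraws = 0
    for i in range(n_iterations):
        for attempt in range(max_redraws_per_iteration + 1):
            rng = np.random.default_rng([seed, i, attempt])
            draw = sample_parameters(specs, rng)
            try:
                results = evaluate(draw)
            except ValueError:
                redraws += 1
                continue
            break
        else:
            raise RuntimeError(
                f"iteration {i}: no feasible draw in "
                f"{max_redraws_per_iteration} redraws")
        param_rows.append(draw)
        cost_rows.append({k: v[0] for k, v in results.items()})
        qaly_rows.append({k: v[1] for k, v in results.items()})
    return PSAResult(params=pd.DataFrame(param_rows),
                     costs=pd.DataFrame(cost_rows),
                     qalys=pd.DataFrame(qaly_rows),
                     seed=seed, redraws=redraws)


def default_wtp_grid() -> np.ndarray:
    """WTP grid for acceptability curves: 0 to 40,000 USD/QALY by 500."""
    return np.arange(0.0, 40_000.0 + 1, 500.0)


def acceptability_curve(psa: PSAResult, wtp_grid=None) -> pd.DataFrame:
    """Probability each strategy is optimal, per willingness-to-pay.

    Optimality per iteration is the highest net monetary benefit
    ``qalys * wtp - cost``; ties split evenly.  Rows are indexed by WTP and
    sum to 1.
    """
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("WTP grid is empty")
    costs = psa.costs.to_numpy()
    qalys = psa.qalys.to_numpy()
    n_iter, n_strat = costs.shape
    probs = np.zeros((wtp_grid.size, n_strat))
    for k, wtp in enumerate(wtp_grid):
        nmb = qalys * wtp - costs
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        probs[k] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return pd.DataFrame(probs, index=pd.Index(wtp_grid, name="wtp"),
                        columns=psa.costs.columns)
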
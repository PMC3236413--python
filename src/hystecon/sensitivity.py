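"""Deterministic sensitivity analysis over operating-room time.

One-way sweeps rebuild a single method's subtree with the base OR time set
to each grid value while the other methods stay at their default expected
costs (flat reference lines).  Because billing is per 15-minute increment,
every cost curve is a nondecreasing step function with jumps only at
increment boundaries; the cost-equivalence threshold between two methods
therefore resolves to the first minute of a billing increment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParameterError
from .methods import SurgicalMethod
from .tree import ModelParameters, build_tree, expected_cost, method_expected_cost_vec

#: Default search window (minutes) for threshold solving.
DEFAULT_THRESHOLD_RANGE: tuple[float, float] = (15.0, 900.0)


@dataclass(frozen=True)
class SAResult:
    """One-way sweep of expected cost against a parameter."""

    method: SurgicalMethod
    parameter: str
    grid: tuple[tuple[float, float], ...]  # (parameter value, expected cost)
    reference_costs: dict[SurgicalMethod, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.grid, columns=["or_time_min", "expected_cost"])


@dataclass(frozen=True)
class ThresholdResult:
    """Cost-equivalence threshold between a swept and a fixed method."""

    method_a: SurgicalMethod  # swept
    method_b: SurgicalMethod  # fixed at its default expected cost
    threshold_minutes: Optional[float]  # None: no crossing in range
    increment_index: Optional[int]
    target_cost: float
    bracket: Optional[tuple[tuple[float, float], tuple[float, float]]]

    @property
    def found(self) -> bool:
        return self.threshold_minutes is not None

    def to_dict(self) -> dict:
        return {
            "method_a": self.method_a.value,
            "method_b": self.method_b.value,
            "threshold_minutes": self.threshold_minutes,
            "increment_index": self.increment_index,
            "target_cost": self.target_cost,
            "bracket": [list(b) for b in self.bracket] if self.bracket else None,
        }


def default_expected_costs(params: ModelParameters) -> dict[SurgicalMethod, float]:
    """Expected cost of every method at its default (mean) parameters."""
    tree = build_tree(params)
    return {m: expected_cost(tree, m) for m in tree.subtrees}


def one_way_or_time(
    params: ModelParameters,
    method: SurgicalMethod,
    or_range: tuple[float, float],
    step: float = 1.0,
) -> SAResult:
    """Sweep one method's base OR time over ``[lo, hi]`` in ``step``-minute
    increments, holding the other methods at their default expected costs."""
    lo, hi = or_range
    if not (0 < lo < hi):
        raise ParameterError(f"invalid OR-time range [{lo}, {hi}]")
    if step <= 0:
        raise ParameterError("step must be > 0")
    grid_t = np.arange(lo, hi + step / 2, step)
    costs = method_expected_cost_vec(params, method, grid_t)
    references = {
        m: c for m, c in default_expected_costs(params).items() if m is not method
    }
    return SAResult(
        method=method,
        parameter="base_or_time",
        grid=tuple(zip(grid_t.tolist(), np.asarray(costs).tolist())),
        reference_costs=references,
    )


def cohort_sweep_range(
    summary_stats, percentiles: tuple[float, float] = (25.0, 75.0)
) -> tuple[float, float]:
    """OR-time sweep range from cohort percentiles (default interquartile)."""
    lo, hi = percentiles
    if not hasattr(summary_stats, "p25"):
        raise ParameterError("expected ContinuousStats for OR time")
    mapping = {25.0: summary_stats.p25, 50.0: summary_stats.p50, 75.0: summary_stats.p75}
    try:
        return mapping[float(lo)], mapping[float(hi)]
    except KeyError as exc:  # pragma: no cover - config guard
        raise ParameterError("sweep percentiles must be among {25, 50, 75}") from exc


def threshold_or_time(
    params: ModelParameters,
    method_a: SurgicalMethod,
    method_b: SurgicalMethod,
    search_range: tuple[float, float] = DEFAULT_THRESHOLD_RANGE,
    step: float = 1.0,
) -> ThresholdResult:
    """Smallest OR time at which ``method_a``'s expected cost reaches
    ``method_b``'s default expected cost.

    Scans an integer-minute grid (default [15, 900]); since the cost curve is
    a step function of OR time, the reported threshold is the first minute of
    a billing increment.  Absence of a crossing is reported as a result, not
    an exception.
    """
    # Target via the same evaluation kernel as the sweep, so exact-equality
    # crossings (e.g. a method against itself) resolve consistently.
    target = float(
        method_expected_cost_vec(
            params, method_b, params.methods[method_b].base_or_time
        )
    )
    lo, hi = search_range
    if not (0 < lo < hi):
        raise ParameterError(f"invalid search range [{lo}, {hi}]")
    grid_t = np.arange(lo, hi + step / 2, step)
    costs = np.asarray(method_expected_cost_vec(params, method_a, grid_t))
    above = costs >= target
    if not above.any():
        return ThresholdResult(
            method_a=method_a,
            method_b=method_b,
            threshold_minutes=None,
            increment_index=None,
            target_cost=float(target),
            bracket=None,
        )
    idx = int(np.argmax(above))
    t_star = float(grid_t[idx])
    inc = params.fee_schedule.increments(t_star)
    bracket = None
    if idx > 0:
        bracket = (
            (float(grid_t[idx - 1]), float(costs[idx - 1])),
            (t_star, float(costs[idx])),
        )
    return ThresholdResult(
        method_a=method_a,
        method_b=method_b,
        threshold_minutes=t_star,
        increment_index=int(inc),
        target_cost=float(target),
        bracket=bracket,
    )
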
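"""Societal cost machinery.

Direct operative charges are driven by operating-room occupancy billed on a
graduated fee schedule in 15-minute increments, plus an equipment component.
The hospital's observed billing structure makes time charges ~190-fold larger
than equipment charges, so by default the equipment component is modelled as
``time_charge / 190``, with an additional flat amortization fee for every
robotic case.  Indirect societal costs are foregone wages during the
post-surgical work absence (human-capital / absenteeism approach), valued at
median weekly earnings spread over a calendar week.

The per-increment rate and the robot flat fee are not published; they are
identified by least squares from the per-method mean OR times and mean
operative charges (:func:`calibrate_fee_schedule`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import CalibrationError, ParameterError
from .methods import METHOD_ORDER, SurgicalMethod

#: Relative slack used when mapping minutes to billing increments, so that an
#: OR time landing on an increment boundary up to float rounding does not
#: spill into the next increment.
_CEIL_EPS = 1e-9

#: Days per week under each wage day-convention.
DAY_CONVENTIONS = {"calendar": 7.0, "workweek": 5.0}


class FeeSchedule(BaseModel):
    """Graduated OR-time fee schedule plus equipment policy.

    ``per_increment_charge`` lists the charge of the 1st, 2nd, ... billing
    increment; a single-element list encodes a flat rate, and the last rate
    extends to any further increments.  Equipment is charged either as a flat
    per-method fee (``equipment_mode="flat"``) or as ``time_charge / ratio``
    (``"ratio"``); in both modes every robotic case additionally pays
    ``robot_flat_fee`` (equipment amortization).
    """

    model_config = ConfigDict(frozen=True)

    increment_length: float = Field(default=15.0, gt=0)
    per_increment_charge: list[float] = Field(min_length=1)
    equipment_mode: Literal["ratio", "flat"] = "ratio"
    time_to_equipment_ratio: float = Field(default=190.0, gt=0)
    equipment_fee: dict[SurgicalMethod, float] = Field(
        default_factory=lambda: {m: 0.0 for m in METHOD_ORDER}
    )
    robot_flat_fee: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "FeeSchedule":
        if any(c < 0 for c in self.per_increment_charge):
            raise ValueError("per-increment charges must be >= 0")
        if any(f < 0 for f in self.equipment_fee.values()):
            raise ValueError("equipment fees must be >= 0")
        return self

    def increments(self, minutes) -> np.ndarray | int:
        """Number of billing increments covering ``minutes`` of OR occupancy."""
        arr = np.asarray(minutes, dtype=float)
        if np.any(arr <= 0):
            raise ParameterError("OR time must be > 0 minutes")
        k = np.ceil(arr / self.increment_length - _CEIL_EPS).astype(int)
        return int(k) if np.isscalar(minutes) else k

    def cumulative_charge(self, k) -> np.ndarray | float:
        """Total time charge of the first ``k`` increments (last rate extends)."""
        rates = np.asarray(self.per_increment_charge, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(rates)])
        karr = np.asarray(k)
        inside = np.minimum(karr, len(rates))
        extra = np.maximum(karr - len(rates), 0)
        out = cum[inside] + extra * rates[-1]
        return float(out) if np.isscalar(k) else out


class WageParameters(BaseModel):
    """Absenteeism (foregone-wage) parameters.

    ``median_weekly_earnings`` is the median weekly salary of full-time
    workers (USD); ``return_to_work_days`` gives the published per-method
    post-surgical absence interval in days; ``employment_adjustment`` scales
    for the employment rate (1.0 = everyone works).
    """

    model_config = ConfigDict(frozen=True)

    median_weekly_earnings: float = Field(default=657.0, gt=0)
    days_per_week_convention: Literal["calendar", "workweek"] = "calendar"
    employment_adjustment: float = Field(default=1.0, gt=0, le=1.0)
    return_to_work_days: dict[SurgicalMethod, tuple[float, float]] = Field(
        default_factory=lambda: {
            SurgicalMethod.TAH: (38.0, 41.0),
            SurgicalMethod.TLH: (19.0, 24.0),
            SurgicalMethod.TRH: (19.0, 24.0),
        }
    )
    point_estimate_rule: Literal["midpoint", "lower", "upper"] = "midpoint"

    @model_validator(mode="after")
    def _check(self) -> "WageParameters":
        for method, (lo, hi) in self.return_to_work_days.items():
            if not (0 <= lo <= hi):
                raise ValueError(
                    f"return-to-work interval for {method.value} out of order: [{lo}, {hi}]"
                )
        return self

    def absence_days(self, method: SurgicalMethod) -> float:
        lo, hi = self.return_to_work_days[method]
        if self.point_estimate_rule == "lower":
            return lo
        if self.point_estimate_rule == "upper":
            return hi
        return (lo + hi) / 2.0

    @property
    def daily_wage(self) -> float:
        return self.median_weekly_earnings / DAY_CONVENTIONS[self.days_per_week_convention]


@dataclass(frozen=True)
class CostComponents:
    """Decomposition of one encounter's societal cost (USD)."""

    operative_charge: float
    nonoperative_encounter_charge: float
    indirect_societal_cost: float

    @property
    def total_societal_cost(self) -> float:
        return (
            self.operative_charge
            + self.nonoperative_encounter_charge
            + self.indirect_societal_cost
        )


def or_time_charge(schedule: FeeSchedule, minutes) -> float | np.ndarray:
    """Time charge for ``minutes`` of OR occupancy (scalar or array).

    Bills ``ceil(minutes / increment_length)`` increments on the graduated
    scale; a nondecreasing step function of time, constant on each half-open
    interval ``((k-1)*L, k*L]``.
    """
    return schedule.cumulative_charge(schedule.increments(minutes))


def equipment_charge(
    schedule: FeeSchedule, method: SurgicalMethod, time_charge
) -> float | np.ndarray:
    """Equipment component under the active policy (robot fee included)."""
    if not isinstance(method, SurgicalMethod):
        raise ParameterError(f"unknown method: {method!r}")
    robot = schedule.robot_flat_fee if method is SurgicalMethod.TRH else 0.0
    if schedule.equipment_mode == "ratio":
        return time_charge / schedule.time_to_equipment_ratio + robot
    return schedule.equipment_fee.get(method, 0.0) + robot


def operative_charge(
    schedule: FeeSchedule, method: SurgicalMethod, minutes
) -> float | np.ndarray:
    """Total operative charge: time charge plus equipment charge."""
    tc = or_time_charge(schedule, minutes)
    return tc + equipment_charge(schedule, method, tc)


def indirect_cost(wages: WageParameters, method: SurgicalMethod) -> float:
    """Foregone wages during the method's post-surgical work absence."""
    if method not in wages.return_to_work_days:
        raise ParameterError(f"no return-to-work interval configured for {method}")
    return wages.absence_days(method) * wages.daily_wage * wages.employment_adjustment


def societal_cost(
    schedule: FeeSchedule,
    wages: WageParameters,
    method: SurgicalMethod,
    minutes: float,
    nonoperative_charge: float,
    cost_to_charge_ratio: Optional[float] = None,
) -> CostComponents:
    """Full societal cost of one encounter.

    ``cost_to_charge_ratio`` (0.5–0.7 when enabled) optionally converts the
    charge components to approximate costs; it never scales the indirect
    (wage) component.
    """
    if nonoperative_charge < 0:
        raise ParameterError("nonoperative charge must be >= 0")
    mult = 1.0
    if cost_to_charge_ratio is not None:
        if not 0.5 <= cost_to_charge_ratio <= 0.7:
            raise ParameterError("cost-to-charge ratio must lie in [0.5, 0.7]")
        mult = cost_to_charge_ratio
    return CostComponents(
        operative_charge=mult * operative_charge(schedule, method, minutes),
        nonoperative_encounter_charge=mult * nonoperative_charge,
        indirect_societal_cost=indirect_cost(wages, method),
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted fee schedule plus the calibration report."""

    schedule: FeeSchedule
    per_increment_rate: float
    robot_flat_fee: float
    predicted: dict[SurgicalMethod, float]
    residuals: dict[SurgicalMethod, float]
    relative_residuals: dict[SurgicalMethod, float]
    increments: dict[SurgicalMethod, int]

    def to_dict(self) -> dict:
        return {
            "per_increment_rate": self.per_increment_rate,
            "robot_flat_fee": self.robot_flat_fee,
            "increments": {m.value: k for m, k in self.increments.items()},
            "predicted": {m.value: v for m, v in self.predicted.items()},
            "residuals": {m.value: v for m, v in self.residuals.items()},
            "relative_residuals": {
                m.value: v for m, v in self.relative_residuals.items()
            },
        }


def calibrate_fee_schedule(
    or_time_means: dict[SurgicalMethod, float],
    operative_charge_means: dict[SurgicalMethod, float],
    *,
    increment_length: float = 15.0,
    time_to_equipment_ratio: float = 190.0,
    robot_method: SurgicalMethod = SurgicalMethod.TRH,
    tolerance: float | None = 0.02,
) -> CalibrationResult:
    """Identify the flat per-increment rate and the robot flat fee.

    The model for method *m*'s mean operative charge is::

        C_m = k_m * r * (1 + 1/ratio) + f * [m is robotic]

    with ``k_m = ceil(mean OR time / increment_length)``.  The two free
    parameters (rate ``r``, robot fee ``f``) are fitted by least squares.

    Raises
    ------
    CalibrationError
        If fewer than two distinct increment counts are present (the rate is
        then not identified against the fee), the fit is rank-deficient or
        yields negative parameters, or a ``tolerance`` is given and any mean
        charge is reproduced with larger relative error.
    """
    methods = [m for m in METHOD_ORDER if m in or_time_means]
    if set(methods) != set(operative_charge_means):
        raise CalibrationError("OR-time and charge means must cover the same methods")
    if len(methods) < 2:
        raise CalibrationError("need at least two methods to calibrate")
    ks = {
        m: int(math.ceil(or_time_means[m] / increment_length - _CEIL_EPS))
        for m in methods
    }
    if any(or_time_means[m] <= 0 for m in methods):
        raise CalibrationError("OR-time means must be > 0")
    if len(set(ks.values())) < 2:
        raise CalibrationError(
            "degenerate calibration inputs: all methods bill the same number "
            "of increments"
        )
    design = np.array(
        [[ks[m], 1.0 if m is robot_method else 0.0] for m in methods], dtype=float
    )
    y = np.array([operative_charge_means[m] for m in methods], dtype=float)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise CalibrationError("calibration design is rank-deficient")
    g, f = float(coef[0]), float(coef[1])
    rate = g / (1.0 + 1.0 / time_to_equipment_ratio)
    if rate < 0 or f < 0:
        raise CalibrationError(f"negative fitted parameters: rate={rate}, fee={f}")
    schedule = FeeSchedule(
        increment_length=increment_length,
        per_increment_charge=[rate],
        equipment_mode="ratio",
        time_to_equipment_ratio=time_to_equipment_ratio,
        robot_flat_fee=f,
    )
    predicted = {
        m: float(operative_charge(schedule, m, or_time_means[m])) for m in methods
    }
    residuals = {m: predicted[m] - operative_charge_means[m] for m in methods}
    rel = {m: residuals[m] / operative_charge_means[m] for m in methods}
    if tolerance is not None:
        bad = {m.value: rel[m] for m in methods if abs(rel[m]) > tolerance}
        if bad:
            raise CalibrationError(
                f"calibration misses {tolerance:.0%} tolerance: {bad}"
            )
    return CalibrationResult(
        schedule=schedule,
        per_increment_rate=rate,
        robot_flat_fee=f,
        predicted=predicted,
        residuals=residuals,
        relative_residuals=rel,
        increments=ks,
    )
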
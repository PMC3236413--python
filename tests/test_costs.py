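"""Fee schedule, absenteeism costs, societal cost assembly, calibration."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hystecon.costs import (
    CalibrationResult,
    FeeSchedule,
    WageParameters,
    calibrate_fee_schedule,
    indirect_cost,
    operative_charge,
    or_time_charge,
    societal_cost,
)
from hystecon.errors import CalibrationError, ParameterError
from hystecon.methods import SurgicalMethod

TAH, TLH, TRH = SurgicalMethod.TAH, SurgicalMethod.TLH, SurgicalMethod.TRH


def flat_schedule(rate: float = 100.0, **kw) -> FeeSchedule:
    return FeeSchedule(per_increment_charge=[rate], equipment_mode="flat", **kw)


# ---------------------------------------------------------------------------
# OR-time charge


def test_ceiling_at_increment_boundary():
    s = flat_schedule(100.0)
    assert or_time_charge(s, 15) == 100.0
    assert or_time_charge(s, 16) == 200.0
    assert or_time_charge(s, 0.1) == 100.0


def test_graduated_rates_with_last_rate_extension():
    s = FeeSchedule(per_increment_charge=[100.0, 80.0, 60.0], equipment_mode="flat")
    # 50 min -> 4 increments: 100 + 80 + 60 + 60
    assert or_time_charge(s, 50) == 300.0


@pytest.mark.parametrize("k", range(1, 41))
def test_exact_multiples_bill_exactly_k_increments(k):
    s = flat_schedule(137.0)
    assert or_time_charge(s, 15.0 * k) == pytest.approx(137.0 * k, rel=1e-12)


@given(st.floats(min_value=0.5, max_value=620.0))
def test_charge_is_a_step_function_constant_within_increments(minutes):
    s = FeeSchedule(per_increment_charge=[120.0, 90.0, 70.0], equipment_mode="flat")
    k = math.ceil(minutes / 15.0 - 1e-9)
    assert or_time_charge(s, minutes) == or_time_charge(s, 15.0 * k)


@given(
    st.floats(min_value=1.0, max_value=600.0),
    st.floats(min_value=0.0, max_value=60.0),
)
def test_charge_is_nondecreasing_in_time(minutes, extra):
    s = FeeSchedule(per_increment_charge=[120.0, 90.0, 70.0], equipment_mode="flat")
    assert or_time_charge(s, minutes + extra) >= or_time_charge(s, minutes)


def test_nonpositive_minutes_rejected():
    with pytest.raises(ParameterError):
        or_time_charge(flat_schedule(), 0)
    with pytest.raises(ParameterError):
        or_time_charge(flat_schedule(), -10)


# ---------------------------------------------------------------------------
# Operative charge and equipment policy


def test_zero_equipment_fees_reduce_to_time_charge():
    s = flat_schedule(100.0)
    for m in SurgicalMethod:
        assert operative_charge(s, m, 47) == or_time_charge(s, 47)


def test_ratio_policy_adds_1_over_190():
    s = FeeSchedule(
        per_increment_charge=[19000.0], equipment_mode="ratio", time_to_equipment_ratio=190.0
    )
    # one increment: time charge 19,000 -> equipment 100 -> 19,100 (non-robot)
    assert operative_charge(s, TAH, 10) == pytest.approx(19100.0)
    s_robot = s.model_copy(update={"robot_flat_fee": 600.0})
    assert operative_charge(s_robot, TRH, 10) == pytest.approx(19700.0)
    assert operative_charge(s_robot, TLH, 10) == pytest.approx(19100.0)


def test_unknown_method_rejected():
    with pytest.raises(ParameterError):
        operative_charge(flat_schedule(), "open", 60)


# ---------------------------------------------------------------------------
# Indirect (absenteeism) cost


def test_one_week_absence_costs_one_weekly_wage():
    wages = WageParameters(return_to_work_days={m: (7.0, 7.0) for m in SurgicalMethod})
    assert indirect_cost(wages, TAH) == pytest.approx(657.0)


def test_default_midpoint_arithmetic():
    wages = WageParameters()
    assert indirect_cost(wages, TLH) == pytest.approx(21.5 * 657.0 / 7.0)
    assert indirect_cost(wages, TLH) == pytest.approx(2017.93, abs=0.005)
    assert indirect_cost(wages, TAH) == pytest.approx(39.5 * 657.0 / 7.0)


def test_employment_adjustment_is_exactly_linear():
    full = WageParameters()
    half = WageParameters(employment_adjustment=0.5)
    for m in SurgicalMethod:
        assert indirect_cost(half, m) == pytest.approx(0.5 * indirect_cost(full, m), rel=1e-15)


@pytest.mark.parametrize(
    "rule,expected_days", [("midpoint", 21.5), ("lower", 19.0), ("upper", 24.0)]
)
def test_point_estimate_rules(rule, expected_days):
    wages = WageParameters(point_estimate_rule=rule)
    assert indirect_cost(wages, TRH) == pytest.approx(expected_days * 657.0 / 7.0)


def test_workweek_convention_divides_by_five():
    wages = WageParameters(days_per_week_convention="workweek")
    assert indirect_cost(wages, TLH) == pytest.approx(21.5 * 657.0 / 5.0)


# ---------------------------------------------------------------------------
# Societal cost assembly


def test_zero_everything_totals_zero():
    s = flat_schedule(0.0)
    wages = WageParameters(return_to_work_days={m: (0.0, 0.0) for m in SurgicalMethod})
    c = societal_cost(s, wages, TAH, 60, 0.0)
    assert c.total_societal_cost == 0.0


def test_components_add_up(params):
    c = societal_cost(params.fee_schedule, params.wages, TLH, 187.0, 5661.0)
    assert c.total_societal_cost == pytest.approx(
        c.operative_charge + c.nonoperative_encounter_charge + c.indirect_societal_cost
    )


def test_cost_to_charge_multiplier_scales_only_charges():
    s = flat_schedule(100.0)  # 10 min -> operative 100
    wages = WageParameters(
        median_weekly_earnings=70.0,
        return_to_work_days={m: (1.0, 1.0) for m in SurgicalMethod},
    )  # indirect = 10
    c = societal_cost(s, wages, TAH, 10, 40.0, cost_to_charge_ratio=0.5)
    assert c.operative_charge == pytest.approx(50.0)
    assert c.nonoperative_encounter_charge == pytest.approx(20.0)
    assert c.indirect_societal_cost == pytest.approx(10.0)
    assert c.total_societal_cost == pytest.approx(80.0)


def test_multiplier_outside_published_band_rejected():
    with pytest.raises(ParameterError):
        societal_cost(flat_schedule(), WageParameters(), TAH, 60, 0.0, cost_to_charge_ratio=0.3)


# ---------------------------------------------------------------------------
# Calibration


def _exact_inputs(rate: float, fee: float, ratio: float = 190.0):
    times = {TAH: 192.28, TLH: 186.80, TRH: 252.6}
    g = rate * (1 + 1 / ratio)
    charges = {
        m: g * math.ceil(times[m] / 15) + (fee if m is TRH else 0.0) for m in times
    }
    return times, charges


def test_calibration_recovers_exact_truth():
    times, charges = _exact_inputs(2500.0, 600.0)
    result = calibrate_fee_schedule(times, charges)
    assert result.per_increment_rate == pytest.approx(2500.0, rel=1e-12)
    assert result.robot_flat_fee == pytest.approx(600.0, rel=1e-9)
    for m, resid in result.relative_residuals.items():
        assert abs(resid) < 1e-12


def test_calibration_matches_brute_force_grid(calibration):
    """Least-squares fit must agree with an exhaustive grid search over the
    (per-increment rate, robot fee) plane on the published inputs."""
    from hystecon.defaults import MEAN_OPERATIVE_CHARGE, OR_TIME_MEAN

    ks = np.array([13, 13, 17], dtype=float)
    robot = np.array([0.0, 0.0, 1.0])
    y = np.array([MEAN_OPERATIVE_CHARGE[m] for m in (TAH, TLH, TRH)])
    rates = np.arange(2400.0, 2800.0, 0.5)
    fees = np.arange(0.0, 1200.0, 0.5)
    g = rates[:, None, None] * (1 + 1 / 190.0)
    pred = g * ks[None, None, :] + fees[None, :, None] * robot[None, None, :]
    sse = ((pred - y[None, None, :]) ** 2).sum(axis=-1)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    assert calibration.per_increment_rate == pytest.approx(rates[i], abs=0.5)
    # a 0.5 rate-grid step moves the conditionally optimal fee by ~17*0.5
    assert calibration.robot_flat_fee == pytest.approx(fees[j], abs=9.0)


def test_calibration_reproduces_published_means_within_2pc(calibration):
    assert isinstance(calibration, CalibrationResult)
    for m, resid in calibration.relative_residuals.items():
        assert abs(resid) <= 0.02, m


def test_calibration_stable_under_1pc_perturbation():
    from hystecon.defaults import MEAN_OPERATIVE_CHARGE, OR_TIME_MEAN

    base = calibrate_fee_schedule(OR_TIME_MEAN, MEAN_OPERATIVE_CHARGE)
    bumped_charges = dict(MEAN_OPERATIVE_CHARGE)
    bumped_charges[TAH] *= 1.01
    bumped = calibrate_fee_schedule(OR_TIME_MEAN, bumped_charges)
    rel_shift = abs(bumped.per_increment_rate - base.per_increment_rate) / base.per_increment_rate
    assert rel_shift <= 0.01


def test_degenerate_increments_rejected():
    times = {TAH: 100.0, TLH: 100.0, TRH: 100.0}
    charges = {TAH: 1000.0, TLH: 1000.0, TRH: 1500.0}
    with pytest.raises(CalibrationError):
        calibrate_fee_schedule(times, charges)


def test_inconsistent_charges_fail_tolerance():
    times = {TAH: 100.0, TLH: 200.0, TRH: 300.0}
    charges = {TAH: 1000.0, TLH: 5000.0, TRH: 1000.0}
    with pytest.raises(CalibrationError):
        calibrate_fee_schedule(times, charges)


def test_operative_charge_tracks_or_time_on_synthetic_cohort(
    calibration, default_cohort
):
    """Billed through the calibrated schedule, operative charge correlates
    with OR time at r > 0.96 — the structural consequence of time-driven
    billing with a 190:1 equipment share."""
    df = default_cohort
    charges = [
        float(operative_charge(calibration.schedule, SurgicalMethod(m), t))
        for m, t in zip(df["method"], df["or_time"])
    ]
    r = np.corrcoef(df["or_time"], charges)[0, 1]
    assert r > 0.96
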
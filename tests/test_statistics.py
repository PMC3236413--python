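"""Cohort summaries, exact/asymptotic group tests, parameter estimation."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hystecon.cohort import COHORT_COLUMNS
from hystecon.defaults import NONOPERATIVE_CHARGE, default_fee_schedule, default_wages
from hystecon.errors import ConfigurationError, DegenerateTestError, ParameterError
from hystecon.methods import SurgicalMethod
from hystecon.statistics import (
    compare_groups,
    estimate_model_parameters,
    fisher_exact_2xc,
    format_percent,
    summarize_cohort,
)

TAH, TLH, TRH = SurgicalMethod.TAH, SurgicalMethod.TLH, SurgicalMethod.TRH


def make_frame(rows: list[dict]) -> pd.DataFrame:
    """Cohort frame from sparse row dicts (unspecified fields get benign values)."""
    base = {
        "patient_id": "p",
        "method": "TAH",
        "age": 60.0,
        "bmi": 30.0,
        "prior_laparotomy": False,
        "prior_laparoscopy": False,
        "adhesions": False,
        "uterine_weight": 100.0,
        "lnd": False,
        "or_time": 200.0,
        "ebl": 100.0,
        "los": 2.0,
        "conversion": False,
        "organ_injury": False,
        "hemorrhage": False,
        "postop_complication": False,
    }
    return pd.DataFrame([{**base, **r} for r in rows], columns=list(COHORT_COLUMNS))


@pytest.mark.parametrize(
    "count,n,decimals,expected",
    [
        (6, 118, 1, 5.1),     # laparoscopic conversions
        (54, 73, 1, 74.0),    # abdominal lymph-node dissections
        (40, 234, 1, 17.1),   # robotic share of the full cohort
        (8, 73, 1, 11.0),     # abdominal postoperative complications
        (1, 118, 2, 0.85),    # laparoscopic organ injury
    ],
)
def test_printed_count_percentages(count, n, decimals, expected):
    assert format_percent(count, n, decimals) == expected


def test_summary_statistics_match_hand_computation():
    values = [150.0, 180.0, 200.0, 240.0]
    rows = [{"method": "TLH", "or_time": v, "conversion": i == 0} for i, v in enumerate(values)]
    summary = summarize_cohort(make_frame(rows))
    s = summary.methods[TLH].continuous["or_time"]
    assert s.n == 4
    assert s.mean == pytest.approx(192.5)
    assert s.sd == pytest.approx(np.std(values, ddof=1))
    assert s.minimum == 150.0 and s.maximum == 240.0
    half = 1.96 * s.sd / math.sqrt(4)
    assert s.ci95 == pytest.approx((s.mean - half, s.mean + half))
    assert (s.p25, s.p50, s.p75) == pytest.approx(
        tuple(np.percentile(values, [25, 50, 75]))
    )
    conv = summary.methods[TLH].binary["conversion"]
    assert conv.count == 1 and conv.proportion == pytest.approx(0.25)


def test_conversion_proportion_from_118_records():
    rows = [{"method": "TLH", "conversion": i < 6} for i in range(118)]
    summary = summarize_cohort(make_frame(rows))
    prop = summary.methods[TLH].binary["conversion"].proportion
    assert prop == pytest.approx(6 / 118)
    assert format_percent(6, 118) == 5.1


def test_single_record_degenerate_summary():
    summary = summarize_cohort(make_frame([{"method": "TRH", "or_time": 250.0}]))
    s = summary.methods[TRH].continuous["or_time"]
    assert s.sd is None and s.ci95 is None
    assert s.mean == s.minimum == s.maximum == 250.0


def test_missing_field_absent_not_zero():
    df = make_frame([{"method": "TAH"}] * 3)
    df["ebl"] = np.nan
    summary = summarize_cohort(df)
    assert "ebl" not in summary.methods[TAH].continuous


def test_empty_cohort_rejected():
    with pytest.raises(ParameterError):
        summarize_cohort(make_frame([]).iloc[0:0])


# ---------------------------------------------------------------------------
# Exact and asymptotic tests


def test_fisher_exact_matches_closed_form_and_scipy():
    table = np.array([[10, 0], [0, 10]])
    p = fisher_exact_2xc(table)
    assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)
    _, p_scipy = stats.fisher_exact(table)
    assert p == pytest.approx(p_scipy, rel=1e-9)


@pytest.mark.parametrize("seed", range(6))
def test_fisher_2x2_agrees_with_scipy_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    table = rng.integers(0, 12, size=(2, 2))
    table[0, 0] += 1  # avoid fully degenerate margins
    _, p_scipy = stats.fisher_exact(table)
    assert fisher_exact_2xc(table) == pytest.approx(p_scipy, rel=1e-9)


def test_identical_boolean_distributions_not_significant():
    rows = (
        [{"method": "TAH", "lnd": i < 100} for i in range(200)]
        + [{"method": "TLH", "lnd": i < 100} for i in range(200)]
        + [{"method": "TRH", "lnd": i < 100} for i in range(200)]
    )
    cmp = compare_groups(make_frame(rows), "lnd")
    assert cmp.test == "chi-square"
    assert cmp.p_value > 0.99 and not cmp.significant


def test_sparse_table_switches_to_exact_test():
    rows = (
        [{"method": "TAH", "organ_injury": i == 0} for i in range(73)]
        + [{"method": "TLH", "organ_injury": i == 0} for i in range(118)]
        + [{"method": "TRH"} for _ in range(43)]
    )
    cmp = compare_groups(make_frame(rows), "organ_injury")
    assert cmp.test == "fisher-exact"
    assert 0 <= cmp.p_value <= 1 and not cmp.significant


def test_or_time_anova_significant_across_seeds():
    """Cohort-sized OR-time samples (robotic mean ~60 min above the others)
    must yield a significant ANOVA in essentially every replicate."""
    n_sig = 0
    seeds = range(50)
    for seed in seeds:
        rng = np.random.default_rng(seed)
        rows = (
            [{"method": "TAH", "or_time": v} for v in rng.normal(192.28, 48.8, 73)]
            + [{"method": "TLH", "or_time": v} for v in rng.normal(186.80, 48.8, 118)]
            + [{"method": "TRH", "or_time": v} for v in rng.normal(252.6, 48.8, 43)]
        )
        cmp = compare_groups(make_frame(rows), "or_time")
        assert cmp.test == "anova"
        n_sig += cmp.significant
        if cmp.significant:
            assert cmp.pairwise is not None
            for (a, b), (t, p_adj) in cmp.pairwise.items():
                assert 0 <= p_adj <= 1
    assert n_sig >= 0.99 * len(seeds)


def test_bonferroni_is_three_times_raw_p_capped():
    rng = np.random.default_rng(0)
    groups = {
        "TAH": rng.normal(0, 1, 60),
        "TLH": rng.normal(0.1, 1, 60),
        "TRH": rng.normal(3, 1, 60),
    }
    rows = [
        {"method": m, "or_time": 200 + v} for m, vs in groups.items() for v in vs
    ]
    cmp = compare_groups(make_frame(rows), "or_time")
    assert cmp.significant and cmp.pairwise
    for (a, b), (t, p_adj) in cmp.pairwise.items():
        _, raw = stats.ttest_ind(
            np.array([200 + v for v in groups[a.value]]),
            np.array([200 + v for v in groups[b.value]]),
        )
        assert p_adj == pytest.approx(min(1.0, 3.0 * raw), rel=1e-12)


def test_constant_variable_raises_degenerate_error():
    rows = [{"method": m} for m in ("TAH", "TLH", "TRH") for _ in range(5)]
    with pytest.raises(DegenerateTestError):
        compare_groups(make_frame(rows), "lnd")  # all False
    with pytest.raises(DegenerateTestError):
        compare_groups(make_frame(rows), "or_time")  # all equal


# ---------------------------------------------------------------------------
# Parameter estimation


def _summary_with_conversions():
    rows = (
        [{"method": "TAH", "lnd": i < 54, "hemorrhage": i == 0} for i in range(73)]
        + [{"method": "TLH", "conversion": i < 6} for i in range(118)]
        + [{"method": "TRH"} for _ in range(43)]
    )
    return summarize_cohort(make_frame(rows))


def _estimate(summary, overrides):
    return estimate_model_parameters(
        summary,
        overrides,
        fee_schedule=default_fee_schedule(),
        wages=default_wages(),
        nonoperative_charges=NONOPERATIVE_CHARGE,
    )


def test_estimated_probabilities_come_from_counts():
    params = _estimate(_summary_with_conversions(), {TRH: {"p_conversion": 0.03}})
    assert params.methods[TLH].p_conversion == pytest.approx(6 / 118)
    assert params.methods[TAH].p_lnd == pytest.approx(54 / 73)
    assert params.methods[TAH].p_hemorrhage == pytest.approx(1 / 73)
    assert params.methods[TAH].p_conversion == 0.0
    assert params.methods[TRH].p_conversion == 0.03
    assert params.methods[TRH].provenance["p_conversion"] == "override"
    assert params.methods[TLH].provenance["p_conversion"] == "cohort"


def test_missing_literature_override_is_a_configuration_error():
    with pytest.raises(ConfigurationError, match="TRH.p_conversion"):
        _estimate(_summary_with_conversions(), None)


def test_all_zero_counts_with_zero_overrides_give_zero_probabilities():
    rows = [{"method": m} for m in ("TAH", "TLH", "TRH") for _ in range(10)]
    params = _estimate(summarize_cohort(make_frame(rows)), {TRH: {"p_conversion": 0.0}})
    for m in SurgicalMethod:
        mp = params.methods[m]
        assert mp.p_lnd == 0.0 and mp.p_conversion == 0.0 and mp.p_hemorrhage == 0.0
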
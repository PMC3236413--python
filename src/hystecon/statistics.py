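"""Cohort summarization, group-comparison tests and model-parameter estimation.

Summaries report, per method: n; mean, sample (n-1) sd, range, normal 95% CI
of the mean and quartiles (linear-interpolation percentiles) for continuous
fields; count and proportion (non-missing denominator) for binary fields.

Group comparisons follow the conventional rules for three-arm cohorts:
chi-square for categorical variables, switching to the exact conditional
(Fisher / Freeman–Halton) test when any expected cell count falls below 5;
one-way ANOVA for continuous variables with Bonferroni-corrected pairwise
two-sided t-tests when the omnibus test is significant at alpha = 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BOOLEAN_FIELDS, CONTINUOUS_FIELDS, records_to_frame
from .costs import FeeSchedule, WageParameters
from .errors import ConfigurationError, DegenerateTestError, ParameterError
from .methods import METHOD_ORDER, SurgicalMethod
from .tree import MethodParameters, ModelParameters

ALPHA = 0.01  # significance level used throughout the analysis
Z_95 = 1.96  # normal quantile for the 95% CI of the mean

#: (method, parameter) pairs whose cohort-zero estimates must come from the
#: published literature instead (no robotic conversions were observed).
DEFAULT_LITERATURE_REQUIRED: frozenset[tuple[SurgicalMethod, str]] = frozenset(
    {(SurgicalMethod.TRH, "p_conversion")}
)


# ---------------------------------------------------------------------------
# Summary containers


@dataclass(frozen=True)
class ContinuousStats:
    n: int
    mean: float
    sd: Optional[float]  # None when n < 2
    minimum: float
    maximum: float
    ci95: Optional[tuple[float, float]]
    p25: float
    p50: float
    p75: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "min": self.minimum,
            "max": self.maximum,
            "ci95": list(self.ci95) if self.ci95 is not None else None,
            "p25": self.p25,
            "p50": self.p50,
            "p75": self.p75,
        }


@dataclass(frozen=True)
class BinaryStats:
    n: int
    count: int
    proportion: float

    def to_dict(self) -> dict:
        return {"n": self.n, "count": self.count, "proportion": self.proportion}


@dataclass(frozen=True)
class MethodSummary:
    n: int
    continuous: dict[str, ContinuousStats]
    binary: dict[str, BinaryStats]


@dataclass(frozen=True)
class CohortSummary:
    methods: dict[SurgicalMethod, MethodSummary]

    def to_dict(self) -> dict:
        return {
            m.value: {
                "n": s.n,
                "continuous": {k: v.to_dict() for k, v in s.continuous.items()},
                "binary": {k: v.to_dict() for k, v in s.binary.items()},
            }
            for m, s in self.methods.items()
        }


def format_percent(count: int, n: int, decimals: int = 1) -> float:
    """Proportion as a percentage rounded to ``decimals`` (5.1 for 6/118)."""
    if n <= 0:
        raise ParameterError("denominator must be positive")
    return round(100.0 * count / n, decimals)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        if len(records) == 0:
            raise ParameterError("empty cohort")
        return records
    df = records_to_frame(records)
    return df


def summarize_cohort(records) -> CohortSummary:
    """Per-method descriptive statistics of a patient-level cohort.

    Accepts the canonical cohort DataFrame or an iterable of PatientRecord.
    Fields that are missing for every patient of a method are omitted from
    that method's summary rather than reported as zero.
    """
    df = _as_frame(records)
    out: dict[SurgicalMethod, MethodSummary] = {}
    for value, group in df.groupby("method", sort=True):
        method = SurgicalMethod(value)
        cont: dict[str, ContinuousStats] = {}
        for fname in CONTINUOUS_FIELDS:
            x = pd.to_numeric(group[fname], errors="coerce").dropna().to_numpy(float)
            if x.size == 0:
                continue
            n = int(x.size)
            mean = float(np.mean(x))
            if n >= 2:
                sd = float(np.std(x, ddof=1))
                half = Z_95 * sd / math.sqrt(n)
                ci = (mean - half, mean + half)
            else:
                sd, ci = None, None
            q25, q50, q75 = np.percentile(x, [25, 50, 75])  # linear interpolation
            cont[fname] = ContinuousStats(
                n=n,
                mean=mean,
                sd=sd,
                minimum=float(np.min(x)),
                maximum=float(np.max(x)),
                ci95=ci,
                p25=float(q25),
                p50=float(q50),
                p75=float(q75),
            )
        binary: dict[str, BinaryStats] = {}
        for fname in BOOLEAN_FIELDS:
            col = group[fname].dropna()
            if col.size == 0:
                continue
            count = int(col.astype(bool).sum())
            binary[fname] = BinaryStats(
                n=int(col.size), count=count, proportion=count / col.size
            )
        out[method] = MethodSummary(n=int(len(group)), continuous=cont, binary=binary)
    return CohortSummary(methods=out)


# ---------------------------------------------------------------------------
# Group comparisons


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test: str  # chi-square | fisher-exact | anova
    statistic: Optional[float]
    p_value: float
    significant: bool
    #: Bonferroni-adjusted pairwise t-test p-values, only when the omnibus
    #: ANOVA is significant: {(method_a, method_b): (t, adjusted p)}.
    pairwise: Optional[dict[tuple[SurgicalMethod, SurgicalMethod], tuple[float, float]]] = None

    def to_row(self) -> dict:
        return {
            "variable": self.variable,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def fisher_exact_2xc(table: np.ndarray) -> float:
    """Exact conditional p-value for a 2 x c contingency table.

    Freeman–Halton generalization of Fisher's exact test: enumerate every
    table with the observed margins, accumulate the point probabilities no
    larger than the observed one.  Integer arithmetic throughout, so the
    comparison of point probabilities is exact.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ParameterError("fisher_exact_2xc expects a 2 x c table")
    col_sums = table.sum(axis=0)
    r1 = int(table[0].sum())
    total = int(table.sum())
    denom = math.comb(total, r1)
    obs_weight = math.prod(
        math.comb(int(c), int(a)) for c, a in zip(col_sums, table[0])
    )
    cols = [int(c) for c in col_sums]
    num = 0

    def recurse(j: int, remaining: int, weight: int) -> None:
        nonlocal num
        if j == len(cols) - 1:
            if 0 <= remaining <= cols[j]:
                w = weight * math.comb(cols[j], remaining)
                if w <= obs_weight:
                    num += w
            return
        tail_capacity = sum(cols[j + 1 :])
        lo = max(0, remaining - tail_capacity)
        hi = min(cols[j], remaining)
        for a in range(lo, hi + 1):
            recurse(j + 1, remaining - a, weight * math.comb(cols[j], a))

    recurse(0, r1, 1)
    return num / denom


def _categorical_comparison(variable: str, groups: dict[SurgicalMethod, pd.Series]) -> GroupComparison:
    methods = [m for m in METHOD_ORDER if m in groups]
    table = np.array(
        [
            [int(groups[m].astype(bool).sum()) for m in methods],
            [int((~groups[m].astype(bool)).sum()) for m in methods],
        ]
    )
    if table.sum(axis=1).min() == 0:
        raise DegenerateTestError(f"variable '{variable}' is constant")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        p = fisher_exact_2xc(table)
        return GroupComparison(
            variable=variable,
            test="fisher-exact",
            statistic=None,
            p_value=float(p),
            significant=bool(p < ALPHA),
        )
    return GroupComparison(
        variable=variable,
        test="chi-square",
        statistic=float(chi2),
        p_value=float(p),
        significant=bool(p < ALPHA),
    )


def _continuous_comparison(variable: str, groups: dict[SurgicalMethod, np.ndarray]) -> GroupComparison:
    methods = [m for m in METHOD_ORDER if m in groups]
    arrays = [groups[m] for m in methods]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise DegenerateTestError(f"variable '{variable}' is constant")
    f_stat, p = stats.f_oneway(*arrays)
    pairwise = None
    if p < ALPHA:
        pairwise = {}
        pairs = [(a, b) for i, a in enumerate(methods) for b in methods[i + 1 :]]
        for a, b in pairs:
            t, raw = stats.ttest_ind(groups[a], groups[b])
            pairwise[(a, b)] = (float(t), min(1.0, 3.0 * float(raw)))
    return GroupComparison(
        variable=variable,
        test="anova",
        statistic=float(f_stat),
        p_value=float(p),
        significant=bool(p < ALPHA),
        pairwise=pairwise,
    )


def compare_groups(records, variable: str) -> GroupComparison:
    """Test whether ``variable`` differs across the surgical methods.

    Booleans: chi-square on the 2 x k table, or the exact conditional test
    when any expected count < 5.  Continuous: one-way ANOVA, plus pairwise
    Bonferroni-corrected (x3) t-tests when the ANOVA is significant.
    """
    df = _as_frame(records)
    if variable not in df.columns:
        raise ParameterError(f"unknown variable '{variable}'")
    present = [SurgicalMethod(v) for v in sorted(df["method"].unique())]
    if len(present) < 2:
        raise ParameterError("need at least two groups to compare")
    if variable in BOOLEAN_FIELDS:
        groups = {
            m: df.loc[df["method"] == m.value, variable].dropna() for m in present
        }
        return _categorical_comparison(variable, groups)
    groups_num = {
        m: pd.to_numeric(df.loc[df["method"] == m.value, variable], errors="coerce")
        .dropna()
        .to_numpy(float)
        for m in present
    }
    return _continuous_comparison(variable, groups_num)


def comparisons_table(records, variables: Iterable[str]) -> pd.DataFrame:
    """Run :func:`compare_groups` over several variables; skip degenerate ones."""
    rows = []
    for v in variables:
        try:
            rows.append(compare_groups(records, v).to_row())
        except DegenerateTestError:
            rows.append(
                {
                    "variable": v,
                    "test": "degenerate",
                    "statistic": None,
                    "p_value": None,
                    "significant": None,
                }
            )
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p_value", "significant"])


# ---------------------------------------------------------------------------
# Model-parameter estimation


def estimate_model_parameters(
    summary: CohortSummary,
    overrides: Optional[dict[SurgicalMethod, dict[str, float]]] = None,
    *,
    fee_schedule: FeeSchedule,
    wages: WageParameters,
    nonoperative_charges: dict[SurgicalMethod, float],
    added_times: Optional[dict[str, float]] = None,
    literature_required: Iterable[tuple[SurgicalMethod, str]] = DEFAULT_LITERATURE_REQUIRED,
    cost_to_charge_ratio: Optional[float] = None,
) -> ModelParameters:
    """Turn a cohort summary into decision-model parameters.

    Branch probabilities (LND, conversion, hemorrhage) and the OR-time
    mean/sd are taken from the summary.  A probability that the cohort
    estimates as zero and that is flagged in ``literature_required`` must be
    supplied in ``overrides`` (its provenance is tagged "override"); omitting
    it raises :class:`ConfigurationError`.  Any other override also replaces
    the cohort value.
    """
    overrides = overrides or {}
    required = set(literature_required)
    added = {"lnd": 30.0, "conversion": 60.0, "hemorrhage": 30.0}
    if added_times:
        added.update(added_times)
    methods: dict[SurgicalMethod, MethodParameters] = {}
    for method in METHOD_ORDER:
        if method not in summary.methods:
            raise ParameterError(f"summary lacks method {method.value}")
        ms = summary.methods[method]
        if "or_time" not in ms.continuous:
            raise ParameterError(f"summary lacks OR time for {method.value}")
        ov = {str(k): float(v) for k, v in (overrides.get(method) or {}).items()}
        values: dict[str, float] = {}
        provenance: dict[str, str] = {}
        for pname, fname in (
            ("p_lnd", "lnd"),
            ("p_conversion", "conversion"),
            ("p_hemorrhage", "hemorrhage"),
        ):
            cohort_value = ms.binary[fname].proportion if fname in ms.binary else 0.0
            if method is SurgicalMethod.TAH and pname == "p_conversion":
                values[pname], provenance[pname] = 0.0, "structural"
                continue
            if pname in ov:
                values[pname], provenance[pname] = ov[pname], "override"
            elif cohort_value == 0.0 and (method, pname) in required:
                raise ConfigurationError(
                    f"{method.value}.{pname} is zero in the cohort and flagged as "
                    "literature-sourced: an explicit override is required"
                )
            else:
                values[pname], provenance[pname] = cohort_value, "cohort"
        orstats = ms.continuous["or_time"]
        methods[method] = MethodParameters(
            **values,
            base_or_time=ov.get("base_or_time", orstats.mean),
            or_time_sd=ov.get("or_time_sd", orstats.sd or 0.0),
            added_time_lnd=added["lnd"],
            added_time_conversion=added["conversion"],
            added_time_hemorrhage=added["hemorrhage"],
            nonoperative_encounter_charge=nonoperative_charges[method],
            n=ms.n,
            provenance=provenance,
        )
    return ModelParameters(
        methods=methods,
        fee_schedule=fee_schedule,
        wages=wages,
        cost_to_charge_ratio=cost_to_charge_ratio,
    )
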
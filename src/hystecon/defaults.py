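"""Default study parameters.

These constants parameterize the shipped configuration: the 2009 single-
institution endometrial-cancer hysterectomy cohort (73 abdominal, 118
laparoscopic, 43 robotic cases) with its published per-method means,
dispersions and event rates, the per-method mean operative and encounter
charges used to calibrate the fee schedule, and the wage parameters of the
absenteeism model.

Dispersion notes: the published OR-time/EBL/LOS intervals are 95% CIs of the
mean, so the cohort SDs used here are recovered as half-width * sqrt(n) /
1.96 (see docs/methods.md).  The robotic conversion probability was never
observed in the cohort; its default (mean 0.03, sd 0.015) is a clearly
labelled literature-style placeholder, not an observed value.
"""

from __future__ import annotations

from .cohort import CohortGeneratorConfig, ContinuousSpec, MethodCohortSpec
from .costs import (
    CalibrationResult,
    FeeSchedule,
    WageParameters,
    calibrate_fee_schedule,
)
from .methods import METHOD_ORDER, SurgicalMethod
from .psa import DistributionSpec, PSAConfig
from .tree import MethodParameters, ModelParameters

TAH, TLH, TRH = SurgicalMethod.TAH, SurgicalMethod.TLH, SurgicalMethod.TRH

#: Cohort sizes per method (the full cohort totalled 234 hysterectomies).
COHORT_N = {TAH: 73, TLH: 118, TRH: 43}
TOTAL_N = 234
ROBOTIC_COUNT = 40  # robotic share of the full 234-case cohort

#: Mean OR time (in-room to out-of-room, minutes).
OR_TIME_MEAN = {TAH: 192.28, TLH: 186.80, TRH: 252.6}
#: Cohort SD of OR time, recovered from the published 95% CIs.
OR_TIME_SD = {TAH: 48.824, TLH: 48.809, TRH: 48.814}

#: Mean operative charge (USD-2009) — fee-schedule calibration targets.
MEAN_OPERATIVE_CHARGE = {TAH: 33756.0, TLH: 33706.0, TRH: 44698.0}
#: Mean total encounter charge (USD-2009).
MEAN_ENCOUNTER_CHARGE = {TAH: 54110.0, TLH: 39367.0, TRH: 51552.0}
#: Nonoperative encounter charge = encounter charge - operative charge.
NONOPERATIVE_CHARGE = {
    m: MEAN_ENCOUNTER_CHARGE[m] - MEAN_OPERATIVE_CHARGE[m] for m in METHOD_ORDER
}

#: Observed time-to-equipment charge ratio.
TIME_TO_EQUIPMENT_RATIO = 190.0

#: Branch probabilities (published percentages).
P_LND = {TAH: 0.740, TLH: 0.385, TRH: 0.379}
P_CONVERSION = {TAH: 0.0, TLH: 0.051, TRH: 0.0}
P_HEMORRHAGE = {TAH: 0.0145, TLH: 0.0091, TRH: 0.0}

#: Literature placeholder for the unobserved robotic conversion probability.
TRH_CONVERSION_PLACEHOLDER = DistributionSpec(
    mean=0.03, sd=0.015, lower=0.0, upper=1.0, source="literature-placeholder"
)

#: Added OR time (minutes) per event; whole billing increments by design.
ADDED_TIMES = {"lnd": 30.0, "conversion": 60.0, "hemorrhage": 30.0}

#: Continuous cohort specs: mean, cohort sd, truncation bounds.
_CONTINUOUS = {
    TAH: {
        "age": ContinuousSpec(mean=61.9, sd=9.2, lower=43, upper=87),
        "bmi": ContinuousSpec(mean=35.7, sd=10.1, lower=16.7, upper=69.4),
        "uterine_weight": ContinuousSpec(mean=243.5, sd=330.12, lower=25, upper=2170),
        "or_time": ContinuousSpec(mean=192.28, sd=48.824, lower=30, upper=600),
        "ebl": ContinuousSpec(mean=255.94, sd=175.242, lower=0),
        "los": ContinuousSpec(mean=3.84, sd=1.635, lower=0),
    },
    TLH: {
        "age": ContinuousSpec(mean=59.9, sd=10.4, lower=34, upper=91),
        "bmi": ContinuousSpec(mean=29.8, sd=7.5, lower=19.7, upper=59.2),
        "uterine_weight": ContinuousSpec(mean=134.4, sd=101.4, lower=34, upper=704),
        "or_time": ContinuousSpec(mean=186.80, sd=48.809, lower=30, upper=600),
        "ebl": ContinuousSpec(mean=105.23, sd=176.717, lower=0),
        "los": ContinuousSpec(mean=1.44, sd=1.552, lower=0),
    },
    TRH: {
        "age": ContinuousSpec(mean=58.2, sd=7.57, lower=43, upper=74),
        "bmi": ContinuousSpec(mean=40.5, sd=11.0, lower=18.6, upper=61.4),
        "uterine_weight": ContinuousSpec(mean=176.3, sd=153.34, lower=45.5, upper=905),
        "or_time": ContinuousSpec(mean=252.6, sd=48.814, lower=30, upper=600),
        "ebl": ContinuousSpec(mean=41.22, sd=183.679, lower=0),
        "los": ContinuousSpec(mean=1.30, sd=1.572, lower=0),
    },
}

#: Bernoulli rates per method (published percentages).
_RATES = {
    TAH: {
        "prior_laparotomy": 0.464,
        "prior_laparoscopy": 0.197,
        "adhesions": 0.329,
        "lnd": 0.740,
        "conversion": 0.0,
        "organ_injury": 0.0137,
        "postop_complication": 0.110,
        "hemorrhage": 0.0145,
    },
    TLH: {
        "prior_laparotomy": 0.315,
        "prior_laparoscopy": 0.105,
        "adhesions": 0.144,
        "lnd": 0.385,
        "conversion": 0.051,
        "organ_injury": 0.0085,
        "postop_complication": 0.068,
        "hemorrhage": 0.0091,
    },
    TRH: {
        "prior_laparotomy": 0.463,
        "prior_laparoscopy": 0.238,
        "adhesions": 0.395,
        "lnd": 0.379,
        "conversion": 0.0,
        "organ_injury": 0.0,
        "postop_complication": 0.070,
        "hemorrhage": 0.0,
    },
}


def default_cohort_config(
    seed: int = 0, n: dict[SurgicalMethod, int] | None = None
) -> CohortGeneratorConfig:
    """Generator configuration reproducing the study cohort's structure."""
    sizes = dict(COHORT_N)
    if n:
        sizes.update(n)
    return CohortGeneratorConfig(
        methods={
            m: MethodCohortSpec(n=sizes[m], continuous=_CONTINUOUS[m], rates=_RATES[m])
            for m in METHOD_ORDER
        },
        hemorrhage_mode="rate",
        seed=seed,
    )


def default_calibration() -> CalibrationResult:
    """Fee schedule calibrated to the published mean OR times and charges."""
    return calibrate_fee_schedule(
        OR_TIME_MEAN,
        MEAN_OPERATIVE_CHARGE,
        time_to_equipment_ratio=TIME_TO_EQUIPMENT_RATIO,
    )


def default_fee_schedule() -> FeeSchedule:
    return default_calibration().schedule


def default_wages() -> WageParameters:
    return WageParameters()


def default_model_parameters(
    fee_schedule: FeeSchedule | None = None,
    wages: WageParameters | None = None,
    trh_conversion: float | None = None,
) -> ModelParameters:
    """Decision-model parameters from the published point estimates.

    ``trh_conversion`` defaults to the literature placeholder mean (0.03);
    its provenance is tagged accordingly.
    """
    fee_schedule = fee_schedule or default_fee_schedule()
    wages = wages or default_wages()
    p_conv_trh = (
        TRH_CONVERSION_PLACEHOLDER.mean if trh_conversion is None else trh_conversion
    )
    methods = {}
    for m in METHOD_ORDER:
        p_conv = p_conv_trh if m is TRH else P_CONVERSION[m]
        prov = {
            "p_lnd": "cohort",
            "p_conversion": (
                "structural" if m is TAH else ("override" if m is TRH else "cohort")
            ),
            "p_hemorrhage": "cohort",
            "base_or_time": "cohort",
        }
        methods[m] = MethodParameters(
            p_lnd=P_LND[m],
            p_conversion=p_conv,
            p_hemorrhage=P_HEMORRHAGE[m],
            base_or_time=OR_TIME_MEAN[m],
            or_time_sd=OR_TIME_SD[m],
            added_time_lnd=ADDED_TIMES["lnd"],
            added_time_conversion=ADDED_TIMES["conversion"],
            added_time_hemorrhage=ADDED_TIMES["hemorrhage"],
            nonoperative_encounter_charge=NONOPERATIVE_CHARGE[m],
            n=COHORT_N[m],
            provenance=prov,
        )
    return ModelParameters(methods=methods, fee_schedule=fee_schedule, wages=wages)


def default_psa_overrides() -> dict[SurgicalMethod, dict[str, DistributionSpec]]:
    """PSA distributions for parameters the cohort cannot inform."""
    return {
        TRH: {
            "p_conversion": TRH_CONVERSION_PLACEHOLDER,
            "p_hemorrhage": DistributionSpec(
                mean=0.0, sd=0.0, lower=0.0, upper=1.0, source="cohort-degenerate"
            ),
        }
    }


def default_psa_config(n_iterations: int = 10_000, seed: int = 0) -> PSAConfig:
    return PSAConfig(
        n_iterations=n_iterations,
        seed=seed,
        use_common_random_numbers=True,
        overrides=default_psa_overrides(),
    )
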
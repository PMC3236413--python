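"""Synthetic surgical-cohort generator.

Produces patient-level tables whose per-method distributions mirror the
statistical structure assumed by the downstream cost model: continuous
covariates (age, BMI, uterine weight, OR time, EBL, length of stay) drawn
from truncated normal distributions, and binary covariates/outcomes (prior
surgery, adhesions, lymph-node dissection, conversion, organ injury,
postoperative complication) drawn as independent Bernoulli variables.

Hemorrhage (EBL >= 1000 mL) can either be derived from the sampled EBL
("ebl" mode) or forced to a configured Bernoulli rate ("rate" mode, the
default — see docs/methods.md for why the normal EBL assumption makes the
derived rate vanish).

Sampling uses one master seed with per-(method, field) substreams derived
from a stable hash, so adding or reconfiguring one field never perturbs the
draws of any other field.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .errors import ParameterError
from .methods import METHOD_ORDER, SurgicalMethod

#: Threshold (mL) above which estimated blood loss counts as hemorrhage.
HEMORRHAGE_EBL_THRESHOLD = 1000.0

#: Continuous patient-level fields, in canonical column order.
CONTINUOUS_FIELDS: tuple[str, ...] = (
    "age",
    "bmi",
    "uterine_weight",
    "or_time",
    "ebl",
    "los",
)

#: Bernoulli patient-level fields (hemorrhage handled separately).
RATE_FIELDS: tuple[str, ...] = (
    "prior_laparotomy",
    "prior_laparoscopy",
    "adhesions",
    "lnd",
    "conversion",
    "organ_injury",
    "postop_complication",
)

BOOLEAN_FIELDS: tuple[str, ...] = RATE_FIELDS + ("hemorrhage",)

#: Exact cohort CSV header, one row per patient.
COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "method",
    "age",
    "bmi",
    "prior_laparotomy",
    "prior_laparoscopy",
    "adhesions",
    "uterine_weight",
    "lnd",
    "or_time",
    "ebl",
    "los",
    "conversion",
    "organ_injury",
    "hemorrhage",
    "postop_complication",
)


@dataclass(frozen=True)
class PatientRecord:
    """One simulated (or observed) surgical encounter."""

    patient_id: str
    method: SurgicalMethod
    age: float
    bmi: float
    prior_laparotomy: bool
    prior_laparoscopy: bool
    adhesions: bool
    uterine_weight: float
    lnd: bool
    or_time: float
    ebl: float
    los: float
    conversion: bool
    organ_injury: bool
    hemorrhage: bool
    postop_complication: bool

    def __post_init__(self) -> None:
        if self.method is SurgicalMethod.TAH and self.conversion:
            raise ParameterError("conversion must be False for TAH records")
        for name in ("age", "bmi", "or_time"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be finite and > 0")
        for name in ("uterine_weight", "ebl", "los"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ParameterError(f"{name} must be finite and >= 0")


class ContinuousSpec(BaseModel):
    """Truncated-normal specification: parent mean/sd plus truncation bounds."""

    model_config = ConfigDict(frozen=True)

    mean: float
    sd: float = Field(ge=0)
    lower: Optional[float] = None
    upper: Optional[float] = None

    @model_validator(mode="after")
    def _check_bounds(self) -> "ContinuousSpec":
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError(f"truncation bounds out of order: [{self.lower}, {self.upper}]")
        return self

    def standardized_bounds(self) -> tuple[float, float]:
        if self.sd == 0:
            return -np.inf, np.inf
        a = -np.inf if self.lower is None else (self.lower - self.mean) / self.sd
        b = np.inf if self.upper is None else (self.upper - self.mean) / self.sd
        return a, b

    def truncated_moments(self) -> tuple[float, float]:
        """Analytic (mean, sd) of the truncated distribution actually sampled."""
        if self.sd == 0:
            return self.mean, 0.0
        a, b = self.standardized_bounds()
        m, v = stats.truncnorm.stats(a, b, loc=self.mean, scale=self.sd, moments="mv")
        return float(m), float(np.sqrt(v))

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Inverse CDF of the truncated normal — exact truncated sampling."""
        if self.sd == 0:
            return np.full_like(np.asarray(u, dtype=float), self.mean)
        a, b = self.standardized_bounds()
        return stats.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)


class MethodCohortSpec(BaseModel):
    """Per-method sample size, continuous specs and Bernoulli rates."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(ge=1)
    continuous: dict[str, ContinuousSpec]
    rates: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "MethodCohortSpec":
        missing = set(CONTINUOUS_FIELDS) - set(self.continuous)
        if missing:
            raise ValueError(f"missing continuous specs: {sorted(missing)}")
        for name, rate in self.rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {name}={rate} outside [0, 1]")
        missing_rates = set(RATE_FIELDS) - set(self.rates)
        if missing_rates:
            raise ValueError(f"missing rates: {sorted(missing_rates)}")
        return self


class CohortGeneratorConfig(BaseModel):
    """Full generator configuration: one spec per method plus global options."""

    model_config = ConfigDict(frozen=True)

    methods: dict[SurgicalMethod, MethodCohortSpec]
    hemorrhage_mode: Literal["rate", "ebl"] = "rate"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortGeneratorConfig":
        for method in METHOD_ORDER:
            if method not in self.methods:
                raise ValueError(f"missing cohort spec for {method.value}")
        tah = self.methods[SurgicalMethod.TAH]
        if tah.rates.get("conversion", 0.0) != 0.0:
            raise ValueError("TAH conversion rate must be 0 (laparotomy cannot convert)")
        if self.hemorrhage_mode == "rate":
            for method, spec in self.methods.items():
                if "hemorrhage" not in spec.rates:
                    raise ValueError(
                        f"hemorrhage rate required for {method.value} in 'rate' mode"
                    )
        return self


def _substream(seed: int, method: SurgicalMethod, field: str) -> np.random.Generator:
    """Deterministic per-(method, field) RNG derived from the master seed.

    The stream key is a stable CRC32 of ``"method:field"``, so the draws for
    one field are unaffected by the presence or configuration of any other.
    """
    key = zlib.crc32(f"{method.value}:{field}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def generate_cohort(
    config: CohortGeneratorConfig, seed: int | None = None
) -> pd.DataFrame:
    """Generate a synthetic cohort, one row per patient.

    Parameters
    ----------
    config
        Validated generator configuration.
    seed
        Master seed; defaults to ``config.seed``. Identical (config, seed)
        pairs produce identical output.

    Returns
    -------
    pandas.DataFrame with the canonical column order (:data:`COHORT_COLUMNS`),
    boolean fields as numpy bools, exactly ``config.methods[m].n`` rows per
    method.
    """
    master = config.seed if seed is None else seed
    frames = []
    for method in METHOD_ORDER:
        spec = config.methods[method]
        n = spec.n
        cols: dict[str, np.ndarray] = {}
        for field in CONTINUOUS_FIELDS:
            rng = _substream(master, method, field)
            cols[field] = spec.continuous[field].ppf(rng.random(n))
        for field in RATE_FIELDS:
            rng = _substream(master, method, field)
            cols[field] = rng.random(n) < spec.rates[field]
        if config.hemorrhage_mode == "ebl":
            cols["hemorrhage"] = cols["ebl"] >= HEMORRHAGE_EBL_THRESHOLD
        else:
            rng = _substream(master, method, "hemorrhage")
            cols["hemorrhage"] = rng.random(n) < spec.rates["hemorrhage"]
        cols["patient_id"] = np.array(
            [f"{method.value}-{i:05d}" for i in range(n)], dtype=object
        )
        cols["method"] = np.array([method.value] * n, dtype=object)
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)
    return df[list(COHORT_COLUMNS)]


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort table with booleans serialized as 0/1."""
    out = df.copy()
    for field in BOOLEAN_FIELDS:
        out[field] = out[field].astype(int)
    out.to_csv(path, index=False, lineterminator="\n")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV back into the canonical in-memory form."""
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"cohort CSV missing columns: {sorted(missing)}")
    for field in BOOLEAN_FIELDS:
        df[field] = df[field].astype(bool)
    return df[list(COHORT_COLUMNS)]


def records_to_frame(records) -> pd.DataFrame:
    """Convert an iterable of :class:`PatientRecord` to the canonical table."""
    rows = [
        {c: (r.method.value if c == "method" else getattr(r, c)) for c in COHORT_COLUMNS}
        for r in records
    ]
    if not rows:
        raise ParameterError("empty record collection")
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Convert a cohort table to a list of validated :class:`PatientRecord`."""
    return [
        PatientRecord(
            **{
                c: (SurgicalMethod(row[c]) if c == "method" else row[c])
                for c in COHORT_COLUMNS
            }
        )
        for row in df.to_dict("records")
    ]
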
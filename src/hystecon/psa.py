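"""Probabilistic sensitivity analysis (Monte Carlo).

Each sampled decision-model parameter is given a normal distribution centred
on its point estimate, with spread representing parameter (sampling)
uncertainty — the binomial standard error sqrt(p(1-p)/n) for the LND,
conversion and hemorrhage branch probabilities.  By default only these
clinical outcome probabilities are sampled: the expected-cost operator is
multilinear in them, so their uncertainty propagates without bias, whereas
pushing OR-time draws through the stepped billing schedule would add a
discretization bias of up to one increment to the mean.  OR-time (or any
other) spreads can still be requested through explicit distribution
overrides.

Truncation policy: probabilities are truncated to [0, 1] and times to be
positive, sampled by inverse CDF on uniform draws (exact, no mass atoms at
the bounds, common-random-number friendly).  Truncated sampling is
*mean-preserving*: the parent normal's location is shifted so the truncated
distribution's mean equals the point estimate — the truncated-normal
analogue of the moment-matched bounded distributions conventionally used in
probabilistic sensitivity analysis — so the simulation remains an unbiased
propagation of parameter uncertainty.

Parameters the cohort estimates with zero variance must either be flagged
with an explicit (literature-sourced) distribution or are held constant; a
flagged parameter without a distribution is a configuration error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .cohort import ContinuousSpec
from .errors import ConfigurationError, ParameterError
from .methods import CONVERTIBLE_METHODS, METHOD_ORDER, SurgicalMethod
from .statistics import DEFAULT_LITERATURE_REQUIRED
from .tree import ModelParameters, method_expected_cost_vec

#: Parameter slots sampled per method, in stable stream order.
SAMPLED_PARAMETERS: tuple[str, ...] = (
    "base_or_time",
    "p_lnd",
    "p_conversion",
    "p_hemorrhage",
)

#: Open lower bound for sampled OR times (minutes).
_TIME_FLOOR = 1e-9


class DistributionSpec(ContinuousSpec):
    """Truncated-normal parameter distribution with a provenance label.

    With ``mean_matched`` (default) the parent normal's location is solved so
    that the *truncated* mean equals ``mean``; the configured ``sd`` remains
    the parent scale.  Matching is skipped when it is infeasible (the target
    mean on or outside the bounds) or irrelevant (no truncation, sd = 0).
    """

    model_config = ConfigDict(frozen=True)

    source: str = "cohort"
    mean_matched: bool = True

    def _matched_loc(self) -> float:
        lo = -np.inf if self.lower is None else self.lower
        hi = np.inf if self.upper is None else self.upper
        if self.sd == 0 or (lo == -np.inf and hi == np.inf):
            return self.mean
        if not (lo < self.mean < hi):
            return self.mean  # infeasible target: fall back to plain truncation
        from scipy import optimize, stats

        def truncated_mean(loc: float) -> float:
            a = (lo - loc) / self.sd
            b = (hi - loc) / self.sd
            return float(stats.truncnorm.mean(a, b, loc=loc, scale=self.sd))

        span = 8.5 * self.sd
        f = lambda loc: truncated_mean(loc) - self.mean
        lo_b, hi_b = self.mean - span, self.mean + span
        if f(lo_b) > 0 or f(hi_b) < 0:  # target unreachable within bracket
            return self.mean
        return float(optimize.brentq(f, lo_b, hi_b, xtol=1e-12))

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.sd == 0 or not self.mean_matched:
            return super().ppf(u)
        from scipy import stats

        loc = self._matched_loc()
        lo = -np.inf if self.lower is None else (self.lower - loc) / self.sd
        hi = np.inf if self.upper is None else (self.upper - loc) / self.sd
        return stats.truncnorm.ppf(u, lo, hi, loc=loc, scale=self.sd)


class PSAConfig(BaseModel):
    """Monte Carlo configuration."""

    model_config = ConfigDict(frozen=True)

    n_iterations: int = Field(default=10_000, ge=1)
    seed: int = 0
    use_common_random_numbers: bool = True
    #: Explicit distributions replacing the cohort-derived ones,
    #: e.g. the literature-sourced robotic conversion probability.
    overrides: dict[SurgicalMethod, dict[str, DistributionSpec]] = Field(
        default_factory=dict
    )


@dataclass(frozen=True)
class MethodPSA:
    costs: np.ndarray
    mean: float
    sd: float
    p2_5: float
    p50: float
    p97_5: float

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "p2.5": self.p2_5,
            "p50": self.p50,
            "p97.5": self.p97_5,
        }


@dataclass(frozen=True)
class PSAResult:
    n_iterations: int
    seed: int
    methods: dict[SurgicalMethod, MethodPSA]
    distributions: dict[SurgicalMethod, dict[str, DistributionSpec]]

    def summary_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "methods": {m.value: s.to_dict() for m, s in self.methods.items()},
        }


@dataclass(frozen=True)
class IncrementalResult:
    """Per-iteration cost difference method_a - method_b."""

    method_a: SurgicalMethod
    method_b: SurgicalMethod
    delta: np.ndarray
    p_a_cheaper: float  # P(delta < 0)

    def to_dict(self) -> dict:
        return {
            "method_a": self.method_a.value,
            "method_b": self.method_b.value,
            "mean_delta": float(np.mean(self.delta)),
            "p_a_cheaper": self.p_a_cheaper,
        }


def resolve_distributions(
    params: ModelParameters,
    config: PSAConfig,
    literature_required: Iterable[tuple[SurgicalMethod, str]] = DEFAULT_LITERATURE_REQUIRED,
) -> dict[SurgicalMethod, dict[str, DistributionSpec]]:
    """Build the sampled distribution for every (method, parameter) slot.

    Cohort-derived defaults: probability p ~ N(p, sqrt(p(1-p)/n)) truncated
    to [0, 1] with mean matching; the base OR time is held at its point
    estimate (degenerate spec) — see the module docstring for why.  Explicit
    overrides win; :func:`or_time_se_spec` builds a standard-error OR-time
    spread for callers who want time uncertainty propagated.  A flagged
    literature-sourced slot with zero variance and no override raises
    :class:`ConfigurationError`.
    """
    required = set(literature_required)
    out: dict[SurgicalMethod, dict[str, DistributionSpec]] = {}
    for method in METHOD_ORDER:
        mp = params.methods[method]
        n = mp.n
        ov = config.overrides.get(method, {})
        specs: dict[str, DistributionSpec] = {}
        for pname in SAMPLED_PARAMETERS:
            if pname == "p_conversion" and method not in CONVERTIBLE_METHODS:
                continue  # structural zero: the abdominal tree has no conversion node
            if pname in ov:
                specs[pname] = ov[pname]
                continue
            if pname == "base_or_time":
                spec = DistributionSpec(
                    mean=mp.base_or_time, sd=0.0, lower=_TIME_FLOOR,
                    source="point-estimate",
                )
            else:
                p = getattr(mp, pname)
                sd = float(np.sqrt(p * (1.0 - p) / n)) if n else 0.0
                spec = DistributionSpec(mean=p, sd=sd, lower=0.0, upper=1.0, source="cohort")
            if spec.sd == 0.0 and (method, pname) in required:
                raise ConfigurationError(
                    f"{method.value}.{pname} has zero cohort variance and is flagged "
                    "literature-sourced: provide an explicit distribution"
                )
            specs[pname] = spec
        out[method] = specs
    return out


def or_time_se_spec(params: ModelParameters, method: SurgicalMethod) -> DistributionSpec:
    """OR-time distribution with standard-error spread (cohort sd / sqrt(n)),
    truncated to positive times — an explicit override for callers who want
    OR-time sampling despite the step-billing discretization bias."""
    mp = params.methods[method]
    sd = mp.or_time_sd / np.sqrt(mp.n) if mp.n else mp.or_time_sd
    return DistributionSpec(
        mean=mp.base_or_time, sd=float(sd), lower=_TIME_FLOOR, source="cohort-se"
    )


def degenerate_psa_config(
    params: ModelParameters, n_iterations: int = 100, seed: int = 0
) -> PSAConfig:
    """A PSA configuration with every distribution collapsed to its point
    estimate (sd = 0): every iteration reproduces the deterministic model."""
    overrides: dict[SurgicalMethod, dict[str, DistributionSpec]] = {}
    for method in METHOD_ORDER:
        mp = params.methods[method]
        specs = {
            "base_or_time": DistributionSpec(mean=mp.base_or_time, sd=0.0, source="fixed"),
            "p_lnd": DistributionSpec(mean=mp.p_lnd, sd=0.0, source="fixed"),
            "p_hemorrhage": DistributionSpec(mean=mp.p_hemorrhage, sd=0.0, source="fixed"),
        }
        if method in CONVERTIBLE_METHODS:
            specs["p_conversion"] = DistributionSpec(
                mean=mp.p_conversion, sd=0.0, source="fixed"
            )
        overrides[method] = specs
    return PSAConfig(n_iterations=n_iterations, seed=seed, overrides=overrides)


def _uniform_stream(seed: int, slot: int, method_idx: Optional[int], n: int) -> np.ndarray:
    key = [int(seed), 1000 + slot]
    if method_idx is not None:
        key.append(method_idx)
    rng = np.random.default_rng(np.random.SeedSequence(key))
    return rng.random(n)


def run_psa(
    params: ModelParameters,
    config: PSAConfig,
    literature_required: Iterable[tuple[SurgicalMethod, str]] = DEFAULT_LITERATURE_REQUIRED,
) -> PSAResult:
    """Sample the decision model ``n_iterations`` times.

    Per iteration every resolved parameter is drawn from its truncated
    normal, terminal costs are rebuilt and the expected cost of each method
    is computed from the sampled parameters.  With common random numbers
    (default) the same uniform stream feeds the corresponding parameter slot
    of every method, so incremental comparisons are paired.
    """
    dists = resolve_distributions(params, config, literature_required)
    n = config.n_iterations
    methods_out: dict[SurgicalMethod, MethodPSA] = {}
    for mi, method in enumerate(METHOD_ORDER):
        specs = dists[method]
        draws: dict[str, np.ndarray] = {}
        for si, pname in enumerate(SAMPLED_PARAMETERS):
            if pname not in specs:
                continue
            u = _uniform_stream(
                config.seed, si, None if config.use_common_random_numbers else mi, n
            )
            x = specs[pname].ppf(u)
            if pname == "base_or_time":
                x = np.maximum(x, _TIME_FLOOR)
            draws[pname] = np.asarray(x, dtype=float)
        costs = np.asarray(
            method_expected_cost_vec(
                params,
                method,
                draws["base_or_time"],
                p_lnd=draws["p_lnd"],
                p_conversion=draws.get("p_conversion"),
                p_hemorrhage=draws["p_hemorrhage"],
            ),
            dtype=float,
        )
        if costs.shape != (n,):
            costs = np.broadcast_to(costs, (n,)).copy()
        q = np.percentile(costs, [2.5, 50, 97.5])
        methods_out[method] = MethodPSA(
            costs=costs,
            mean=float(np.mean(costs)),
            sd=float(np.std(costs, ddof=1)) if n > 1 else 0.0,
            p2_5=float(q[0]),
            p50=float(q[1]),
            p97_5=float(q[2]),
        )
    return PSAResult(
        n_iterations=n, seed=config.seed, methods=methods_out, distributions=dists
    )


def incremental_distribution(
    result: PSAResult, method_a: SurgicalMethod, method_b: SurgicalMethod
) -> IncrementalResult:
    """Per-iteration incremental cost of ``method_a`` over ``method_b``."""
    a = result.methods[method_a].costs
    b = result.methods[method_b].costs
    if a.shape != b.shape:
        raise ParameterError("mismatched PSA sample lengths")
    delta = a - b
    return IncrementalResult(
        method_a=method_a,
        method_b=method_b,
        delta=delta,
        p_a_cheaper=float(np.mean(delta < 0)),
    )
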
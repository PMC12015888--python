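"""Uncertainty analyses: probabilistic SA with CEAC, one-way deterministic
SA with tornado ordering, and the five scenario analyses.

PSA draws each uncertain parameter independently from a family chosen by
its support (beta for probabilities and utilities, gamma for costs,
lognormal for relative effects), parameterized by moment matching from
the point estimate and a standard error (the printed SE where one exists,
otherwise 20% of the mean).  The DSA varies one parameter at a time by
+/-20% of the point estimate, clipped to its support.  Scenarios are pure
parameter/structural overrides of the base case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_engine import MortalityTable, run_cohort
from .outcomes import IncrementalResult, incremental_compare
from .parameters import (
    INPATIENT_TYPES,
    PLATELET_STATUSES,
    TREATMENTS,
    FREQUENTIST_RESPONSE,
    ModelParameters,
    get_path,
    set_path,
    validate_parameters,
)
from .payoffs import CEOutcome, accumulate_outcomes

logger = logging.getLogger(__name__)

SCENARIO_NAMES = ("frequentist_response", "subsequent_lines", "standard_tariff",
                  "qualitative_tariff", "window_12_weeks")

DEFAULT_SE_FRACTION = 0.20


# ---------------------------------------------------------------------------
# Distribution assignment and sampling
# ---------------------------------------------------------------------------


@dataclass
class DistributionSpec:
    """Sampling family for one scalar parameter (dot-path addressed)."""

    path: str
    family: str               # beta | gamma | lognormal | normal | fixed
    mean: float
    se: float = 0.0
    group: str | None = None  # joint-renormalization group (distributions)

    def sample(self, rng: np.random.Generator) -> float:
        m, s = self.mean, self.se
        if self.family == "fixed" or s == 0.0:
            return m
        if self.family == "beta":
            if m <= 0.0 or m >= 1.0:
                return m
            nu = m * (1.0 - m) / s**2 - 1.0
            if nu <= 0:  # SE too large for the support; fall back to the mean
                return m
            return float(rng.beta(m * nu, (1.0 - m) * nu))
        if self.family == "gamma":
            if m <= 0.0:
                return m
            shape = (m / s) ** 2
            return float(rng.gamma(shape, s**2 / m))
        if self.family == "lognormal":
            sigma2 = np.log1p((s / m) ** 2)
            mu = np.log(m) - sigma2 / 2.0
            return float(rng.lognormal(mu, np.sqrt(sigma2)))
        if self.family == "normal":
            return float(rng.normal(m, s))
        raise ValueError(f"unknown family '{self.family}'")


def _beta_spec(path: str, mean: float, se: float | None = None,
               group: str | None = None) -> DistributionSpec:
    return DistributionSpec(path, "beta", mean,
                            se if se is not None else DEFAULT_SE_FRACTION * mean,
                            group)


def _gamma_spec(path: str, mean: float) -> DistributionSpec:
    return DistributionSpec(path, "gamma", mean, DEFAULT_SE_FRACTION * mean)


def assign_distributions(p: ModelParameters) -> list[DistributionSpec]:
    """Default distribution set for the probabilistic analysis.

    Probabilities, fractions and utilities are beta; costs are gamma; the
    adverse-event disutility uses its printed SE; structural counts (cycle
    lengths, windows, horizon) are fixed and not sampled.
    """
    specs: list[DistributionSpec] = []
    for t in TREATMENTS:
        specs.append(_beta_spec(f"response.{t}.response_probability",
                                p.response[t].response_probability))
    for status in PLATELET_STATUSES:
        for cat in ("minor", "outpatient", "inpatient"):
            specs.append(_beta_spec(f"bleeds.probabilities.{status}.{cat}",
                                    p.bleeds.probabilities[status][cat]))
        for t in INPATIENT_TYPES:
            specs.append(_beta_spec(
                f"bleeds.inpatient_type_distribution_raw.{status}.{t}",
                p.bleeds.inpatient_type_distribution_raw[status][t],
                group=f"inpatient_type_distribution.{status}"))
    for t in INPATIENT_TYPES:
        specs.append(_beta_spec(f"bleeds.case_fatality.{t}",
                                p.bleeds.case_fatality[t]))
    variant = p.costs.bleed_tariff_variant
    for kind, gbp in p.costs.tariff().items():
        if gbp > 0:
            specs.append(_gamma_spec(f"costs.bleed_tariffs.{variant}.{kind}", gbp))
    for t, gbp in p.costs.inpatient_hcru_extra.items():
        if gbp > 0:
            specs.append(_gamma_spec(f"costs.inpatient_hcru_extra.{t}", gbp))
    for kind, gbp in p.costs.follow_up.items():
        specs.append(_gamma_spec(f"costs.follow_up.{kind}", gbp))
    for status in PLATELET_STATUSES:
        for cat in ("no_bleed", "outpatient"):
            specs.append(_beta_spec(f"utilities.state_utility.{status}.{cat}",
                                    p.utilities.state_utility[status][cat]))
    for t, u in p.utilities.inpatient_utility.items():
        specs.append(_beta_spec(f"utilities.inpatient_utility.{t}", u))
    specs.append(_beta_spec("utilities.tpora_trae_disutility",
                            p.utilities.tpora_trae_disutility,
                            se=p.utilities.tpora_trae_disutility_se))
    for state, frac in p.care.concomitant_fraction.items():
        specs.append(_beta_spec(f"care.concomitant_fraction.{state}", frac))
    for status, frac in p.care.rescue_fraction.items():
        specs.append(_beta_spec(f"care.rescue_fraction.{status}", frac))
    ap = p.care.appendix
    for fld in ("concomitant_cost_per_cycle", "rescue_acquisition_cost_per_use",
                "rescue_administration_cost_per_use"):
        gbp = getattr(ap, fld)
        if gbp > 0:
            specs.append(_gamma_spec(f"care.appendix.{fld}", gbp))
    specs.append(_beta_spec("care.appendix.trae_incidence_per_cycle_on_treatment",
                            ap.trae_incidence_per_cycle_on_treatment))
    return specs


def sample_parameter_set(p: ModelParameters, specs: list[DistributionSpec],
                         rng: np.random.Generator) -> ModelParameters:
    """Independent draw per spec; joint distribution groups renormalized.

    The returned parameter set passes :func:`validate_parameters`; draws
    violating a joint constraint (a relative distribution not summing
    to 1) are renormalized and the event logged at DEBUG level.
    """
    sampled = p.copy()
    groups: dict[str, list[str]] = {}
    for spec in specs:
        set_path(sampled, spec.path, spec.sample(rng))
        if spec.group:
            groups.setdefault(spec.group, []).append(spec.path)
    for group, paths in groups.items():
        total = sum(get_path(sampled, path) for path in paths)
        if total > 0 and abs(total - 1.0) > 1e-12:
            logger.debug("renormalizing %s (drawn sum %.4f)", group, total)
            for path in paths:
                set_path(sampled, path, get_path(sampled, path) / total)
    # the <50 >= >=50 ordering of bleed risks can be violated by extreme
    # draws; restore it by swapping, keeping both marginals in play
    for cat in ("minor", "outpatient", "inpatient"):
        lo = sampled.bleeds.probabilities["lt50"][cat]
        hi = sampled.bleeds.probabilities["ge50"][cat]
        if lo < hi:
            sampled.bleeds.probabilities["lt50"][cat] = hi
            sampled.bleeds.probabilities["ge50"][cat] = lo
    u = sampled.utilities.state_utility
    if u["ge50"]["no_bleed"] < u["lt50"]["no_bleed"]:
        u["ge50"]["no_bleed"], u["lt50"]["no_bleed"] = \
            u["lt50"]["no_bleed"], u["ge50"]["no_bleed"]
    problems = validate_parameters(sampled)
    if problems:
        raise RuntimeError("sampled parameter set invalid: " + "; ".join(problems))
    return sampled


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------


@dataclass
class PSAResult:
    """Per-iteration incremental (QALY, cost) pairs per comparison."""

    reference: str
    iterations: pd.DataFrame  # columns: iteration, comparator, delta_qaly, delta_cost
    seed: int
    n_iterations: int

    def deltas(self, comparator: str) -> pd.DataFrame:
        return self.iterations[self.iterations["comparator"] == comparator]


def run_psa(p: ModelParameters, n_iterations: int, seed: int,
            table: MortalityTable | None = None,
            specs: list[DistributionSpec] | None = None,
            reference: str = "avatrombopag") -> PSAResult:
    """Monte-Carlo parameter uncertainty: sample, rerun all treatments,
    record reference-minus-comparator deltas.  Deterministic under seed."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if table is None:
        from .synthetic_data import synthetic_life_table
        table = synthetic_life_table(p.life_table)
    specs = assign_distributions(p) if specs is None else specs
    rng = np.random.default_rng(seed)
    records = []
    for it in range(n_iterations):
        sampled = sample_parameter_set(p, specs, rng)
        outcomes = {t: accumulate_outcomes(run_cohort(sampled, t, table), sampled, t)
                    for t in TREATMENTS}
        for comparator in TREATMENTS:
            if comparator == reference:
                continue
            inc = incremental_compare(outcomes[reference], outcomes[comparator])
            records.append({"iteration": it, "comparator": comparator,
                            "delta_qaly": inc.delta_qaly,
                            "delta_cost": inc.delta_cost})
    return PSAResult(reference=reference, iterations=pd.DataFrame(records),
                     seed=seed, n_iterations=n_iterations)


def compute_ceac(result: PSAResult,
                 thresholds: list[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability: per threshold, the fraction of
    iterations whose net monetary benefit is strictly positive."""
    if result.iterations.empty:
        raise ValueError("empty PSA result")
    rows = []
    for comparator in result.iterations["comparator"].unique():
        d = result.deltas(comparator)
        dq = d["delta_qaly"].to_numpy()
        dc = d["delta_cost"].to_numpy()
        for lam in thresholds:
            nmb = lam * dq - dc
            rows.append({"comparator": comparator, "threshold": lam,
                         "probability_cost_effective": float(np.mean(nmb > 0))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DSA
# ---------------------------------------------------------------------------

#: Parameters eligible for one-way variation (editable).
DSA_PARAMETERS: tuple[str, ...] = (
    "response.avatrombopag.response_probability",
    "response.eltrombopag.response_probability",
    "response.romiplostim.response_probability",
    "treatments.avatrombopag.dose",
    "treatments.eltrombopag.dose",
    "treatments.romiplostim.dose",
    "bleeds.probabilities.ge50.outpatient",
    "bleeds.probabilities.lt50.outpatient",
    "bleeds.probabilities.lt50.inpatient",
    "bleeds.case_fatality.intracranial",
    "bleeds.case_fatality.gastrointestinal",
    "bleeds.case_fatality.other",
    "costs.bleed_tariffs.increased_nhs.outpatient",
    "costs.bleed_tariffs.increased_nhs.intracranial",
    "costs.bleed_tariffs.increased_nhs.gastrointestinal",
    "costs.bleed_tariffs.increased_nhs.other",
    "costs.bleed_tariffs.increased_nhs.minor",
    "costs.follow_up.haematologist_consultation",
    "utilities.state_utility.ge50.no_bleed",
    "utilities.state_utility.lt50.no_bleed",
    "utilities.tpora_trae_disutility",
    "care.concomitant_fraction.response",
    "care.concomitant_fraction.no_response",
    "care.rescue_fraction.ge50",
    "care.rescue_fraction.lt50",
    "care.appendix.rescue_acquisition_cost_per_use",
    "care.appendix.concomitant_cost_per_cycle",
)

_PROBABILITY_PREFIXES = ("response.", "bleeds.probabilities", "bleeds.case_fatality",
                         "care.concomitant_fraction", "care.rescue_fraction",
                         "care.appendix.trae_incidence")


@dataclass
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_low: float | str
    icer_high: float | str
    nmb_low: float
    nmb_high: float

    @property
    def nmb_range(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def _clip_to_support(path: str, value: float) -> float:
    if path.startswith(_PROBABILITY_PREFIXES) or "utilities" in path:
        return min(max(value, 0.0), 1.0)
    return max(value, 0.0)


def _icer_and_nmb(p: ModelParameters, table: MortalityTable,
                  intervention: str, comparator: str,
                  wtp: float) -> tuple[float | str, float]:
    outcomes = {t: accumulate_outcomes(run_cohort(p, t, table), p, t)
                for t in (intervention, comparator)}
    inc = incremental_compare(outcomes[intervention], outcomes[comparator])
    return inc.icer, wtp * inc.delta_qaly - inc.delta_cost


def run_dsa(p: ModelParameters, bound_fraction: float = 0.20,
            parameters: tuple[str, ...] = DSA_PARAMETERS,
            intervention: str = "avatrombopag",
            comparator: str = "eltrombopag",
            wtp: float = 20000.0,
            table: MortalityTable | None = None) -> list[TornadoEntry]:
    """One-way sensitivity analysis.

    Each eligible parameter is set to (1 +/- bound_fraction) times its
    point estimate (clipped to support) with everything else at base case;
    the deterministic model is rerun and the ICER and net monetary benefit
    of the intervention versus the comparator recorded at both bounds.
    Entries come back sorted by net-monetary-benefit range (tornado order).
    """
    if table is None:
        from .synthetic_data import synthetic_life_table
        table = synthetic_life_table(p.life_table)
    entries = []
    for path in parameters:
        base = get_path(p, path)
        low_v = _clip_to_support(path, base * (1.0 - bound_fraction))
        high_v = _clip_to_support(path, base * (1.0 + bound_fraction))
        results = {}
        for tag, value in (("low", low_v), ("high", high_v)):
            varied = p.copy()
            set_path(varied, path, value)
            results[tag] = _icer_and_nmb(varied, table, intervention,
                                         comparator, wtp)
        entries.append(TornadoEntry(
            parameter=path, low_value=low_v, high_value=high_v,
            icer_low=results["low"][0], icer_high=results["high"][0],
            nmb_low=results["low"][1], nmb_high=results["high"][1]))
    entries.sort(key=lambda e: e.nmb_range, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter, "low_value": e.low_value,
        "high_value": e.high_value, "icer_low": e.icer_low,
        "icer_high": e.icer_high, "nmb_low": e.nmb_low,
        "nmb_high": e.nmb_high, "nmb_range": e.nmb_range,
    } for e in entries])


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSpec:
    """A named scenario expressed purely as overrides of the base case."""

    name: str
    description: str = ""


@dataclass
class ScenarioResult:
    name: str
    outcomes: dict[str, CEOutcome]
    incrementals: dict[str, IncrementalResult] = field(default_factory=dict)


def apply_scenario(p: ModelParameters, name: str) -> ModelParameters:
    """Return a parameter set with the named scenario's overrides applied."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario '{name}'; valid: {SCENARIO_NAMES}")
    s = p.copy()
    if name == "frequentist_response":
        for t, prob in FREQUENTIST_RESPONSE.items():
            s.response[t].response_probability = prob
    elif name == "standard_tariff":
        s.costs.bleed_tariff_variant = "standard_nhs"
    elif name == "qualitative_tariff":
        s.costs.bleed_tariff_variant = "qualitative_study"
    elif name == "window_12_weeks":
        for r in s.response.values():
            r.non_response_window_cycles = 3
            r.time_to_response_cycles = min(r.time_to_response_cycles, 3)
    elif name == "subsequent_lines":
        s.settings.enable_subsequent_lines = True
        s.care.appendix.refractory_inpatient_bleed_multiplier = 2.0
    return s


def run_scenario(p: ModelParameters, name: str,
                 table: MortalityTable | None = None,
                 reference: str = "avatrombopag") -> ScenarioResult:
    """Apply a scenario's overrides and rerun the deterministic model."""
    s = apply_scenario(p, name)
    if table is None:
        from .synthetic_data import synthetic_life_table
        table = synthetic_life_table(s.life_table)
    outcomes = {t: accumulate_outcomes(run_cohort(s, t, table), s, t)
                for t in TREATMENTS}
    incrementals = {t: incremental_compare(outcomes[reference], outcomes[t])
                    for t in TREATMENTS if t != reference}
    return ScenarioResult(name=name, outcomes=outcomes, incrementals=incrementals)
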
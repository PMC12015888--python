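"""Model input set for the TPO-RA cost-effectiveness model.

Defines, defaults, loads and validates every input the cohort model
consumes: cohort demography, the three treatment profiles, response
parameters, bleeding-event model, cost tariffs, utilities, the care model
(concomitant / rescue therapy use) and simulation settings.

Every scalar carries a provenance tag (see :data:`PROVENANCE`): values
printed in the published input table are tagged ``table1``; values that in
the source analysis live only in an unpublished appendix are explicit,
user-overridable placeholders tagged ``placeholder``; structural
conventions chosen by this package are tagged ``convention``.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Iterator

import yaml

# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

TREATMENTS = ("avatrombopag", "eltrombopag", "romiplostim")

#: Alive health states plus the absorbing death state.
STATES = ("response", "no_response", "no_active_treatment", "dead")
ALIVE_STATES = STATES[:-1]

#: Binary platelet status: >=50e9/L ("ge50") versus <50e9/L ("lt50").
PLATELET_GE50 = "ge50"
PLATELET_LT50 = "lt50"
PLATELET_STATUSES = (PLATELET_GE50, PLATELET_LT50)

BLEED_CATEGORIES = ("minor", "outpatient", "inpatient")
INPATIENT_TYPES = ("intracranial", "gastrointestinal", "other")
TARIFF_VARIANTS = ("increased_nhs", "standard_nhs", "qualitative_study")

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Demography:
    """Cohort entry characteristics (means over the trial population)."""

    mean_age: float = 44.6            # years
    male_fraction: float = 0.367      # proportion
    mean_weight_kg: float = 82.97
    mean_body_area_m2: float = 1.94


@dataclass
class TreatmentProfile:
    """Dosing and pricing of one TPO-RA.

    ``relative_dose_intensity`` scales the label dose to the mean realized
    dose; it is an assumption-tier input (the label start dose overstates
    the maintenance dose actually dispensed for avatrombopag).
    ``vial_wastage`` rounds the weekly weight-based dose up to whole
    0.125 mg billing units (romiplostim only).
    """

    name: str
    dosing_mode: str                  # fixed_daily_mg | weight_based_weekly_mg_per_kg
    dose: float                       # mg/day or mg/kg/week
    pack_price: float                 # GBP per priced unit
    pack_content_mg: float            # mg of drug per priced unit
    admin_cost_per_administration: float = 0.0
    home_admin_fraction_first_cycle: float = 1.0
    home_admin_fraction_later_cycles: float = 1.0
    vial_wastage: bool = False
    relative_dose_intensity: float = 1.0


@dataclass
class ResponseModel:
    """Durable-response parameters for one treatment.

    The per-cycle response realization happens at ``time_to_response_cycles``;
    non-responders leave active treatment when the assessment window
    (``non_response_window_cycles``) closes.  ``duration_mode`` selects the
    embedding of the mean response duration: ``geometric`` (constant exit
    hazard 1/mean) or ``fixed`` (hard stop after the mean).
    """

    response_probability: float
    time_to_response_cycles: int = 6
    non_response_window_cycles: int = 7
    mean_response_duration_cycles: float = 109.0
    duration_mode: str = "geometric"


@dataclass
class BleedModel:
    """Per-cycle bleeding probabilities by platelet status.

    ``inpatient_type_distribution_raw`` stores the printed relative
    distribution (which for the <50 status sums to 1.01 due to rounding);
    the normalized distribution actually used by the model is exposed via
    :meth:`inpatient_type_distribution`.
    """

    probabilities: dict[str, dict[str, float]] = field(default_factory=lambda: {
        PLATELET_GE50: {"minor": 0.100, "outpatient": 0.071, "inpatient": 0.000},
        PLATELET_LT50: {"minor": 0.171, "outpatient": 0.455, "inpatient": 0.043},
    })
    inpatient_type_distribution_raw: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            PLATELET_GE50: {"intracranial": 0.00, "gastrointestinal": 0.29, "other": 0.71},
            PLATELET_LT50: {"intracranial": 0.19, "gastrointestinal": 0.19, "other": 0.63},
        })
    case_fatality: dict[str, float] = field(default_factory=lambda: {
        "intracranial": 0.132, "gastrointestinal": 0.046, "other": 0.017,
    })

    def inpatient_type_distribution(self, status: str) -> dict[str, float]:
        """Relative distribution of inpatient bleed types, normalized to 1."""
        raw = self.inpatient_type_distribution_raw[status]
        total = sum(raw.values())
        if total <= 0:
            return {t: 0.0 for t in raw}
        return {t: v / total for t, v in raw.items()}


@dataclass
class CostSet:
    """Unit costs: bleed tariffs (three variants), inpatient HCRU uplift,
    follow-up / monitoring costs."""

    bleed_tariff_variant: str = "increased_nhs"
    bleed_tariffs: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "increased_nhs": {"minor": 0.0, "outpatient": 494.0, "intracranial": 7044.0,
                          "gastrointestinal": 5503.0, "other": 3485.0},
        "standard_nhs": {"minor": 0.0, "outpatient": 460.0, "intracranial": 4691.0,
                         "gastrointestinal": 3092.0, "other": 2891.0},
        "qualitative_study": {"minor": 0.0, "outpatient": 3134.0, "intracranial": 25699.0,
                              "gastrointestinal": 14325.0, "other": 14325.0},
    })
    # Additional per-admission resource use (ER, ward stay, surgery, ambulance,
    # imaging, labs) on top of the tariff; appendix-tier placeholder.
    inpatient_hcru_extra: dict[str, float] = field(default_factory=lambda: {
        "intracranial": 6350.0, "gastrointestinal": 4960.0, "other": 3220.0,
    })
    follow_up: dict[str, float] = field(default_factory=lambda: {
        "haematologist_consultation": 173.39, "blood_test": 2.79, "biochemistry": 1.10,
    })
    monitoring_visits_per_year: float = 12.0

    def tariff(self, variant: str | None = None) -> dict[str, float]:
        return self.bleed_tariffs[variant or self.bleed_tariff_variant]

    def follow_up_per_visit(self) -> float:
        return sum(self.follow_up.values())


@dataclass
class UtilitySet:
    """Health-state utilities by platelet status and bleed category."""

    state_utility: dict[str, dict[str, float]] = field(default_factory=lambda: {
        PLATELET_GE50: {"no_bleed": 0.801, "outpatient": 0.625},
        PLATELET_LT50: {"no_bleed": 0.760, "outpatient": 0.584},
    })
    inpatient_utility: dict[str, float] = field(default_factory=lambda: {
        "intracranial": 0.038, "gastrointestinal": 0.45, "other": 0.45,
    })
    tpora_trae_disutility: float = 0.10
    tpora_trae_disutility_se: float = 0.025
    # Appendix-tier decrements per exposed patient-cycle (placeholder).
    appendix_disutilities: dict[str, float] = field(default_factory=lambda: {
        "rescue_therapy": 0.05, "concomitant_medication": 0.02,
    })


@dataclass
class AppendixPlaceholders:
    """Inputs the source analysis keeps in an unpublished appendix.

    All values here are placeholders calibrated so that the lifetime
    category subtotals are of the order of the published cost breakdown;
    users with the appendix in hand should override them via config.
    """

    concomitant_cost_per_cycle: float = 154.0           # GBP / patient-cycle on concomitant meds
    rescue_acquisition_cost_per_use: float = 2050.0     # GBP / rescue episode (IVIg-dominated mix)
    rescue_administration_cost_per_use: float = 905.0   # GBP / rescue episode
    trae_incidence_per_cycle_on_treatment: float = 0.02
    trae_cost_per_event: float = 0.0
    trae_duration_fraction_of_cycle: float = 1.0
    # Subsequent-lines scenario machinery (scenario analysis only).
    subsequent_line_response_probabilities: list[float] = field(
        default_factory=lambda: [0.30, 0.25, 0.20])
    subsequent_line_time_to_response_cycles: int = 3
    subsequent_line_window_cycles: int = 3
    subsequent_line_mean_duration_cycles: float = 26.0
    subsequent_line_cost_per_cycle: float = 200.0
    refractory_inpatient_bleed_multiplier: float = 1.0  # 2.0 in the subsequent-lines scenario


@dataclass
class CareModel:
    """Concomitant-medication and rescue-therapy use by model state."""

    concomitant_fraction: dict[str, float] = field(default_factory=lambda: {
        "response": 0.359, "no_response": 0.449, "no_active_treatment": 0.449,
    })
    rescue_fraction: dict[str, float] = field(default_factory=lambda: {
        PLATELET_GE50: 0.03, PLATELET_LT50: 0.22,
    })
    appendix: AppendixPlaceholders = field(default_factory=AppendixPlaceholders)


@dataclass
class LifeTableSpec:
    """Gompertz-Makeham annual-mortality generator parameters per sex.

    q(a) = 1 - exp(-(A + B*exp(C*a))), calibrated to 2019 UK national
    life-table magnitudes (period life expectancy ~80 male / ~83 female).
    """

    male: tuple[float, float, float] = (2.0e-4, 2.2e-5, 0.097)
    female: tuple[float, float, float] = (1.3e-4, 1.4e-5, 0.1005)
    max_age: int = 120


@dataclass
class SimulationSettings:
    cycle_length_days: float = 28.0
    annual_discount_rate: float = 0.035
    max_age: float = 100.0            # lifetime-horizon proxy
    wtp_thresholds: list[float] = field(
        default_factory=lambda: [float(x) for x in range(0, 50001, 5000)])
    seed: int = 20210913
    enable_subsequent_lines: bool = False
    monitoring_off_treatment: bool = True

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR


@dataclass
class ModelParameters:
    """The complete, validated input set of the cost-effectiveness model."""

    demography: Demography = field(default_factory=Demography)
    treatments: dict[str, TreatmentProfile] = field(default_factory=dict)
    response: dict[str, ResponseModel] = field(default_factory=dict)
    bleeds: BleedModel = field(default_factory=BleedModel)
    costs: CostSet = field(default_factory=CostSet)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    care: CareModel = field(default_factory=CareModel)
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    life_table: LifeTableSpec = field(default_factory=LifeTableSpec)

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------

TABLE1 = "table1"
PLACEHOLDER = "placeholder"
CONVENTION = "convention"

#: Dot-path -> provenance tag for every leaf of the default base case.
#: Paths not listed are structural conventions of this package.
PROVENANCE: dict[str, str] = {
    "demography.mean_age": TABLE1,
    "demography.male_fraction": TABLE1,
    "demography.mean_weight_kg": TABLE1,
    "demography.mean_body_area_m2": TABLE1,
    "treatments.avatrombopag.dose": TABLE1,
    "treatments.avatrombopag.pack_price": TABLE1,
    "treatments.avatrombopag.pack_content_mg": TABLE1,
    "treatments.avatrombopag.relative_dose_intensity": PLACEHOLDER,
    "treatments.eltrombopag.dose": TABLE1,
    "treatments.eltrombopag.pack_price": TABLE1,
    "treatments.eltrombopag.pack_content_mg": TABLE1,
    "treatments.romiplostim.dose": TABLE1,
    "treatments.romiplostim.pack_price": TABLE1,
    "treatments.romiplostim.pack_content_mg": TABLE1,
    "treatments.romiplostim.admin_cost_per_administration": TABLE1,
    "treatments.romiplostim.home_admin_fraction_first_cycle": TABLE1,
    "treatments.romiplostim.home_admin_fraction_later_cycles": TABLE1,
    "response.avatrombopag.response_probability": TABLE1,
    "response.eltrombopag.response_probability": TABLE1,
    "response.romiplostim.response_probability": TABLE1,
    "response.avatrombopag.time_to_response_cycles": TABLE1,
    "response.avatrombopag.mean_response_duration_cycles": TABLE1,
    "bleeds.probabilities": TABLE1,
    "bleeds.inpatient_type_distribution_raw": TABLE1,
    "bleeds.case_fatality": TABLE1,
    "costs.bleed_tariffs": TABLE1,
    "costs.follow_up": TABLE1,
    "costs.inpatient_hcru_extra": PLACEHOLDER,
    "costs.monitoring_visits_per_year": CONVENTION,
    "utilities.state_utility": TABLE1,
    "utilities.inpatient_utility": TABLE1,
    "utilities.tpora_trae_disutility": TABLE1,
    "utilities.tpora_trae_disutility_se": TABLE1,
    "utilities.appendix_disutilities": PLACEHOLDER,
    "care.concomitant_fraction.response": TABLE1,
    "care.concomitant_fraction.no_response": TABLE1,
    "care.concomitant_fraction.no_active_treatment": CONVENTION,
    "care.rescue_fraction": TABLE1,
    "care.appendix": PLACEHOLDER,
    "settings.cycle_length_days": TABLE1,
    "settings.annual_discount_rate": TABLE1,
    "settings.max_age": CONVENTION,
    "life_table": PLACEHOLDER,
}


def placeholder_paths() -> list[str]:
    """Dot-paths of every input that is an assumption, not a published value."""
    return sorted(p for p, tag in PROVENANCE.items() if tag == PLACEHOLDER)


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------

#: Durable response probabilities consumed by the model.  The base case is
#: the Bayesian network-meta-analysis set anchored on avatrombopag; the
#: frequentist set is used by the corresponding scenario analysis.
BAYESIAN_RESPONSE = {"avatrombopag": 0.73, "eltrombopag": 0.27, "romiplostim": 0.55}
FREQUENTIST_RESPONSE = {"avatrombopag": 0.42, "eltrombopag": 0.22, "romiplostim": 0.47}

#: Trial durable-response 2x2 counts (treatment events/n, placebo events/n).
TRIAL_COUNTS = {
    "avatrombopag": (11, 32, 0, 17),
    "eltrombopag": (57, 95, 4, 39),
    "romiplostim_splenectomised": (16, 42, 0, 21),
    "romiplostim_nonsplenectomised": (25, 41, 1, 21),
}


def default_base_case() -> ModelParameters:
    """The published base case: increased-NHS bleed tariff, Bayesian response
    probabilities, list prices, calibrated placeholders for appendix inputs."""
    treatments = {
        "avatrombopag": TreatmentProfile(
            name="avatrombopag", dosing_mode="fixed_daily_mg", dose=20.0,
            pack_price=1920.0, pack_content_mg=30 * 20.0,
            relative_dose_intensity=0.63),
        "eltrombopag": TreatmentProfile(
            name="eltrombopag", dosing_mode="fixed_daily_mg", dose=50.0,
            pack_price=1540.0, pack_content_mg=28 * 50.0),
        "romiplostim": TreatmentProfile(
            name="romiplostim", dosing_mode="weight_based_weekly_mg_per_kg",
            dose=0.004, pack_price=241.0, pack_content_mg=0.125,
            admin_cost_per_administration=241.06,
            home_admin_fraction_first_cycle=0.0,
            home_admin_fraction_later_cycles=0.723,
            vial_wastage=False),
    }
    response = {t: ResponseModel(response_probability=p)
                for t, p in BAYESIAN_RESPONSE.items()}
    return ModelParameters(treatments=treatments, response=response)


# ---------------------------------------------------------------------------
# Serialization / config loading
# ---------------------------------------------------------------------------


def _to_plain(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def params_to_dict(p: ModelParameters) -> dict:
    """Plain nested-dict form of a parameter set (YAML-serializable)."""
    return _to_plain(p)


def save_config(p: ModelParameters, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(p), sort_keys=False))


class ConfigError(ValueError):
    """Raised when a config file does not match the parameter schema."""


def _apply_overrides(obj: Any, overrides: dict, path: str) -> Any:
    """Recursively apply a nested override dict onto a dataclass tree."""
    if is_dataclass(obj) and not isinstance(obj, type):
        known = {f.name: f for f in fields(obj)}
        for key, val in overrides.items():
            if key not in known:
                raise ConfigError(f"unknown key '{path}{key}'")
            cur = getattr(obj, key)
            if isinstance(val, dict) and (is_dataclass(cur) or isinstance(cur, dict)):
                _apply_overrides(cur, val, f"{path}{key}.")
            else:
                if isinstance(cur, tuple) and isinstance(val, list):
                    val = tuple(val)
                setattr(obj, key, val)
        return obj
    if isinstance(obj, dict):
        for key, val in overrides.items():
            if key not in obj:
                raise ConfigError(f"unknown key '{path}{key}'")
            cur = obj[key]
            if isinstance(val, dict) and (is_dataclass(cur) or isinstance(cur, dict)):
                _apply_overrides(cur, val, f"{path}{key}.")
            else:
                obj[key] = val
        return obj
    raise ConfigError(f"cannot override scalar at '{path[:-1]}' with a mapping")


def load_config(path: str | Path) -> ModelParameters:
    """Load a YAML config as overrides on top of :func:`default_base_case`.

    Unknown keys raise :class:`ConfigError` naming the offending key path;
    an empty file returns the default base case unchanged.  The returned
    set is validated; any violation raises :class:`ConfigError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    p = default_base_case()
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _apply_overrides(p, raw, "")
    problems = validate_parameters(p)
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))
    return p


def params_from_dict(d: dict) -> ModelParameters:
    """Rebuild a parameter set from :func:`params_to_dict` output."""
    p = default_base_case()
    _apply_overrides(p, copy.deepcopy(d), "")
    return p


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _prob(x: float) -> bool:
    return 0.0 <= x <= 1.0


def validate_parameters(p: ModelParameters) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    v: list[str] = []
    d = p.demography
    if not _prob(d.male_fraction):
        v.append("demography.male_fraction: must be in [0,1]")
    if not d.mean_age > 18:
        v.append("demography.mean_age: must exceed 18 (adult cohort)")
    if not d.mean_weight_kg > 0:
        v.append("demography.mean_weight_kg: must be positive")

    for name in TREATMENTS:
        if name not in p.treatments:
            v.append(f"treatments.{name}: missing profile")
            continue
        t = p.treatments[name]
        if t.dosing_mode not in ("fixed_daily_mg", "weight_based_weekly_mg_per_kg"):
            v.append(f"treatments.{name}.dosing_mode: unknown mode '{t.dosing_mode}'")
        for fld in ("dose", "pack_price", "pack_content_mg",
                    "admin_cost_per_administration", "relative_dose_intensity"):
            if getattr(t, fld) < 0:
                v.append(f"treatments.{name}.{fld}: must be >= 0")
        for fld in ("home_admin_fraction_first_cycle", "home_admin_fraction_later_cycles"):
            if not _prob(getattr(t, fld)):
                v.append(f"treatments.{name}.{fld}: must be in [0,1]")

    for name in TREATMENTS:
        if name not in p.response:
            v.append(f"response.{name}: missing response model")
            continue
        r = p.response[name]
        if not _prob(r.response_probability):
            v.append(f"response.{name}.response_probability: must be in [0,1]")
        if r.time_to_response_cycles > r.non_response_window_cycles:
            v.append(f"response.{name}: time_to_response_cycles exceeds the "
                     "non-response window")
        if r.mean_response_duration_cycles < 1:
            v.append(f"response.{name}.mean_response_duration_cycles: must be >= 1")
        if r.duration_mode not in ("geometric", "fixed"):
            v.append(f"response.{name}.duration_mode: unknown mode '{r.duration_mode}'")

    b = p.bleeds
    for status in PLATELET_STATUSES:
        probs = b.probabilities[status]
        for cat in BLEED_CATEGORIES:
            if not _prob(probs[cat]):
                v.append(f"bleeds.probabilities.{status}.{cat}: must be in [0,1]")
        if sum(probs.values()) > 1.0 + 1e-9:
            v.append(f"bleeds.probabilities.{status}: categories sum above 1")
        dist = b.inpatient_type_distribution(status)
        if abs(sum(dist.values()) - 1.0) > 1e-9 and b.probabilities[status]["inpatient"] > 0:
            v.append(f"bleeds.inpatient_type_distribution.{status}: does not normalize to 1")
    for cat in BLEED_CATEGORIES:
        if b.probabilities[PLATELET_LT50][cat] < b.probabilities[PLATELET_GE50][cat]:
            v.append(f"bleeds.probabilities: {cat} risk for <50 status below >=50 status")
    for t, cf in b.case_fatality.items():
        if not _prob(cf):
            v.append(f"bleeds.case_fatality.{t}: must be in [0,1]")

    c = p.costs
    if c.bleed_tariff_variant not in c.bleed_tariffs:
        v.append(f"costs.bleed_tariff_variant: unknown variant '{c.bleed_tariff_variant}'")
    for variant, tariffs in c.bleed_tariffs.items():
        for kind, gbp in tariffs.items():
            if gbp < 0:
                v.append(f"costs.bleed_tariffs.{variant}.{kind}: must be >= 0")
        if tariffs.get("minor", 0.0) != 0.0:
            v.append(f"costs.bleed_tariffs.{variant}.minor: minor bleeds are costless")
    for kind, gbp in c.inpatient_hcru_extra.items():
        if gbp < 0:
            v.append(f"costs.inpatient_hcru_extra.{kind}: must be >= 0")
    for kind, gbp in c.follow_up.items():
        if gbp < 0:
            v.append(f"costs.follow_up.{kind}: must be >= 0")

    u = p.utilities
    for status in PLATELET_STATUSES:
        for cat, util in u.state_utility[status].items():
            if not (-0.1 <= util <= 1.0):
                v.append(f"utilities.state_utility.{status}.{cat}: outside [-0.1, 1]")
    for t, util in u.inpatient_utility.items():
        if not (-0.1 <= util <= 1.0):
            v.append(f"utilities.inpatient_utility.{t}: outside [-0.1, 1]")
    if (u.state_utility[PLATELET_GE50]["no_bleed"]
            < u.state_utility[PLATELET_LT50]["no_bleed"]):
        v.append("utilities.state_utility: no-bleed utility for >=50 below <50")

    care = p.care
    for state, frac in care.concomitant_fraction.items():
        if not _prob(frac):
            v.append(f"care.concomitant_fraction.{state}: must be in [0,1]")
    for status, frac in care.rescue_fraction.items():
        if not _prob(frac):
            v.append(f"care.rescue_fraction.{status}: must be in [0,1]")
    ap = care.appendix
    for fld in ("concomitant_cost_per_cycle", "rescue_acquisition_cost_per_use",
                "rescue_administration_cost_per_use", "trae_cost_per_event",
                "subsequent_line_cost_per_cycle"):
        if getattr(ap, fld) < 0:
            v.append(f"care.appendix.{fld}: must be >= 0")
    if not _prob(ap.trae_incidence_per_cycle_on_treatment):
        v.append("care.appendix.trae_incidence_per_cycle_on_treatment: must be in [0,1]")

    s = p.settings
    if not (0.0 <= s.annual_discount_rate < 1.0):
        v.append("settings.annual_discount_rate: must be in [0,1)")
    if not s.max_age > p.demography.mean_age:
        v.append("settings.max_age: must exceed the cohort mean age")
    if s.cycle_length_days <= 0:
        v.append("settings.cycle_length_days: must be positive")

    return v


# ---------------------------------------------------------------------------
# Dot-path access (used by the uncertainty analyses and tests)
# ---------------------------------------------------------------------------


def get_path(p: ModelParameters, path: str) -> Any:
    obj: Any = p
    for part in path.split("."):
        try:
            if is_dataclass(obj) and not isinstance(obj, type):
                obj = getattr(obj, part)
            elif isinstance(obj, dict):
                obj = obj[part]
            elif isinstance(obj, (list, tuple)):
                obj = obj[int(part)]
            else:
                raise KeyError(path)
        except (AttributeError, IndexError, ValueError) as exc:
            raise KeyError(path) from exc
    return obj


def set_path(p: ModelParameters, path: str, value: Any) -> None:
    parts = path.split(".")
    obj = get_path(p, ".".join(parts[:-1])) if len(parts) > 1 else p
    last = parts[-1]
    if is_dataclass(obj) and not isinstance(obj, type):
        if not hasattr(obj, last):
            raise KeyError(path)
        setattr(obj, last, value)
    elif isinstance(obj, dict):
        if last not in obj:
            raise KeyError(path)
        obj[last] = value
    elif isinstance(obj, list):
        obj[int(last)] = value
    else:
        raise KeyError(path)


def iter_scalar_paths(p: ModelParameters, prefix: str = "") -> Iterator[tuple[str, Any]]:
    """Yield (dot-path, value) for every numeric leaf of the parameter tree."""
    def walk(obj: Any, path: str) -> Iterator[tuple[str, Any]]:
        if is_dataclass(obj) and not isinstance(obj, type):
            for f in fields(obj):
                yield from walk(getattr(obj, f.name), f"{path}{f.name}.")
        elif isinstance(obj, dict):
            for k, val in obj.items():
                yield from walk(val, f"{path}{k}.")
        elif isinstance(obj, (int, float)) and not isinstance(obj, bool):
            yield path[:-1], obj
    yield from walk(p, prefix)
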
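"""Costs and quality-adjusted survival attached to a cohort trace.

Per cycle the model accrues: drug acquisition and administration for the
active TPO-RA (and, in the subsequent-lines scenario, later treatment
lines), rescue-therapy and concomitant-medication costs, monthly
monitoring (haematologist consultation + full blood count + biochemistry),
bleeding-event management costs (tariff plus an inpatient resource-use
uplift), life-years and bleed-weighted utility.  Everything is discounted
per cycle at the annual rate; undiscounted twins are retained.

No half-cycle correction is applied: each cycle's payoff uses the
end-of-cycle occupancy discounted at the end-of-cycle time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_engine import Trace
from .parameters import (
    INPATIENT_TYPES,
    Demography,
    ModelParameters,
    TreatmentProfile,
)

# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class CostBreakdown:
    """Lifetime GBP totals by category (mirrors the published breakdown)."""

    active_acquisition: float = 0.0
    rescue_acquisition: float = 0.0
    concomitant_acquisition: float = 0.0
    active_administration: float = 0.0
    rescue_administration: float = 0.0
    concomitant_administration: float = 0.0
    monitoring: float = 0.0
    outpatient_bleed: float = 0.0
    intracranial: float = 0.0
    gastrointestinal: float = 0.0
    other_inpatient: float = 0.0
    minor_bleed: float = 0.0
    trae_management: float = 0.0

    def components(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def total(self) -> float:
        return sum(self.components().values())

    @property
    def bleeding_total(self) -> float:
        return (self.outpatient_bleed + self.intracranial
                + self.gastrointestinal + self.other_inpatient
                + self.minor_bleed)

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(**{k: v + other.components()[k]
                                for k, v in self.components().items()})

    def scaled(self, factor: float) -> "CostBreakdown":
        return CostBreakdown(**{k: v * factor for k, v in self.components().items()})


@dataclass
class CEOutcome:
    """Discounted totals for one treatment, with undiscounted twins."""

    treatment: str
    total_qalys: float
    total_lys: float
    costs: CostBreakdown
    undiscounted_qalys: float
    undiscounted_lys: float
    undiscounted_costs: CostBreakdown
    annual_discount_rate: float = 0.035

    @property
    def total_cost(self) -> float:
        return self.costs.total


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def discount_factor(cycle_index: int, annual_rate: float,
                    cycle_length_days: float = 28.0) -> float:
    """(1+r)^(-t) with t the end-of-cycle time in years."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    years = cycle_index * cycle_length_days / 365.25
    return float((1.0 + annual_rate) ** (-years))


def treatment_cost_cycle(treatment: TreatmentProfile, cycle_index: int,
                         on_treatment_fraction: float, demog: Demography,
                         cycle_length_days: float = 28.0) -> tuple[float, float]:
    """(acquisition, administration) GBP for one cycle of one TPO-RA.

    Fixed daily dosing: days x dose x unit price.  Weight-based weekly
    dosing: weekly mg from mean weight, billed fractionally per mg or
    rounded up to whole billing units under ``vial_wastage``.
    Administration cost applies to the clinic-administered fraction
    (home administration is free) and is nonzero only for drugs with a
    positive per-administration cost.
    """
    weeks = cycle_length_days / 7.0
    price_per_mg = treatment.pack_price / treatment.pack_content_mg
    dose = treatment.dose * treatment.relative_dose_intensity
    if treatment.dosing_mode == "fixed_daily_mg":
        acquisition = cycle_length_days * dose * price_per_mg
        administrations = 0.0
    elif treatment.dosing_mode == "weight_based_weekly_mg_per_kg":
        weekly_mg = dose * demog.mean_weight_kg
        if treatment.vial_wastage:
            units = np.ceil(weekly_mg / treatment.pack_content_mg)
            weekly_cost = units * treatment.pack_price
        else:
            weekly_cost = weekly_mg * price_per_mg
        acquisition = weeks * weekly_cost
        administrations = weeks
    else:
        raise ValueError(f"unknown dosing mode '{treatment.dosing_mode}'")
    home = (treatment.home_admin_fraction_first_cycle if cycle_index <= 1
            else treatment.home_admin_fraction_later_cycles)
    administration = (administrations * treatment.admin_cost_per_administration
                      * (1.0 - home))
    return (acquisition * on_treatment_fraction,
            administration * on_treatment_fraction)


def event_cost_cycle(row: pd.Series | dict, p: ModelParameters) -> CostBreakdown:
    """Undiscounted non-drug costs for one trace row.

    Bleeding costs weight the expected event fractions by the configured
    tariff variant (inpatient admissions additionally carry the
    resource-use uplift); rescue and concomitant costs use the appendix
    placeholder unit costs; monitoring covers all alive patients at the
    configured monthly visit schedule.
    """
    tariff = p.costs.tariff()
    ap = p.care.appendix
    out = CostBreakdown()
    out.outpatient_bleed = row["outpatient_bleed"] * tariff["outpatient"]
    out.minor_bleed = row["minor_bleed"] * tariff["minor"]
    inpatient_fields = {"intracranial": "intracranial",
                        "gastrointestinal": "gastrointestinal",
                        "other": "other_inpatient"}
    for t in INPATIENT_TYPES:
        cost_per_admission = tariff[t] + p.costs.inpatient_hcru_extra[t]
        setattr(out, inpatient_fields[t],
                row[f"inpatient_{t}"] * cost_per_admission)
    out.rescue_acquisition = row["rescue_use"] * ap.rescue_acquisition_cost_per_use
    out.rescue_administration = row["rescue_use"] * ap.rescue_administration_cost_per_use
    out.concomitant_acquisition = (row["concomitant_use"]
                                   * ap.concomitant_cost_per_cycle)
    monitored = row["alive"] if p.settings.monitoring_off_treatment else row["on_treatment"]
    out.monitoring = (monitored * p.costs.follow_up_per_visit()
                      * p.costs.monitoring_visits_per_year * p.settings.cycle_years)
    out.trae_management = (row["on_treatment"]
                           * ap.trae_incidence_per_cycle_on_treatment
                           * ap.trae_cost_per_event)
    return out


def utility_cycle(row: pd.Series | dict, p: ModelParameters) -> float:
    """Undiscounted QALY increment for one trace row.

    Each platelet status contributes occupancy x cycle-years x a
    bleed-weighted utility: outpatient-bleed fractions take the outpatient
    utility, inpatient fractions the type-specific utilities, the
    remainder (including minor bleeds) the no-bleed utility.  Expected
    disutility decrements for TPO-RA adverse events, rescue episodes and
    concomitant medication are subtracted.
    """
    u = p.utilities
    b = p.bleeds
    ap = p.care.appendix
    cy = p.settings.cycle_years
    qaly = 0.0
    for status, occ_col in (("ge50", "ge50"), ("lt50", "lt50")):
        occ = row[occ_col]
        if occ == 0.0:
            continue
        probs = b.probabilities[status]
        dist = b.inpatient_type_distribution(status)
        u_inpatient = sum(dist[t] * u.inpatient_utility[t] for t in dist)
        p_out, p_inp = probs["outpatient"], probs["inpatient"]
        mean_u = (p_out * u.state_utility[status]["outpatient"]
                  + p_inp * u_inpatient
                  + (1.0 - p_out - p_inp) * u.state_utility[status]["no_bleed"])
        qaly += occ * mean_u * cy
    # refractory patients' doubled inpatient risk is reflected in costs and
    # mortality; their utility keeps the status-level bleed weighting
    decrement = (row["on_treatment"] * ap.trae_incidence_per_cycle_on_treatment
                 * u.tpora_trae_disutility * ap.trae_duration_fraction_of_cycle
                 + row["rescue_use"] * u.appendix_disutilities["rescue_therapy"]
                 + row["concomitant_use"] * u.appendix_disutilities["concomitant_medication"])
    return qaly - decrement * cy


def accumulate_outcomes(trace: Trace, p: ModelParameters,
                        treatment: str | None = None) -> CEOutcome:
    """Sum discounted per-cycle cost and QALY increments over the horizon."""
    treatment = treatment or trace.treatment
    profile = p.treatments[treatment]
    rate = p.settings.annual_discount_rate
    cdays = p.settings.cycle_length_days
    cy = p.settings.cycle_years
    ap = p.care.appendix

    disc_costs = CostBreakdown()
    undisc_costs = CostBreakdown()
    qalys = lys = u_qalys = u_lys = 0.0

    frame = trace.frame
    for i in range(1, len(frame)):
        row = frame.iloc[i]
        c = int(row["cycle"])
        d = discount_factor(c, rate, cdays)
        acq, admin = treatment_cost_cycle(profile, c, row["on_treatment"],
                                          p.demography, cdays)
        inc = event_cost_cycle(row, p)
        inc.active_acquisition = acq
        inc.active_administration = admin
        if "line_on_treatment" in row.index and row["line_on_treatment"] > 0:
            inc.active_acquisition += (row["line_on_treatment"]
                                       * ap.subsequent_line_cost_per_cycle)
        undisc_costs = undisc_costs + inc
        disc_costs = disc_costs + inc.scaled(d)
        q = utility_cycle(row, p)
        ly = row["alive"] * cy
        qalys += d * q
        lys += d * ly
        u_qalys += q
        u_lys += ly

    return CEOutcome(treatment=treatment, total_qalys=qalys, total_lys=lys,
                     costs=disc_costs, undiscounted_qalys=u_qalys,
                     undiscounted_lys=u_lys, undiscounted_costs=undisc_costs,
                     annual_discount_rate=rate)


def outcome_for(p: ModelParameters, treatment: str,
                table=None) -> CEOutcome:
    """Convenience: run the cohort and accumulate outcomes."""
    from .cohort_engine import run_cohort
    return accumulate_outcomes(run_cohort(p, treatment, table), p, treatment)


def breakdown_frame(outcomes: dict[str, CEOutcome]) -> pd.DataFrame:
    """Cost-breakdown table (one column per treatment), discounted GBP."""
    rows = {}
    for name, oc in outcomes.items():
        c = oc.costs
        rows[name] = {
            "total": c.total,
            "treatment_acquisition": (c.active_acquisition + c.rescue_acquisition
                                      + c.concomitant_acquisition),
            "active_treatment": c.active_acquisition,
            "rescue_therapy": c.rescue_acquisition,
            "concomitant_itp_medication": c.concomitant_acquisition,
            "treatment_administration": (c.active_administration
                                         + c.rescue_administration
                                         + c.concomitant_administration),
            "active_treatment_administration": c.active_administration,
            "rescue_therapy_administration": c.rescue_administration,
            "concomitant_administration": c.concomitant_administration,
            "monitoring": c.monitoring,
            "bleeding": c.bleeding_total,
            "minor_bleed": c.minor_bleed,
            "outpatient_bleed": c.outpatient_bleed,
            "inpatient_bleed": (c.intracranial + c.gastrointestinal
                                + c.other_inpatient),
            "intracranial_haemorrhage": c.intracranial,
            "gastrointestinal_bleed": c.gastrointestinal,
            "other_inpatient_bleed": c.other_inpatient,
            "trae_management": c.trae_management,
        }
    return pd.DataFrame(rows)
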
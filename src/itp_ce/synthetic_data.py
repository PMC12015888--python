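"""Synthetic stand-ins for every non-published input the model needs.

Three generators live here: a Gompertz-Makeham life table emulating 2019
UK national mortality (the model normally consumes an official life
table, supplied as a two- or three-column delimited file); the calibrated
appendix placeholder set (concomitant / rescue / adverse-event inputs the
source analysis keeps in an unpublished appendix); and a tiny
hand-computed cohort trace used as an exact oracle for the engine.
"""

from __future__ import annotations

import numpy as np

from .cohort_engine import MortalityTable
from .parameters import (
    AppendixPlaceholders,
    LifeTableSpec,
    ModelParameters,
    default_base_case,
)

# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------


def synthetic_life_table(spec: LifeTableSpec | None = None) -> MortalityTable:
    """Annual death probabilities q(a) = 1 - exp(-(A + B*exp(C*a))) per sex.

    The default parameters are calibrated so period life expectancy and
    the q(45)/q(65)/q(85) magnitudes are close to the 2019 UK national
    life tables (e0 ~ 80.4 male / 82.7 female).
    """
    spec = spec or LifeTableSpec()
    ages = np.arange(0, spec.max_age + 1)
    cols = {}
    for sex, (a, b, c) in (("male", spec.male), ("female", spec.female)):
        hazard = a + b * np.exp(c * ages)
        cols[sex] = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
    return MortalityTable(ages=ages, q_male=cols["male"], q_female=cols["female"])


def constant_hazard_life_table(per_cycle_prob: float,
                               cycle_length_days: float = 28.0,
                               max_age: int = 120) -> MortalityTable:
    """Flat life table whose per-cycle death probability is exactly the
    given value after annual->cycle conversion (testing aid)."""
    annual = 1.0 - (1.0 - per_cycle_prob) ** (365.25 / cycle_length_days)
    ages = np.arange(0, max_age + 1)
    q = np.full_like(ages, annual, dtype=float)
    return MortalityTable(ages=ages, q_male=q, q_female=q)


def zero_mortality_life_table(max_age: int = 120) -> MortalityTable:
    ages = np.arange(0, max_age + 1)
    zeros = np.zeros_like(ages, dtype=float)
    return MortalityTable(ages=ages, q_male=zeros, q_female=zeros)


# ---------------------------------------------------------------------------
# Appendix placeholders
# ---------------------------------------------------------------------------


def placeholder_appendix_parameters(seed: int = 0,
                                    zero: bool = False) -> AppendixPlaceholders:
    """The calibrated appendix placeholder set.

    The defaults are fixed calibrated values (deterministic for every
    seed); ``zero=True`` returns an all-zero variant so rescue,
    concomitant and adverse-event contributions vanish exactly.  The
    calibration targets order-of-magnitude agreement of lifetime category
    subtotals with the published cost breakdown; it is not a derivation.
    """
    del seed  # the calibrated set carries no sampling variability
    if zero:
        return AppendixPlaceholders(
            concomitant_cost_per_cycle=0.0,
            rescue_acquisition_cost_per_use=0.0,
            rescue_administration_cost_per_use=0.0,
            trae_incidence_per_cycle_on_treatment=0.0,
            trae_cost_per_event=0.0,
            subsequent_line_cost_per_cycle=0.0)
    return AppendixPlaceholders()


# ---------------------------------------------------------------------------
# Hand-computed engine oracle
# ---------------------------------------------------------------------------


def reference_hand_trace() -> tuple[ModelParameters, MortalityTable, list[dict]]:
    """Tiny parameter set plus its cycle-by-cycle occupancy, computed by hand.

    Round-number hazards: per-cycle death 0.1 in every state (bleed
    mortality switched off), response probability 0.5 realized at cycle 1,
    non-response window 2 cycles, geometric response loss with mean
    duration 2 cycles (hazard 0.5), 3 cycles simulated.

    Hand arithmetic (death -> loss of pre-existing response -> realization
    -> window expiry):

    cycle 1: survivors 0.9 in no_response; 0.5 respond
             -> response .45, no_response .45, dead .10
    cycle 2: deaths: response .405, no_response .405, dead .19
             loss: .405 x 0.5 = .2025 -> no_active
             window closes: remaining no_response .405 -> no_active
             -> response .2025, no_active .6075, dead .19
    cycle 3: deaths: response .18225, no_active .54675, dead .271
             loss: .091125 -> no_active
             -> response .091125, no_active .637875, dead .271
    """
    p = default_base_case()
    for r in p.response.values():
        r.response_probability = 0.5
        r.time_to_response_cycles = 1
        r.non_response_window_cycles = 2
        r.mean_response_duration_cycles = 2.0
    for cf in p.bleeds.case_fatality:
        p.bleeds.case_fatality[cf] = 0.0
    p.settings.max_age = p.demography.mean_age + 3 * p.settings.cycle_years
    table = constant_hazard_life_table(0.1, p.settings.cycle_length_days)
    expected = [
        {"cycle": 0, "response": 0.0, "no_response": 1.0,
         "no_active_treatment": 0.0, "dead": 0.0},
        {"cycle": 1, "response": 0.45, "no_response": 0.45,
         "no_active_treatment": 0.0, "dead": 0.10},
        {"cycle": 2, "response": 0.2025, "no_response": 0.0,
         "no_active_treatment": 0.6075, "dead": 0.19},
        {"cycle": 3, "response": 0.091125, "no_response": 0.0,
         "no_active_treatment": 0.637875, "dead": 0.271},
    ]
    return p, table, expected
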
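"""Cohort Markov engine: per-cycle occupancy of the model health states.

A treated cohort enters in 'No response' at the mean cohort age and moves
between four health states ('Response', 'No response', 'No active
treatment', 'Death') in 4-week cycles until the lifetime horizon (a
maximum-age proxy).  Mortality blends background (life-table) death with
ITP bleed case fatality; platelet status is >=50e9/L in response states
and <50e9/L everywhere else.

Within a cycle events apply in a fixed order: (1) death, (2) response-loss
for patients already in response, (3) response realization, (4) window
expiry.  Response loss precedes realization so that newly realized
responders start the geometric response-duration clock on their next
cycle; with a mean duration of D cycles the expected number of cycles
spent in response is then exactly D.

The optional subsequent-lines structure (a scenario analysis) lets
patients failing the TPO-RA receive up to three further treatment lines,
modelled as tunnel states replicating the response logic with placeholder
parameters; patients refractory to every line carry an inpatient-bleed
multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import (
    PLATELET_GE50,
    PLATELET_LT50,
    ModelParameters,
)

# ---------------------------------------------------------------------------
# Mortality table
# ---------------------------------------------------------------------------


@dataclass
class MortalityTable:
    """Annual death probability by integer age, per sex.

    A single blended table can be represented by passing the same array for
    both sexes.
    """

    ages: np.ndarray
    q_male: np.ndarray
    q_female: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.q_male = np.asarray(self.q_male, dtype=float)
        self.q_female = np.asarray(self.q_female, dtype=float)
        if not (len(self.ages) == len(self.q_male) == len(self.q_female)):
            raise ValueError("age and probability columns differ in length")
        for q in (self.q_male, self.q_female):
            if np.any((q < 0) | (q > 1)):
                raise ValueError("annual death probabilities must lie in [0,1]")

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_q(self, age: float, male_fraction: float) -> float:
        """Sex-blended annual death probability at floor(age)."""
        ia = int(np.floor(age))
        if ia < self.ages[0] or ia > self.max_age:
            raise ValueError(f"age {age} outside life-table range "
                             f"[{self.ages[0]}, {self.max_age}]")
        i = ia - int(self.ages[0])
        return (male_fraction * float(self.q_male[i])
                + (1.0 - male_fraction) * float(self.q_female[i]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q_male": self.q_male,
                             "q_female": self.q_female})

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_file(cls, path: str | Path) -> "MortalityTable":
        """Read a delimited life table: either two columns (age, q — blended)
        or three (age, q_male, q_female)."""
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] == 2:
            age, q = df.iloc[:, 0], df.iloc[:, 1]
            return cls(age.to_numpy(), q.to_numpy(), q.to_numpy())
        if df.shape[1] >= 3:
            return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                       df.iloc[:, 2].to_numpy())
        raise ValueError("life table needs at least two columns")


# ---------------------------------------------------------------------------
# Elementary rate conversions
# ---------------------------------------------------------------------------


def annual_to_cycle_prob(annual_p: float, cycle_length_days: float) -> float:
    """Convert an annual probability to a per-cycle probability assuming a
    constant hazard within the year: 1 - (1-p)^(days/365.25)."""
    if not 0.0 <= annual_p <= 1.0:
        raise ValueError("annual probability must lie in [0,1]")
    return 1.0 - (1.0 - annual_p) ** (cycle_length_days / 365.25)


def duration_to_hazard(mean_duration_cycles: float) -> float:
    """Constant per-cycle exit probability of a geometric sojourn with the
    given mean: 1/mean."""
    if mean_duration_cycles < 1:
        raise ValueError("mean duration must be at least one cycle")
    return 1.0 / mean_duration_cycles


def background_death_prob(age: float, table: MortalityTable,
                          male_fraction: float,
                          cycle_length_days: float) -> float:
    """Sex-blended per-cycle background death probability at floor(age)."""
    return annual_to_cycle_prob(table.annual_q(age, male_fraction),
                                cycle_length_days)


def itp_bleed_death_prob(status: str, p: ModelParameters,
                         inpatient_multiplier: float = 1.0) -> float:
    """Per-cycle ITP bleed mortality for a platelet status: the inpatient
    bleed probability times the case-fatality expectation over the
    (normalized) inpatient-type distribution."""
    b = p.bleeds
    p_inp = b.probabilities[status]["inpatient"] * inpatient_multiplier
    if p_inp == 0.0:
        return 0.0
    dist = b.inpatient_type_distribution(status)
    return p_inp * sum(dist[t] * b.case_fatality[t] for t in dist)


# ---------------------------------------------------------------------------
# State vector and trace
# ---------------------------------------------------------------------------


@dataclass
class StateVector:
    """Occupancy of the four health states at one cycle boundary."""

    occupancy: dict[str, float]
    cohort_age: float

    def validate(self, tol: float = 1e-9) -> None:
        total = sum(self.occupancy.values())
        if abs(total - 1.0) > tol:
            raise AssertionError(f"occupancy sums to {total}, not 1")
        if min(self.occupancy.values()) < -tol:
            raise AssertionError("negative occupancy")


@dataclass
class Trace:
    """Cycle-by-cycle cohort trajectory with expected event fractions.

    One row per cycle (cycle 0 is the entry state); occupancy columns for
    the four health states plus per-cycle expected fractions of the cohort
    experiencing each bleed category/type, using rescue therapy, using
    concomitant medication, and on active TPO-RA treatment.
    """

    treatment: str
    frame: pd.DataFrame
    extra_states: tuple[str, ...] = field(default=())

    def occupancy(self, state: str) -> np.ndarray:
        return self.frame[state].to_numpy()

    @property
    def n_cycles(self) -> int:
        return len(self.frame) - 1

    def save(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Engine internals
# ---------------------------------------------------------------------------


class _Cohort:
    """Mutable occupancy map over base states plus optional line states."""

    def __init__(self, p: ModelParameters, treatment: str):
        self.p = p
        self.treatment = treatment
        self.lines_enabled = p.settings.enable_subsequent_lines
        ap = p.care.appendix
        self.line_probs = list(ap.subsequent_line_response_probabilities)
        self.line_window = ap.subsequent_line_window_cycles
        self.line_t2r = min(ap.subsequent_line_time_to_response_cycles,
                            self.line_window)
        self.line_hazard = duration_to_hazard(ap.subsequent_line_mean_duration_cycles)
        self.occ: dict[str, float] = {"response": 0.0, "no_response": 1.0,
                                      "no_active_treatment": 0.0, "dead": 0.0}
        if self.lines_enabled:
            for k in range(len(self.line_probs)):
                for j in range(self.line_window):
                    self.occ[f"line{k}_nr{j}"] = 0.0
                self.occ[f"line{k}_resp"] = 0.0
            self.occ["refractory"] = 0.0

    # -- state classification ------------------------------------------------
    def status_of(self, state: str) -> str:
        if state == "response" or state.endswith("_resp"):
            return PLATELET_GE50
        return PLATELET_LT50

    def inpatient_multiplier(self, state: str) -> float:
        if state == "refractory":
            return self.p.care.appendix.refractory_inpatient_bleed_multiplier
        return 1.0

    def alive_states(self) -> list[str]:
        return [s for s in self.occ if s != "dead"]

    # -- destinations --------------------------------------------------------
    def _after_tpora_failure(self) -> str:
        return "line0_nr0" if self.lines_enabled else "no_active_treatment"

    def _after_line_failure(self, k: int) -> str:
        if k + 1 < len(self.line_probs):
            return f"line{k + 1}_nr0"
        return "refractory"

    # -- one cycle -----------------------------------------------------------
    def transition(self, cycle_index: int, q_background: float) -> None:
        p = self.p
        resp = p.response[self.treatment]
        occ = self.occ
        # Mass newly entering a subsequent line this cycle is buffered so it
        # does not advance through that line's tunnel in the same cycle.
        pending: dict[str, float] = {}

        def send(dest: str, mass: float) -> None:
            if dest.startswith("line"):
                pending[dest] = pending.get(dest, 0.0) + mass
            else:
                occ[dest] += mass

        # (1) death: background for everyone alive + bleed fatality by status
        for state in self.alive_states():
            q_bleed = itp_bleed_death_prob(self.status_of(state), p,
                                           self.inpatient_multiplier(state))
            survive = (1.0 - q_background) * (1.0 - q_bleed)
            lost = occ[state] * (1.0 - survive)
            occ[state] -= lost
            occ["dead"] += lost

        # (2) response loss applies to the pre-realization response mass
        if resp.duration_mode == "geometric":
            hazard = duration_to_hazard(resp.mean_response_duration_cycles)
            loss = occ["response"] * hazard
        else:  # fixed duration: hard stop once the mean duration has elapsed
            stop_cycle = resp.time_to_response_cycles + resp.mean_response_duration_cycles
            loss = occ["response"] if cycle_index >= stop_cycle else 0.0
        occ["response"] -= loss
        send(self._after_tpora_failure(), loss)

        # (3) response realization at the time-to-response cycle
        if cycle_index == resp.time_to_response_cycles:
            moved = resp.response_probability * occ["no_response"]
            occ["no_response"] -= moved
            occ["response"] += moved

        # (4) window expiry: remaining non-responders stop TPO-RA treatment
        if cycle_index == resp.non_response_window_cycles:
            send(self._after_tpora_failure(), occ["no_response"])
            occ["no_response"] = 0.0

        if self.lines_enabled:
            self._transition_lines(send)
        for dest, mass in pending.items():
            occ[dest] += mass

    def _transition_lines(self, send) -> None:
        occ = self.occ
        for k, prob in enumerate(self.line_probs):
            # response loss feeds the next line (or terminal no-active state
            # for the last line)
            loss = occ[f"line{k}_resp"] * self.line_hazard
            occ[f"line{k}_resp"] -= loss
            if k + 1 >= len(self.line_probs):
                occ["no_active_treatment"] += loss
            else:
                send(f"line{k + 1}_nr0", loss)
            # advance the non-response tunnel from the deepest stage back
            for j in reversed(range(self.line_window)):
                mass = occ[f"line{k}_nr{j}"]
                if mass == 0.0:
                    continue
                occ[f"line{k}_nr{j}"] = 0.0
                if j + 1 == self.line_t2r:
                    responded = prob * mass
                    occ[f"line{k}_resp"] += responded
                    mass -= responded
                if j + 1 >= self.line_window:
                    dest = self._after_line_failure(k)
                    if dest.startswith("line"):
                        send(dest, mass)
                    else:
                        occ[dest] += mass
                else:
                    occ[f"line{k}_nr{j + 1}"] += mass


def _event_row(cohort: _Cohort, cycle_index: int, window: int) -> dict[str, float]:
    """Expected per-cycle event fractions for the current occupancy."""
    p = cohort.p
    b = p.bleeds
    out: dict[str, float] = {
        "minor_bleed": 0.0, "outpatient_bleed": 0.0,
        "inpatient_intracranial": 0.0, "inpatient_gastrointestinal": 0.0,
        "inpatient_other": 0.0, "rescue_use": 0.0, "concomitant_use": 0.0,
        "ge50": 0.0, "lt50": 0.0, "on_treatment": 0.0, "line_on_treatment": 0.0,
    }
    for state in cohort.alive_states():
        mass = cohort.occ[state]
        if mass == 0.0:
            continue
        status = cohort.status_of(state)
        out[status] += mass
        probs = b.probabilities[status]
        mult = cohort.inpatient_multiplier(state)
        out["minor_bleed"] += mass * probs["minor"]
        out["outpatient_bleed"] += mass * probs["outpatient"]
        dist = b.inpatient_type_distribution(status)
        for t in dist:
            out[f"inpatient_{t}"] += mass * probs["inpatient"] * mult * dist[t]
        out["rescue_use"] += mass * p.care.rescue_fraction[status]
        if state in ("response", "no_response", "no_active_treatment"):
            concom_state = state
        elif state.endswith("_resp"):
            concom_state = "response"
        else:
            concom_state = "no_active_treatment"
        out["concomitant_use"] += mass * p.care.concomitant_fraction[concom_state]
        if state == "response" or (state == "no_response" and cycle_index <= window):
            out["on_treatment"] += mass
        if state.startswith("line"):
            out["line_on_treatment"] += mass
    return out


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def cycle_transition(sv: StateVector, cycle_index: int, p: ModelParameters,
                     treatment: str, table: MortalityTable) -> StateVector:
    """Advance a four-state vector by one cycle (base structure only)."""
    if cycle_index < 1:
        raise ValueError("cycle_index starts at 1")
    cohort = _Cohort(p, treatment)
    cohort.occ.update({s: sv.occupancy.get(s, 0.0) for s in cohort.occ})
    q_bg = background_death_prob(sv.cohort_age, table,
                                 p.demography.male_fraction,
                                 p.settings.cycle_length_days)
    cohort.transition(cycle_index, q_bg)
    out = StateVector(occupancy={s: cohort.occ[s] for s in
                                 ("response", "no_response",
                                  "no_active_treatment", "dead")},
                      cohort_age=sv.cohort_age + p.settings.cycle_years)
    out.validate()
    return out


def run_cohort(p: ModelParameters, treatment: str,
               table: MortalityTable | None = None) -> Trace:
    """Simulate the cohort for one treatment over the lifetime horizon.

    The cohort enters 100% in 'No response' at the mean age and is iterated
    until it reaches ``settings.max_age``.  The returned :class:`Trace` has
    one row per cycle with occupancies, expected event fractions and the
    on-treatment indicator.
    """
    if treatment not in p.response:
        raise KeyError(f"unknown treatment '{treatment}'")
    if table is None:
        from .synthetic_data import synthetic_life_table
        table = synthetic_life_table(p.life_table)
    resp = p.response[treatment]
    window = resp.non_response_window_cycles
    cohort = _Cohort(p, treatment)
    cy = p.settings.cycle_years
    age = p.demography.mean_age

    rows: list[dict[str, float]] = []

    def record(cycle: int, age_now: float) -> None:
        row = {"cycle": float(cycle), "age": age_now}
        for s in ("response", "no_response", "no_active_treatment", "dead"):
            row[s] = cohort.occ[s]
        if cohort.lines_enabled:
            row["line_response"] = sum(v for s, v in cohort.occ.items()
                                       if s.endswith("_resp"))
            row["line_no_response"] = sum(v for s, v in cohort.occ.items()
                                          if "_nr" in s)
            row["refractory"] = cohort.occ["refractory"]
        row["alive"] = 1.0 - cohort.occ["dead"]
        row.update(_event_row(cohort, cycle, window))
        rows.append(row)

    record(0, age)
    cycle = 0
    while age < p.settings.max_age - 1e-12:
        cycle += 1
        q_bg = background_death_prob(age, table, p.demography.male_fraction,
                                     p.settings.cycle_length_days)
        cohort.transition(cycle, q_bg)
        age += cy
        total = sum(cohort.occ.values())
        if abs(total - 1.0) > 1e-9 or min(cohort.occ.values()) < -1e-12:
            raise RuntimeError(f"occupancy invariant violated at cycle {cycle}")
        record(cycle, age)

    extra = tuple(s for s in cohort.occ
                  if s not in ("response", "no_response",
                               "no_active_treatment", "dead"))
    return Trace(treatment=treatment, frame=pd.DataFrame(rows),
                 extra_states=extra)
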
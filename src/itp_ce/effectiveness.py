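"""Derivation machinery for durable-response probabilities.

The model's base case consumes response probabilities directly (they come
from an external Bayesian network meta-analysis anchored on avatrombopag).
This module documents and tests the derivation steps that sit underneath
them: the proportional continuity correction for trial arms with zero
durable responders, placebo adjustment as a risk difference on corrected
proportions, and application of a relative effect (odds ratio) to an
anchor probability.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TrialArmCounts:
    """2x2 durable-response table for one trial: (events, n) per arm."""

    treatment_events: float
    treatment_n: float
    control_events: float
    control_n: float

    def __post_init__(self) -> None:
        for events, n, arm in ((self.treatment_events, self.treatment_n, "treatment"),
                               (self.control_events, self.control_n, "control")):
            if n < 1:
                raise ValueError(f"{arm} arm size must be >= 1")
            if not 0 <= events <= n:
                raise ValueError(f"{arm} events must lie in [0, n]")

    @property
    def has_zero_cell(self) -> bool:
        return 0.0 in (self.treatment_events, self.control_events,
                       self.treatment_n - self.treatment_events,
                       self.control_n - self.control_events)


@dataclass(frozen=True)
class CorrectedCounts:
    """Continuity-corrected table plus the per-arm increments applied."""

    counts: TrialArmCounts
    treatment_increment: float
    control_increment: float

    def proportion(self, arm: str) -> float:
        """Corrected response proportion: (events + inc) / (n + 2*inc)."""
        if arm == "treatment":
            e, n, inc = (self.counts.treatment_events, self.counts.treatment_n,
                         self.treatment_increment)
        elif arm == "control":
            e, n, inc = (self.counts.control_events, self.counts.control_n,
                         self.control_increment)
        else:
            raise ValueError(f"unknown arm '{arm}'")
        return (e + inc) / (n + 2 * inc)


def continuity_correct(counts: TrialArmCounts,
                       total_correction: float = 1.0) -> CorrectedCounts:
    """Apply the arm-size-proportional zero correction.

    When any cell of the 2x2 table is zero, arm *j* receives an increment of
    ``total_correction * n_j / (n_T + n_C)`` added to both its cells (events
    and non-events); tables without zero cells pass through unchanged.  This
    correction weights by arm size and is therefore appropriate for trials
    with unbalanced randomization.
    """
    if total_correction <= 0:
        raise ValueError("total_correction must be positive")
    if not counts.has_zero_cell:
        return CorrectedCounts(counts, 0.0, 0.0)
    total_n = counts.treatment_n + counts.control_n
    return CorrectedCounts(
        counts,
        treatment_increment=total_correction * counts.treatment_n / total_n,
        control_increment=total_correction * counts.control_n / total_n,
    )


def placebo_adjusted_rate(corrected: CorrectedCounts) -> float:
    """Placebo-adjusted response rate: risk difference on corrected
    proportions, floored at zero."""
    diff = corrected.proportion("treatment") - corrected.proportion("control")
    return max(0.0, diff)


def response_probability_from_relative(anchor_probability: float,
                                       odds_ratio: float) -> float:
    """Translate an odds ratio versus the anchor into an absolute probability.

    Returns p with odds(p) = odds(anchor) * odds_ratio; used when a network
    meta-analysis supplies relative effects rather than probabilities.
    """
    if not 0.0 < anchor_probability < 1.0:
        raise ValueError("anchor probability must lie strictly inside (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    odds = anchor_probability / (1.0 - anchor_probability) * odds_ratio
    return odds / (1.0 + odds)
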
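"""Pairwise incremental analysis: ICERs, dominance labels, result tables."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .payoffs import CEOutcome, breakdown_frame

DOMINANT = "dominant"
DOMINATED = "dominated"
EQUIVALENT = "equivalent"


@dataclass
class IncrementalResult:
    """Intervention-minus-comparator increments and their ICER or label.

    ``icer`` is numeric when both increments share a sign (cost per QALY
    gained, or saved per QALY forgone); 'dominant' when the intervention
    gains QALYs and saves money; 'dominated' in the mirror case.
    """

    intervention: str
    comparator: str
    delta_qaly: float
    delta_ly: float
    delta_cost: float
    icer: float | str
    cost_per_ly: float | str


def _ratio_or_label(delta_cost: float, delta_eff: float) -> float | str:
    if delta_eff == 0.0 and delta_cost == 0.0:
        return EQUIVALENT
    if delta_eff == 0.0:
        return DOMINATED if delta_cost > 0 else DOMINANT
    if delta_eff > 0 and delta_cost < 0:
        return DOMINANT
    if delta_eff < 0 and delta_cost > 0:
        return DOMINATED
    return delta_cost / delta_eff


def incremental_compare(intervention: CEOutcome,
                        comparator: CEOutcome) -> IncrementalResult:
    """Compare two outcomes computed under identical settings."""
    if intervention.annual_discount_rate != comparator.annual_discount_rate:
        raise ValueError("outcomes were discounted at different rates")
    dq = intervention.total_qalys - comparator.total_qalys
    dl = intervention.total_lys - comparator.total_lys
    dc = intervention.total_cost - comparator.total_cost
    return IncrementalResult(
        intervention=intervention.treatment, comparator=comparator.treatment,
        delta_qaly=dq, delta_ly=dl, delta_cost=dc,
        icer=_ratio_or_label(dc, dq), cost_per_ly=_ratio_or_label(dc, dl))


def totals_frame(outcomes: dict[str, CEOutcome],
                 reference: str = "avatrombopag") -> pd.DataFrame:
    """Totals-and-increments table versus a named reference treatment.

    Increments are (treatment - reference), matching the published layout
    in which each comparator row carries its increment versus the
    reference arm; ICER magnitudes are computed from unrounded totals.
    """
    if reference not in outcomes:
        raise KeyError(f"reference '{reference}' not among outcomes")
    ref = outcomes[reference]
    rows = []
    for name, oc in outcomes.items():
        row = {"treatment": name,
               "total_qalys": oc.total_qalys,
               "total_lys": oc.total_lys,
               "total_cost": oc.total_cost}
        if name == reference:
            row.update(incremental_qalys=None, incremental_lys=None,
                       incremental_cost=None, icer=None, cost_per_ly=None)
        else:
            inc = incremental_compare(oc, ref)
            row.update(incremental_qalys=inc.delta_qaly,
                       incremental_lys=inc.delta_ly,
                       incremental_cost=inc.delta_cost,
                       icer=inc.icer, cost_per_ly=inc.cost_per_ly)
        rows.append(row)
    return pd.DataFrame(rows).set_index("treatment")


def format_results_tables(outcomes: dict[str, CEOutcome],
                          reference: str = "avatrombopag",
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(totals table, cost-breakdown table) rounded for presentation.

    QALYs/LYs to three decimals, GBP to whole pounds; unrounded values are
    available from :func:`totals_frame` / :func:`payoffs.breakdown_frame`.
    """
    totals = totals_frame(outcomes, reference=reference)
    disp = totals.copy()
    def _blank(x) -> bool:
        return x is None or (isinstance(x, float) and pd.isna(x))

    for col in ("total_qalys", "total_lys", "incremental_qalys", "incremental_lys"):
        disp[col] = disp[col].map(lambda x: None if _blank(x) else round(x, 3))
    for col in ("total_cost", "incremental_cost", "icer", "cost_per_ly"):
        disp[col] = disp[col].map(
            lambda x: x if _blank(x) or isinstance(x, str) else round(x))
    breakdown = breakdown_frame(outcomes).round(0)
    return disp, breakdown
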
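# itp-ce

A cohort Markov cost-effectiveness model of second-line thrombopoietin
receptor agonist (TPO-RA) treatment — **avatrombopag**, **eltrombopag** and
**romiplostim** — for adults with immune thrombocytopenia (ITP), from the
perspective of the UK NHS.

ITP is an autoimmune disease with platelet counts below 100 × 10⁹/L and an
elevated bleeding risk. Adults failing corticosteroids typically move to a
TPO-RA; the three licensed agents have never been compared head-to-head, so
treatment choice leans on indirect comparison of efficacy — and on cost.
This package is for health economists and HTA analysts who want a fully
transparent, config-driven, tested implementation of that comparison:
base-case cost-utility analysis, probabilistic and one-way deterministic
sensitivity analysis, and scenario analyses.

## The model

A cohort enters at mean age 44.6 (36.7% male) in the **'No response'** state
and moves every 4-week cycle between four states — *Response* (platelets
≥ 50 × 10⁹/L), *No response*, *No active treatment* and *Death* — over a
lifetime horizon (to age 100):

- Durable response is realized at 24 weeks (cycle 6) with probability
  **0.73 / 0.27 / 0.55** (avatrombopag / eltrombopag / romiplostim), the
  Bayesian network-meta-analysis estimates the model consumes; patients not
  responding within 28 weeks (7 cycles) stop TPO-RA treatment.
- Response is held for a geometric sojourn with mean **109 cycles**
  (per-cycle exit hazard 1/109), then patients move to *No active treatment*.
- Mortality blends sex-weighted life-table background death with ITP bleed
  case fatality: per cycle, q = 1 − (1 − q_annual)^(28/365.25) plus
  P(inpatient bleed | platelet status) × Σ type-share × case-fatality
  (13.2% intracranial, 4.6% gastrointestinal, 1.7% other).
- Each cycle accrues drug acquisition/administration, rescue therapy,
  concomitant ITP medication, monthly monitoring, bleed-management costs,
  and bleed-weighted utility; everything is discounted at 3.5%/year.
- Strategies are compared by incremental cost-effectiveness ratio
  ICER = ΔC/ΔE, with dominance labels when the signs disagree.

Inputs the source analysis keeps in an unpublished appendix (rescue and
concomitant unit costs, inpatient resource-use uplift, adverse-event
incidences, effective avatrombopag dose intensity) are explicit,
provenance-flagged placeholders — calibrated to the published cost
breakdown, overridable via config, and disclosed at WARN level on every
run. See `docs/methods.md`.

## Worked example

```python
import itp_ce as m

p = m.default_base_case()                      # published Table-1 inputs
table = m.synthetic_life_table(p.life_table)   # UK-2019-like mortality
outcomes = {t: m.outcome_for(p, t, table) for t in m.TREATMENTS}
totals, breakdown = m.format_results_tables(outcomes)
print(totals[["total_qalys", "total_cost", "incremental_cost", "icer"]])
```

prints

```
              total_qalys  total_cost incremental_cost       icer
treatment
avatrombopag       10.932      315212             None       None
eltrombopag         9.935      308889          -6323.0       6340
romiplostim        10.542      393501          78289.0  dominated
```

Read: avatrombopag yields the most QALYs (10.932 discounted). Eltrombopag
is £6,323 cheaper but loses 0.997 QALYs, so moving from eltrombopag to
avatrombopag costs **£6,340 per QALY gained** — far below the usual
£20,000/QALY threshold. Romiplostim costs £78,289 more *and* yields fewer
QALYs, so it is dominated by avatrombopag.

The same analyses are available from the shell:

```sh
itp-ce base                       # totals + cost breakdown tables
itp-ce psa --iterations 1000 --seed 1
itp-ce dsa --bound 0.2            # one-way tornado table
itp-ce scenario --name standard_tariff
itp-ce validate --config my_overrides.yaml
```

Every output directory includes a `manifest.json` sufficient to reproduce
the run; deterministic modes are bit-reproducible.

## Layout

| module | contents |
| --- | --- |
| `itp_ce.parameters` | input dataclasses, defaults, YAML config, validation, provenance flags |
| `itp_ce.effectiveness` | zero-event continuity correction, placebo adjustment, odds-ratio translation |
| `itp_ce.cohort_engine` | life tables, per-cycle transitions, lifetime traces |
| `itp_ce.payoffs` | costing, utilities, discounting, outcome accumulation |
| `itp_ce.outcomes` | incremental comparison, dominance, result tables |
| `itp_ce.uncertainty` | PSA + CEAC, one-way DSA + tornado, five scenarios |
| `itp_ce.synthetic_data` | synthetic life table, appendix placeholders, hand-trace oracle |
| `itp_ce.cli` | `itp-ce` command-line interface |
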
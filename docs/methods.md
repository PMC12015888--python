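# Methods

## Model structure

The model is a cohort (expected-value) Markov state-transition model with
an embedded response decision, 4-week (28-day) cycles and a lifetime
horizon approximated as simulation to age 100. A closed cohort enters in
*No response* at the mean trial age (44.6 years; 36.7% male) and occupies
four health states: *Response* (platelet count ≥ 50 × 10⁹/L), *No
response*, *No active treatment* and *Death*. Platelet status is binary
and tied to state: ≥ 50 in *Response*, < 50 everywhere else. There is no
individual-level simulation; all quantities are cohort expectations.

Within a cycle, events apply in a fixed order:

1. **Death** — background mortality (life table, sex-blended by the male
   fraction, annual probability at floor(age) converted to the cycle with
   1 − (1 − q)^(28/365.25)) combined multiplicatively with ITP bleed
   mortality, P(inpatient bleed | status) × Σ type-share × case fatality.
2. **Loss of response** — patients already in *Response* exit to *No
   active treatment* with the constant hazard 1/109 per cycle (geometric
   sojourn with mean 109 cycles, the standard Markov embedding of a mean
   duration). A `duration_mode: fixed` switch replaces the hazard with a
   hard stop once the mean duration has elapsed.
3. **Response realization** — at cycle 6 (24 weeks) the treatment's
   response probability moves that fraction of surviving non-responders to
   *Response*. Realization is a point event; before it, would-be
   responders carry < 50 status.
4. **Window expiry** — at cycle 7 (28 weeks) all remaining non-responders
   move to *No active treatment*, which is terminal among alive states
   (no re-treatment) outside the subsequent-lines scenario.

Loss (step 2) deliberately precedes realization (step 3): newly realized
responders start the duration clock the next cycle, which makes the
expected number of cycles spent in response exactly equal the configured
mean (the test suite recovers 109 ± 1% from the trace). The ordering of
death before the treatment-pathway events is a convention; alternatives
differ at O(hazard²).

## Key parameters

| parameter | default | units / note |
| --- | --- | --- |
| response probability | 0.73 / 0.27 / 0.55 | avatrombopag / eltrombopag / romiplostim, Bayesian NMA set; frequentist scenario 0.42 / 0.22 / 0.47 |
| time to response | 6 cycles | 24 weeks |
| non-response window | 7 cycles | 28 weeks; 3 cycles in the 12-week scenario |
| mean response duration | 109 cycles | geometric hazard 1/109 |
| bleed probabilities /cycle | ≥50: 10/7.1/0%; <50: 17.1/45.5/4.3% | minor / outpatient / inpatient |
| inpatient type split | ≥50: 0/29/71; <50: 19/19/63 (renormalized) | intracranial / GI / other |
| case fatality | 13.2 / 4.6 / 1.7% | per inpatient bleed by type |
| utilities | ≥50: 0.801 (no bleed), 0.625 (outpatient); <50: 0.760, 0.584; inpatient 0.038/0.45/0.45 | EQ-5D index values |
| discount rate | 3.5%/year | costs and outcomes, per-cycle compounding, no half-cycle correction |
| drug prices | £1920/30×20 mg; £1540/28×50 mg; £241/0.125 mg | list prices |
| dosing | 20 mg/d; 50 mg/d; 0.004 mg/kg/wk | label / trial doses |
| monitoring | £177.28/visit × 12/year | consultation + FBC + biochemistry, all alive patients |

The printed < 50 inpatient type distribution sums to 1.01 (rounding); it
is stored as printed and renormalized at use, since it is a relative
distribution by definition.

Monitoring accrues monthly (12 visits/year), not once per 28-day cycle
(13.04/year): the published per-arm monitoring subtotals equal discounted
life-years × 12 × £177.28 essentially exactly, which fixes the convention.

## Placeholder (appendix-tier) inputs and their calibration

Several inputs of the source analysis are not published in its main text.
They are modelled as explicit placeholder structures, provenance-flagged
(`itp_ce.parameters.PROVENANCE`, `placeholder_paths()`), logged at WARN
level by the CLI, and overridable via config:

- **Rescue therapy**: £2050 acquisition + £905 administration per rescue
  episode (an IVIg-dominated mix of IVIg, IV corticosteroids and platelet
  transfusion); episodes occur in 3% of ≥50 and 22% of <50 patient-cycles.
- **Concomitant ITP medication**: £154 per treated patient-cycle, taken by
  35.9% of responders and 44.9% of patients in the non-response and
  no-active-treatment states (the published figure names the non-response
  state; applying it to *No active treatment* as well is a flagged,
  configurable reading of "higher in the 'Treatment, no response' and 'No
  active treatment' states").
- **Inpatient resource-use uplift**: £6350 / £4960 / £3220 per intracranial
  / GI / other admission, on top of the bleed tariff — the published
  costing includes ER admission, ward stay, emergency surgery, ambulance,
  imaging and laboratory work beyond the tariff itself.
- **Effective avatrombopag dose intensity**: 0.63 × the 20 mg/day label
  dose (≈ 12.6 mg/day). The label start dose overstates the mean
  maintenance dose actually dispensed (avatrombopag titrates between
  20 mg/week and 40 mg/day); the published lifetime acquisition cost and
  the direction/size of its one-way dose sensitivity are consistent with
  this mean, not with 20 mg/day. Eltrombopag and romiplostim use dose
  intensity 1.0.
- **Adverse events**: 2% per on-treatment cycle incidence of serious
  treatment-related events with the published 0.10 (SE 0.025) disutility
  for one cycle and zero management cost (the published cost breakdown
  carries no adverse-event cost row); small placeholder disutilities for
  rescue episodes (0.05) and concomitant medication (0.02).

Calibration was done once, analytically, against the published lifetime
cost-breakdown subtotals (the discounted state-occupancy algebra was
validated first against four independent breakdown rows), and is held
fixed. It targets order-of-magnitude agreement; it is not a derivation of
the unpublished appendix values, and users holding those values should
override the placeholders.

Romiplostim is billed fractionally per mg by default; a `vial_wastage`
flag instead rounds the weekly weight-based dose up to whole 0.125 mg
units. Fractional billing is the default as the less assumption-laden
choice, although whole-vial billing matches the published romiplostim
acquisition total more closely. Romiplostim administration applies the
stated home-administration split (0% in cycle 1, 72.3% thereafter); the
published administration subtotal is substantially lower than any
convention consistent with that split and the acquisition subtotal, so
the model keeps the stated split and accepts the difference (it only
disfavours romiplostim, which is already dominated).

## Synthetic life table

Background mortality normally comes from a national life table (two- or
three-column delimited file: age, q, optionally per sex). The bundled
generator produces a Gompertz–Makeham table per sex,
q(a) = 1 − exp(−(A + B·e^{C·a})), with defaults calibrated once to 2019 UK
period magnitudes: male (A = 2.0e-4, B = 2.2e-5, C = 0.097; e₀ ≈ 80.4,
e₄₅ ≈ 36.7), female (A = 1.3e-4, B = 1.4e-5, C = 0.1005; e₀ ≈ 82.7,
e₄₅ ≈ 38.6). What it does *not* emulate: cohort (projected) improvements,
accident humps at young-adult ages, and any ITP-specific background
excess. Model results using it therefore demonstrate methodological
correctness and magnitude agreement, not actuarial exactness; analyses for
decision-making should substitute the official table.

## Effectiveness derivation machinery

The base case consumes the NMA response probabilities directly. The
`effectiveness` module documents the steps underneath them: the zero-event
continuity correction adds `total_correction × n_arm / (n_T + n_C)` to
both cells of each arm when any 2×2 cell is zero (arm-size-proportional,
appropriate for unbalanced trials); placebo adjustment is the risk
difference of the corrected proportions (events+inc)/(n+2·inc), floored at
zero; and an odds-ratio pathway maps relative effects onto the anchor
probability. The functional form by which the external NMA maps trial
counts to 0.73/0.27/0.55 is not published, so the package does not claim
to re-derive those numbers from the counts.

## Uncertainty analyses

**PSA** assigns families by support — beta for probabilities, fractions
and utilities (moment-matched from mean and SE), gamma for costs,
lognormal available for relative effects — with the printed SE where one
exists (the 0.10 (0.025) adverse-event disutility) and 20% of the mean
otherwise. Draws are independent across parameters (no correlation
structure is published); relative distributions are renormalized after
sampling and ordering constraints (<50 bleed risk ≥ ≥50; no-bleed utility
ordering) are restored by swapping, so every sampled set passes
validation. Structural counts (cycle length, windows, horizon) are fixed.
Results are bit-reproducible under a fixed seed.

**DSA** varies one parameter at a time by ±20% (clipped to support),
reruns the deterministic model, and reports the ICER and the net monetary
benefit at £20,000/QALY at both bounds. Entries are sorted by NMB range:
ICERs flip representation (number ↔ dominance label) when a delta changes
sign, so NMB gives a stable tornado ordering while the ICERs remain
reported per entry. The eligible-parameter list
(`itp_ce.uncertainty.DSA_PARAMETERS`) is explicit and editable; the source
analysis does not enumerate its own.

**Scenarios**: frequentist response set (0.42/0.22/0.47); standard NHS
bleed tariff; qualitative-study tariff; 12-week response window
(window and time-to-response clipped to 3 cycles); and subsequent
treatment lines — up to three further placeholder-parameterized lines
after TPO-RA failure, implemented as tunnel states replicating the
response logic (3-cycle window, placeholder response probabilities
0.30/0.25/0.20, mean duration 26 cycles, £200/cycle), with a 2× inpatient
bleed multiplier for patients refractory to all lines. In this
implementation the multiplier attaches to patients who exhaust every line
without a response; patients who respond in a later line and then relapse
return to ordinary *No active treatment*.

The published PSA probabilities (63.6% / 93.9% at £20,000/QALY) and the
single published DSA value depend on unpublished distribution choices and
appendix bounds and are not reproduction targets; the package's own PSA
yields higher probabilities under its documented assumptions.

## Numerical conventions and problem sizes

Cycle length 28/365.25 years; discount factor (1.035)^(−t) at end-of-cycle
time; no half-cycle correction; occupancy conservation enforced at 1e-9
per cycle; the lifetime horizon is 723 cycles (age 44.6 → 100), beyond
which remaining survivors (< 0.1% of discounted output) are truncated.
Bleed, rescue and concomitant event expectations are recorded on
end-of-cycle occupancy; bleed mortality uses start-of-cycle status — the
difference is O(hazard²). The acceptance script uses the full 723-cycle
horizon and 500 PSA iterations; structural tests truncate the horizon
(5–20 years) since the properties they check are horizon-independent.

## Known limitations

- Bleed categories are treated as mutually exclusive per cycle with the
  printed marginal probabilities; overlaps and within-cycle recurrence are
  ignored.
- Platelet status is binary; no platelet-count trajectories or dose
  titration dynamics.
- Appendix-tier placeholders make the *absolute* cost totals
  calibration-dependent; incremental conclusions are much less sensitive
  because the placeholder costs apply near-symmetrically across arms.
- No treatment switching between TPO-RAs, no value-of-information
  analysis, no currency-year inflation or confidential-discount modelling.
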
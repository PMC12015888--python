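"""Every published base-case input, addressed by its dot-path in the
parameter tree.  The golden-keys test asserts each is loaded verbatim."""

GOLDEN_KEYS = [
    # demography
    ("demography.mean_age", 44.6),
    ("demography.male_fraction", 0.367),
    ("demography.mean_weight_kg", 82.97),
    ("demography.mean_body_area_m2", 1.94),
    # durable response probabilities (Bayesian base case)
    ("response.avatrombopag.response_probability", 0.73),
    ("response.eltrombopag.response_probability", 0.27),
    ("response.romiplostim.response_probability", 0.55),
    # response timing (24 weeks = 6 cycles; 28-week window = 7 cycles;
    # mean duration of response 109 cycles)
    ("response.avatrombopag.time_to_response_cycles", 6),
    ("response.avatrombopag.non_response_window_cycles", 7),
    ("response.avatrombopag.mean_response_duration_cycles", 109.0),
    # per-cycle bleed probabilities
    ("bleeds.probabilities.ge50.minor", 0.100),
    ("bleeds.probabilities.ge50.outpatient", 0.071),
    ("bleeds.probabilities.ge50.inpatient", 0.000),
    ("bleeds.probabilities.lt50.minor", 0.171),
    ("bleeds.probabilities.lt50.outpatient", 0.455),
    ("bleeds.probabilities.lt50.inpatient", 0.043),
    # inpatient bleed type distribution (as printed, pre-normalization)
    ("bleeds.inpatient_type_distribution_raw.ge50.intracranial", 0.00),
    ("bleeds.inpatient_type_distribution_raw.ge50.gastrointestinal", 0.29),
    ("bleeds.inpatient_type_distribution_raw.ge50.other", 0.71),
    ("bleeds.inpatient_type_distribution_raw.lt50.intracranial", 0.19),
    ("bleeds.inpatient_type_distribution_raw.lt50.gastrointestinal", 0.19),
    ("bleeds.inpatient_type_distribution_raw.lt50.other", 0.63),
    # bleed case fatality
    ("bleeds.case_fatality.intracranial", 0.132),
    ("bleeds.case_fatality.gastrointestinal", 0.046),
    ("bleeds.case_fatality.other", 0.017),
    # bleed management tariffs, three variants
    ("costs.bleed_tariffs.increased_nhs.outpatient", 494.0),
    ("costs.bleed_tariffs.increased_nhs.intracranial", 7044.0),
    ("costs.bleed_tariffs.increased_nhs.gastrointestinal", 5503.0),
    ("costs.bleed_tariffs.increased_nhs.other", 3485.0),
    ("costs.bleed_tariffs.standard_nhs.outpatient", 460.0),
    ("costs.bleed_tariffs.standard_nhs.intracranial", 4691.0),
    ("costs.bleed_tariffs.standard_nhs.gastrointestinal", 3092.0),
    ("costs.bleed_tariffs.standard_nhs.other", 2891.0),
    ("costs.bleed_tariffs.qualitative_study.outpatient", 3134.0),
    ("costs.bleed_tariffs.qualitative_study.intracranial", 25699.0),
    ("costs.bleed_tariffs.qualitative_study.gastrointestinal", 14325.0),
    ("costs.bleed_tariffs.qualitative_study.other", 14325.0),
    # drug acquisition (list prices) and dosing
    ("treatments.avatrombopag.pack_price", 1920.0),
    ("treatments.avatrombopag.pack_content_mg", 600.0),
    ("treatments.avatrombopag.dose", 20.0),
    ("treatments.eltrombopag.pack_price", 1540.0),
    ("treatments.eltrombopag.pack_content_mg", 1400.0),
    ("treatments.eltrombopag.dose", 50.0),
    ("treatments.romiplostim.pack_price", 241.0),
    ("treatments.romiplostim.pack_content_mg", 0.125),
    ("treatments.romiplostim.dose", 0.004),
    ("treatments.romiplostim.admin_cost_per_administration", 241.06),
    ("treatments.romiplostim.home_admin_fraction_first_cycle", 0.0),
    ("treatments.romiplostim.home_admin_fraction_later_cycles", 0.723),
    # follow-up costs
    ("costs.follow_up.haematologist_consultation", 173.39),
    ("costs.follow_up.blood_test", 2.79),
    ("costs.follow_up.biochemistry", 1.10),
    # utilities
    ("utilities.state_utility.ge50.no_bleed", 0.801),
    ("utilities.state_utility.ge50.outpatient", 0.625),
    ("utilities.state_utility.lt50.no_bleed", 0.760),
    ("utilities.state_utility.lt50.outpatient", 0.584),
    ("utilities.inpatient_utility.intracranial", 0.038),
    ("utilities.inpatient_utility.gastrointestinal", 0.45),
    ("utilities.inpatient_utility.other", 0.45),
    ("utilities.tpora_trae_disutility", 0.10),
    ("utilities.tpora_trae_disutility_se", 0.025),
    # care model
    ("care.concomitant_fraction.response", 0.359),
    ("care.concomitant_fraction.no_response", 0.449),
    ("care.rescue_fraction.ge50", 0.03),
    ("care.rescue_fraction.lt50", 0.22),
    # settings
    ("settings.cycle_length_days", 28.0),
    ("settings.annual_discount_rate", 0.035),
]

#: Frequentist indirect-comparison response probabilities (scenario 1).
FREQUENTIST_KEYS = [
    ("avatrombopag", 0.42), ("eltrombopag", 0.22), ("romiplostim", 0.47),
]
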
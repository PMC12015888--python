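"""PSA, CEAC, one-way DSA and the five scenario analyses."""

import numpy as np
import pandas as pd
import pytest

import itp_ce as m
from itp_ce.parameters import get_path
from itp_ce.uncertainty import (
    DistributionSpec,
    PSAResult,
    apply_scenario,
    tornado_frame,
)

from conftest import short_horizon


class TestDistributionAssignment:
    def test_families_respect_support(self, params):
        specs = {s.path: s for s in m.assign_distributions(params)}
        assert specs["response.avatrombopag.response_probability"].family == "beta"
        assert specs["costs.bleed_tariffs.increased_nhs.outpatient"].family == "gamma"
        assert specs["utilities.state_utility.ge50.no_bleed"].family == "beta"

    def test_printed_se_used_for_trae_disutility(self, params):
        specs = {s.path: s for s in m.assign_distributions(params)}
        spec = specs["utilities.tpora_trae_disutility"]
        assert (spec.mean, spec.se) == (0.10, 0.025)

    def test_default_se_is_twenty_percent(self, params):
        specs = {s.path: s for s in m.assign_distributions(params)}
        spec = specs["costs.bleed_tariffs.increased_nhs.outpatient"]
        assert spec.se == pytest.approx(0.2 * 494.0)

    def test_structural_counts_not_sampled(self, params):
        paths = {s.path for s in m.assign_distributions(params)}
        assert not any("cycle_length" in p or "window" in p or "max_age" in p
                       for p in paths)


class TestSampling:
    def test_same_seed_same_draw(self, params):
        specs = m.assign_distributions(params)
        a = m.sample_parameter_set(params, specs, np.random.default_rng(7))
        b = m.sample_parameter_set(params, specs, np.random.default_rng(7))
        assert a == b

    def test_all_fixed_reproduces_base_case(self, params):
        specs = [DistributionSpec(s.path, "fixed", s.mean)
                 for s in m.assign_distributions(params)]
        sampled = m.sample_parameter_set(params, specs, np.random.default_rng(0))
        assert sampled == params

    def test_zero_se_beta_is_degenerate(self):
        spec = DistributionSpec("x", "beta", 0.5, 0.0)
        assert spec.sample(np.random.default_rng(0)) == 0.5

    def test_sampled_sets_are_valid(self, params):
        specs = m.assign_distributions(params)
        rng = np.random.default_rng(123)
        for _ in range(20):
            sampled = m.sample_parameter_set(params, specs, rng)
            assert m.validate_parameters(sampled) == []

    def test_type_distributions_renormalized(self, params):
        specs = m.assign_distributions(params)
        rng = np.random.default_rng(5)
        sampled = m.sample_parameter_set(params, specs, rng)
        for status in ("ge50", "lt50"):
            raw = sampled.bleeds.inpatient_type_distribution_raw[status]
            assert sum(raw.values()) == pytest.approx(1.0, abs=1e-9)

    def test_moment_matching(self):
        rng = np.random.default_rng(42)
        beta = DistributionSpec("x", "beta", 0.3, 0.05)
        gamma = DistributionSpec("y", "gamma", 500.0, 100.0)
        bs = [beta.sample(rng) for _ in range(4000)]
        gs = [gamma.sample(rng) for _ in range(4000)]
        assert np.mean(bs) == pytest.approx(0.3, abs=0.01)
        assert np.std(bs) == pytest.approx(0.05, abs=0.01)
        assert np.mean(gs) == pytest.approx(500.0, rel=0.02)
        assert np.std(gs) == pytest.approx(100.0, rel=0.1)


class TestPSA:
    def _fast(self, params):
        return short_horizon(params, 8.0)

    def test_all_fixed_specs_reproduce_base_deltas(self, params, life_table):
        p = self._fast(params)
        specs = [DistributionSpec(s.path, "fixed", s.mean)
                 for s in m.assign_distributions(p)]
        result = m.run_psa(p, 3, seed=1, table=life_table, specs=specs)
        outcomes = {t: m.outcome_for(p, t, life_table) for t in m.TREATMENTS}
        base = m.incremental_compare(outcomes["avatrombopag"],
                                     outcomes["eltrombopag"])
        elt = result.deltas("eltrombopag")
        np.testing.assert_allclose(elt["delta_qaly"], base.delta_qaly, rtol=1e-12)
        np.testing.assert_allclose(elt["delta_cost"], base.delta_cost, rtol=1e-12)

    def test_seed_reproducibility_bit_identical(self, params, life_table):
        p = self._fast(params)
        a = m.run_psa(p, 4, seed=11, table=life_table)
        b = m.run_psa(p, 4, seed=11, table=life_table)
        pd.testing.assert_frame_equal(a.iterations, b.iterations)

    def test_different_seeds_differ(self, params, life_table):
        p = self._fast(params)
        a = m.run_psa(p, 2, seed=1, table=life_table)
        b = m.run_psa(p, 2, seed=2, table=life_table)
        assert not a.iterations.equals(b.iterations)

    def test_iteration_count_and_columns(self, params, life_table):
        p = self._fast(params)
        result = m.run_psa(p, 5, seed=3, table=life_table)
        assert result.n_iterations == 5
        assert len(result.iterations) == 5 * 2  # two comparators
        assert {"iteration", "comparator", "delta_qaly",
                "delta_cost"} <= set(result.iterations.columns)

    def test_rejects_zero_iterations(self, params):
        with pytest.raises(ValueError):
            m.run_psa(params, 0, seed=1)


class TestCEAC:
    @staticmethod
    def _result(dq, dc):
        frame = pd.DataFrame({"iteration": range(len(dq)),
                              "comparator": "eltrombopag",
                              "delta_qaly": dq, "delta_cost": dc})
        return PSAResult("avatrombopag", frame, seed=0, n_iterations=len(dq))

    def test_all_dominant_gives_one_everywhere(self):
        r = self._result([0.5, 1.0, 0.2], [-100.0, -5.0, -3000.0])
        ceac = m.compute_ceac(r, [0.0, 20000.0, 50000.0])
        assert (ceac["probability_cost_effective"] == 1.0).all()

    def test_all_dominated_gives_zero_everywhere(self):
        r = self._result([-0.5, -1.0], [100.0, 5.0])
        ceac = m.compute_ceac(r, [0.0, 20000.0])
        assert (ceac["probability_cost_effective"] == 0.0).all()

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(99)
        dq = rng.normal(0.1, 0.5, 200)
        dc = rng.normal(1000, 5000, 200)
        r = self._result(dq, dc)
        lam = 20000.0
        ceac = m.compute_ceac(r, [lam])
        count = sum(1 for q, c in zip(dq, dc) if lam * q - c > 0)
        assert ceac["probability_cost_effective"].iloc[0] == count / 200

    def test_exact_zero_nmb_counts_as_not_cost_effective(self):
        r = self._result([1.0], [20000.0])
        ceac = m.compute_ceac(r, [20000.0])
        assert ceac["probability_cost_effective"].iloc[0] == 0.0

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(1)
        r = self._result(rng.normal(0, 1, 50), rng.normal(0, 1e4, 50))
        ceac = m.compute_ceac(r, [0, 1e4, 1e5])
        probs = ceac["probability_cost_effective"]
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_empty_result_rejected(self):
        r = PSAResult("avatrombopag", pd.DataFrame(), 0, 0)
        with pytest.raises(ValueError):
            m.compute_ceac(r, [20000.0])


class TestDSA:
    def test_zero_bound_reproduces_base_case(self, params, life_table):
        p = short_horizon(params, 8.0)
        paths = ("response.avatrombopag.response_probability",
                 "costs.bleed_tariffs.increased_nhs.outpatient")
        entries = m.run_dsa(p, bound_fraction=0.0, parameters=paths,
                            table=life_table)
        assert len(entries) == 2
        for e in entries:
            assert e.low_value == e.high_value == get_path(p, e.parameter)
            assert e.nmb_low == pytest.approx(e.nmb_high, abs=1e-9)

    def test_minor_bleed_cost_entry_is_zero_width(self, params, life_table):
        p = short_horizon(params, 8.0)
        entries = m.run_dsa(p, parameters=("costs.bleed_tariffs.increased_nhs.minor",),
                            table=life_table)
        e = entries[0]
        assert e.low_value == e.high_value == 0.0
        assert e.nmb_range == pytest.approx(0.0, abs=1e-9)

    def test_higher_avatrombopag_dose_worsens_its_icer(self, params, life_table):
        """Raising the avatrombopag dose raises the cost per QALY gained
        versus eltrombopag (its published direction of effect)."""
        p = short_horizon(params, 12.0)
        entries = m.run_dsa(p, parameters=("treatments.avatrombopag.dose",),
                            table=life_table)
        e = entries[0]
        assert e.nmb_high < e.nmb_low
        if isinstance(e.icer_low, float) and isinstance(e.icer_high, float):
            assert e.icer_high > e.icer_low

    def test_probability_bounds_clipped_to_unit_interval(self, params, life_table):
        p = short_horizon(params, 6.0)
        p.response["avatrombopag"].response_probability = 0.9
        entries = m.run_dsa(p, bound_fraction=0.2,
                            parameters=("response.avatrombopag.response_probability",),
                            table=life_table)
        assert entries[0].high_value == 1.0

    def test_sorted_by_nmb_range(self, params, life_table):
        p = short_horizon(params, 8.0)
        entries = m.run_dsa(
            p, parameters=("response.avatrombopag.response_probability",
                           "costs.bleed_tariffs.increased_nhs.minor",
                           "care.appendix.rescue_acquisition_cost_per_use"),
            table=life_table)
        ranges = [e.nmb_range for e in entries]
        assert ranges == sorted(ranges, reverse=True)
        frame = tornado_frame(entries)
        assert list(frame["parameter"]) == [e.parameter for e in entries]


class TestScenarios:
    def test_unknown_scenario_rejected(self, params):
        with pytest.raises(ValueError, match="no_such"):
            apply_scenario(params, "no_such")

    def test_frequentist_response_probabilities(self, params):
        s = apply_scenario(params, "frequentist_response")
        assert s.response["avatrombopag"].response_probability == 0.42
        assert s.response["eltrombopag"].response_probability == 0.22
        assert s.response["romiplostim"].response_probability == 0.47

    def test_window_12_weeks_empties_no_response_from_cycle_4(self, params,
                                                              life_table):
        s = apply_scenario(short_horizon(params, 3), "window_12_weeks")
        for r in s.response.values():
            assert r.non_response_window_cycles == 3
        trace = m.run_cohort(s, "avatrombopag", life_table)
        after = trace.frame[trace.frame["cycle"] >= 4]
        assert (after["no_response"] == 0.0).all()
        # some patients do respond (realization clipped into the window)
        assert trace.frame["response"].max() > 0

    def test_standard_tariff_lowers_every_bleeding_component(self, params,
                                                             life_table):
        p = short_horizon(params, 10)
        base = m.outcome_for(p, "eltrombopag", life_table)
        s = apply_scenario(p, "standard_tariff")
        alt = m.outcome_for(s, "eltrombopag", life_table)
        for comp in ("outpatient_bleed", "intracranial", "gastrointestinal",
                     "other_inpatient"):
            assert getattr(alt.costs, comp) < getattr(base.costs, comp)
        assert alt.costs.minor_bleed == base.costs.minor_bleed == 0.0

    def test_qualitative_tariff_raises_bleeding_costs(self, params, life_table):
        p = short_horizon(params, 10)
        base = m.outcome_for(p, "eltrombopag", life_table)
        alt = m.outcome_for(apply_scenario(p, "qualitative_tariff"),
                            "eltrombopag", life_table)
        assert alt.costs.bleeding_total > base.costs.bleeding_total

    def test_subsequent_lines_scenario_runs_and_doubles_refractory_rate(
            self, params, life_table):
        s = apply_scenario(short_horizon(params, 10), "subsequent_lines")
        assert s.settings.enable_subsequent_lines
        assert s.care.appendix.refractory_inpatient_bleed_multiplier == 2.0
        assert (s.bleeds.probabilities["lt50"]["inpatient"]
                * s.care.appendix.refractory_inpatient_bleed_multiplier
                == pytest.approx(0.086))
        result = m.run_scenario(s, "subsequent_lines", table=life_table)
        assert set(result.outcomes) == set(m.TREATMENTS)
        assert result.incrementals["eltrombopag"].delta_qaly != 0.0

    def test_run_scenario_full_pipeline(self, params, life_table):
        result = m.run_scenario(short_horizon(params, 6), "standard_tariff",
                                table=life_table)
        assert result.name == "standard_tariff"
        assert set(result.incrementals) == {"eltrombopag", "romiplostim"}
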
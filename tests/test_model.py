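"""Unit tests for the deterministic cohort engine."""

import math

import pytest

from livessaved import (
    CoverageTrajectory,
    Effect,
    InterventionSpec,
    Scenario,
    ValidationError,
    analyze_pair,
    bongaarts_index,
    decompose_fp_health,
    lives_saved,
    per_intervention_attribution,
    project_births,
    residual_factor,
    run_projection,
)

from conftest import constant_values, make_pair, make_scenario


class TestBongaartsIndex:
    @pytest.mark.parametrize("cp,eff,expected", [
        (0.0, 0.9, 1.0),
        (0.1, 0.9, 1.0 - 1.08 * 0.1 * 0.9),   # 0.9028
        (0.3, 0.9, 1.0 - 1.08 * 0.3 * 0.9),   # 0.7084
    ])
    def test_values(self, cp, eff, expected):
        assert bongaarts_index(cp, eff) == pytest.approx(expected, abs=1e-12)

    def test_rejects_non_positive_index(self):
        with pytest.raises(ValidationError):
            bongaarts_index(1.0, 0.95)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bongaarts_index(-0.1, 0.9)


class TestProjectBirths:
    def test_constant_prevalence_gives_constant_births(
            self, single_cause_profile):
        cp = {y: single_cause_profile.cp0 for y in single_cause_profile.years}
        births = project_births(single_cause_profile, cp, 1.0)
        assert all(b == pytest.approx(100_000.0) for b in births.values())

    def test_hand_example(self, single_cause_profile):
        """women=700k, tfr=5, cp 0.1 -> 0.3 in 2013: births fall by C ratio."""
        cp = {y: single_cause_profile.cp0 for y in single_cause_profile.years}
        cp[2013] = 0.3
        births = project_births(single_cause_profile, cp, 1.0)
        expected = 100_000.0 * (1 - 1.08 * 0.3 * 0.9) / (1 - 1.08 * 0.1 * 0.9)
        assert births[2013] == pytest.approx(expected)     # ~78,467
        assert births[2013] == pytest.approx(78_467, rel=1e-4)
        assert births[2012] == pytest.approx(100_000.0)

    def test_share_is_proportional(self, single_cause_profile):
        cp = {y: 0.2 for y in single_cause_profile.years}
        full = project_births(single_cause_profile, cp, 1.0)
        half = project_births(single_cause_profile, cp, 0.5)
        for year in full:
            assert half[year] == pytest.approx(full[year] / 2)

    def test_missing_year_is_named(self, single_cause_profile):
        with pytest.raises(ValidationError, match="2014"):
            project_births(single_cause_profile, {2010: 0.1}, 1.0,
                           years=[2010, 2014])


class TestResidualFactor:
    def test_empty_product(self, single_cause_library):
        specs = list(single_cause_library.values())
        assert residual_factor(specs, {}, "neonatal", "no_such_cause") == 1.0

    def test_single_effect(self):
        spec = InterventionSpec(
            "iv", "iv", "childbirth", "curative",
            effects=(Effect("neonatal", "c", 0.5, 1.0),))
        assert residual_factor([spec], {"iv": 0.6}, "neonatal", "c") \
            == pytest.approx(0.7)

    def test_order_invariance(self):
        a = InterventionSpec("a", "a", "pregnancy", "preventive",
                             effects=(Effect("neonatal", "c", 0.5, 1.0),))
        b = InterventionSpec("b", "b", "postnatal", "curative",
                             effects=(Effect("neonatal", "c", 0.2, 1.0),))
        cov = {"a": 0.6, "b": 0.5}
        forward = residual_factor([a, b], cov, "neonatal", "c")
        backward = residual_factor([b, a], cov, "neonatal", "c")
        assert forward == pytest.approx(0.7 * 0.9)
        assert forward == backward

    def test_unknown_intervention_rejected(self):
        spec = InterventionSpec(
            "iv", "iv", "childbirth", "curative",
            effects=(Effect("neonatal", "c", 0.5, 1.0),))
        with pytest.raises(ValidationError, match="unknown"):
            residual_factor([spec], {"ghost": 0.5}, "neonatal", "c")


class TestRunProjection:
    def test_baseline_trajectory_reproduces_baseline_rates(
            self, single_cause_profile, single_cause_library):
        values = constant_values(single_cause_profile, "resuscitation",
                                 0.2, 0.2)
        result = run_projection(make_scenario(single_cause_profile, values),
                                single_cause_library)
        for year in single_cause_profile.years:
            assert result.neonatal_deaths[(year, "birth_asphyxia")] \
                == pytest.approx(3000.0)
            assert result.maternal_deaths[(year, "haemorrhage")] \
                == pytest.approx(500.0)

    def test_hand_example_coverage_rise(self, single_cause_profile,
                                        single_cause_library):
        """Coverage 0.2 -> 0.6 with E=0.5: 3000 deaths fall to 3000*0.7/0.9."""
        values = constant_values(single_cause_profile, "resuscitation",
                                 0.2, 0.6)
        result = run_projection(make_scenario(single_cause_profile, values),
                                single_cause_library)
        assert result.neonatal_deaths[(2013, "birth_asphyxia")] \
            == pytest.approx(3000.0 * 0.7 / 0.9)  # ~2333.3

    def test_saturated_baseline_rejected(self, single_cause_profile):
        saturated = {"total": InterventionSpec(
            "total", "total", "childbirth", "curative",
            effects=(Effect("neonatal", "birth_asphyxia", 1.0, 1.0),))}
        profile = single_cause_profile
        object.__setattr__(profile, "baseline_coverage", {"total": 1.0})
        values = constant_values(profile, "total", 1.0, 1.0)
        with pytest.raises(ValidationError, match="saturates"):
            run_projection(make_scenario(profile, values), saturated)


class TestLivesSaved:
    def test_identical_scenarios_save_nothing(self, single_cause_profile,
                                              single_cause_library):
        values = constant_values(single_cause_profile, "resuscitation",
                                 0.2, 0.5)
        result = run_projection(make_scenario(single_cause_profile, values),
                                single_cause_library)
        saved = lives_saved(result, result)
        assert all(v == 0.0 for series in saved.values()
                   for v in series.values())

    def test_subtraction_and_total(self, single_cause_profile,
                                   single_cause_library):
        with_values = constant_values(single_cause_profile, "resuscitation",
                                      0.2, 0.6)
        without_values = constant_values(single_cause_profile,
                                         "resuscitation", 0.2, 0.2)
        w = run_projection(make_scenario(single_cause_profile, with_values),
                           single_cause_library)
        wo = run_projection(
            make_scenario(single_cause_profile, without_values,
                          label="without_funder"),
            single_cause_library)
        saved = lives_saved(w, wo)
        per_year = 3000.0 * (1 - 0.7 / 0.9)   # ~666.7
        for year in single_cause_profile.years[1:]:
            assert saved["neonatal"][year] == pytest.approx(per_year)
        total = sum(v for y, v in saved["neonatal"].items() if y > 2010)
        assert total == pytest.approx(5 * per_year)   # ~3333

    def test_antisymmetry(self, single_cause_profile, single_cause_library):
        a = run_projection(
            make_scenario(single_cause_profile,
                          constant_values(single_cause_profile,
                                          "resuscitation", 0.2, 0.6)),
            single_cause_library)
        b = run_projection(
            make_scenario(single_cause_profile,
                          constant_values(single_cause_profile,
                                          "resuscitation", 0.2, 0.3),
                          label="without_funder"),
            single_cause_library)
        ab = lives_saved(a, b)
        ba = lives_saved(b, a)
        for group in ab:
            for year in ab[group]:
                assert ab[group][year] == pytest.approx(-ba[group][year])

    def test_year_mismatch_rejected(self, single_cause_profile,
                                    single_cause_library):
        values = constant_values(single_cause_profile, "resuscitation",
                                 0.2, 0.5)
        full = run_projection(make_scenario(single_cause_profile, values),
                              single_cause_library)
        truncated = run_projection(
            make_scenario(
                single_cause_profile,
                {k: v for k, v in values.items() if k[1] <= 2013},
                cp={y: 0.1 for y in range(2010, 2014)}),
            single_cause_library)
        with pytest.raises(ValidationError):
            lives_saved(full, truncated)


class TestDecomposition:
    def test_no_fp_means_full_equals_health(self, single_cause_profile,
                                            single_cause_library):
        pair = make_pair(single_cause_profile, single_cause_library,
                         constant_values(single_cause_profile,
                                         "resuscitation", 0.2, 0.6),
                         constant_values(single_cause_profile,
                                         "resuscitation", 0.2, 0.4))
        result = analyze_pair(pair, single_cause_library)
        for year in result.maternal_fp:
            assert result.maternal_fp[year] == pytest.approx(0.0, abs=1e-9)
            assert result.newborn_fertility[year] == pytest.approx(0.0,
                                                                   abs=1e-9)

    def test_fp_only_portfolio(self, single_cause_profile,
                               single_cause_library):
        profile = single_cause_profile
        with_values = constant_values(profile, "contraception", 0.1, 0.3)
        without_values = constant_values(profile, "contraception", 0.1, 0.1)
        cp_with = {y: with_values[("contraception", y)]
                   for y in profile.years}
        cp_without = {y: 0.1 for y in profile.years}
        pair = make_pair(profile, single_cause_library, with_values,
                         without_values, cp_with, cp_without)
        result = analyze_pair(pair, single_cause_library)
        for year in result.maternal_health:
            assert result.maternal_health[year] == pytest.approx(0.0,
                                                                 abs=1e-9)
            assert result.newborn_primary[year] == pytest.approx(0.0,
                                                                 abs=1e-9)
        assert sum(result.maternal_fp.values()) > 0
        assert sum(result.newborn_fertility.values()) > 0

    def test_additivity_in_mixed_portfolio(self, single_cause_profile,
                                           single_cause_library):
        profile = single_cause_profile
        with_values = {**constant_values(profile, "resuscitation", 0.2, 0.6),
                       **constant_values(profile, "contraception", 0.1, 0.25)}
        without_values = {
            **constant_values(profile, "resuscitation", 0.2, 0.4),
            **constant_values(profile, "contraception", 0.1, 0.15)}
        cp_with = {y: with_values[("contraception", y)] for y in profile.years}
        cp_without = {y: without_values[("contraception", y)]
                      for y in profile.years}
        pair = make_pair(profile, single_cause_library, with_values,
                         without_values, cp_with, cp_without)
        result = analyze_pair(pair, single_cause_library)
        for year in result.maternal_total:
            assert result.maternal_fp[year] + result.maternal_health[year] \
                == pytest.approx(result.maternal_total[year], abs=1e-9)

    def test_mismatched_profiles_rejected(self, single_cause_profile,
                                          single_cause_library):
        import dataclasses
        other = dataclasses.replace(single_cause_profile,
                                    country_id="elsewhere")
        values = constant_values(single_cause_profile, "resuscitation",
                                 0.2, 0.5)
        a = run_projection(make_scenario(single_cause_profile, values),
                           single_cause_library)
        b = run_projection(make_scenario(other, values),
                           single_cause_library)
        with pytest.raises(ValidationError, match="different profiles"):
            decompose_fp_health((a, a), (b, b))


class TestAttribution:
    def test_single_intervention_gets_everything(self, single_cause_profile,
                                                 single_cause_library):
        pair = make_pair(single_cause_profile, single_cause_library,
                         constant_values(single_cause_profile,
                                         "resuscitation", 0.2, 0.6),
                         constant_values(single_cause_profile,
                                         "resuscitation", 0.2, 0.2))
        result = analyze_pair(pair, single_cause_library)
        headline = (sum(result.maternal_total.values())
                    + sum(result.newborn_primary.values()))
        assert result.per_intervention["resuscitation"] \
            == pytest.approx(headline, abs=1e-6)

    def test_identical_twins_share_equally(self, single_cause_profile):
        twins = {
            f"twin_{i}": InterventionSpec(
                f"twin_{i}", f"twin {i}", "childbirth", "curative",
                effects=(Effect("neonatal", "birth_asphyxia", 0.3, 1.0),))
            for i in "ab"}
        profile = single_cause_profile
        object.__setattr__(profile, "baseline_coverage",
                           {"twin_a": 0.2, "twin_b": 0.2})
        with_values = {**constant_values(profile, "twin_a", 0.2, 0.6),
                       **constant_values(profile, "twin_b", 0.2, 0.6)}
        without_values = {**constant_values(profile, "twin_a", 0.2, 0.2),
                          **constant_values(profile, "twin_b", 0.2, 0.2)}
        pair = make_pair(profile, twins, with_values, without_values)
        shares = per_intervention_attribution(pair, twins)
        assert shares["twin_a"] == pytest.approx(shares["twin_b"])

    def test_conservation_vs_leave_one_out(self, single_cause_profile):
        """Log shares and normalized leave-one-out differ per intervention
        but both sum to the pair's total lives saved."""
        specs = {
            "strong": InterventionSpec(
                "strong", "strong", "childbirth", "curative",
                effects=(Effect("neonatal", "birth_asphyxia", 0.6, 1.0),)),
            "weak": InterventionSpec(
                "weak", "weak", "postnatal", "preventive",
                effects=(Effect("neonatal", "birth_asphyxia", 0.2, 1.0),)),
        }
        profile = single_cause_profile
        object.__setattr__(profile, "baseline_coverage",
                           {"strong": 0.1, "weak": 0.3})
        with_values = {**constant_values(profile, "strong", 0.1, 0.7),
                       **constant_values(profile, "weak", 0.3, 0.5)}
        without_values = {**constant_values(profile, "strong", 0.1, 0.1),
                          **constant_values(profile, "weak", 0.3, 0.3)}
        pair = make_pair(profile, specs, with_values, without_values)
        result = analyze_pair(pair, specs)
        total = (sum(result.maternal_total.values())
                 + sum(result.newborn_primary.values()))
        log_shares = result.per_intervention
        assert sum(log_shares.values()) == pytest.approx(total, abs=1e-6)

        # leave-one-out oracle: marginal contribution of dropping each
        # intervention's coverage change, normalized to the same total
        def total_saved(active):
            wv, wov = {}, {}
            for (iid, year), v in with_values.items():
                wv[(iid, year)] = v if iid in active \
                    else without_values[(iid, year)]
            p = make_pair(profile, specs, wv, without_values)
            r = analyze_pair(p, specs)
            return (sum(r.maternal_total.values())
                    + sum(r.newborn_primary.values()))

        loo = {iid: total - total_saved({other for other in specs
                                         if other != iid})
               for iid in specs}
        loo_norm = {iid: v * total / sum(loo.values())
                    for iid, v in loo.items()}
        assert sum(loo_norm.values()) == pytest.approx(total, abs=1e-6)
        # the two rules agree on the ranking but not the exact split
        assert loo_norm["strong"] > loo_norm["weak"]
        assert log_shares["strong"] > log_shares["weak"]
        assert abs(loo_norm["strong"] - log_shares["strong"]) > 1e-9
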
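"""Shared fixtures: a hand-checkable single-cause country and helpers."""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Tuple

import pytest

from livessaved import (
    CountryProfile,
    CoverageTrajectory,
    Effect,
    InterventionSpec,
    Scenario,
    ScenarioPair,
)


@pytest.fixture
def single_cause_profile() -> CountryProfile:
    """100,000 births/year, NMR 30, one cause per group, cp0 = 0.1."""
    return CountryProfile(
        country_id="testland",
        tfr0=5.0,
        women_reproductive_age=700_000,
        nmr0=30.0,
        mmr0=500.0,
        neonatal_cause_fractions={"birth_asphyxia": 1.0},
        maternal_cause_fractions={"haemorrhage": 1.0},
        baseline_coverage={"resuscitation": 0.2, "uterotonics": 0.1},
        cp0=0.1,
        contraceptive_effectiveness=0.9,
    )


@pytest.fixture
def single_cause_library() -> Dict[str, InterventionSpec]:
    return {
        "resuscitation": InterventionSpec(
            "resuscitation", "neonatal resuscitation", "childbirth",
            "curative",
            effects=(Effect("neonatal", "birth_asphyxia", 0.5, 1.0),)),
        "uterotonics": InterventionSpec(
            "uterotonics", "uterotonics", "childbirth", "curative",
            effects=(Effect("maternal", "haemorrhage", 0.4, 1.0),)),
        "contraception": InterventionSpec(
            "contraception", "modern contraception", "pre-pregnancy",
            "preventive", effects=(), is_family_planning=True),
    }


def constant_values(profile: CountryProfile, iid: str, baseline: float,
                    level: float) -> Dict[Tuple[str, int], float]:
    """Baseline value in the baseline year, a flat level afterwards."""
    return {(iid, year): (baseline if year == profile.baseline_year
                          else level)
            for year in profile.years}


def make_scenario(profile: CountryProfile,
                  values: Dict[Tuple[str, int], float],
                  cp: Optional[Dict[int, float]] = None,
                  label: str = "with_funder",
                  share: float = 1.0) -> Scenario:
    if cp is None:
        cp = {year: profile.cp0 for year in profile.years}
    return Scenario(profile=profile,
                    trajectory=CoverageTrajectory(dict(values), dict(cp)),
                    label=label, population_share=share)


def make_pair(profile: CountryProfile,
              specs: Mapping[str, InterventionSpec],
              with_values: Dict[Tuple[str, int], float],
              without_values: Dict[Tuple[str, int], float],
              cp_with: Optional[Dict[int, float]] = None,
              cp_without: Optional[Dict[int, float]] = None,
              share: float = 1.0) -> ScenarioPair:
    """Build a full scenario pair; the health-only pair holds prevalence
    (and family-planning coverage) at the with-funder values."""
    years = profile.years
    if cp_with is None:
        cp_with = {year: profile.cp0 for year in years}
    if cp_without is None:
        cp_without = dict(cp_with)
    health_without = dict(without_values)
    for iid in {i for i, _ in with_values}:
        if specs[iid].is_family_planning:
            for year in years:
                health_without[(iid, year)] = with_values[(iid, year)]
    return ScenarioPair(
        with_funder=make_scenario(profile, with_values, cp_with,
                                  "with_funder", share),
        without_funder=make_scenario(profile, without_values, cp_without,
                                     "without_funder", share),
        health_only_with=make_scenario(profile, with_values, cp_with,
                                       "with_funder", share),
        health_only_without=make_scenario(profile, health_without, cp_with,
                                          "without_funder", share),
    )
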
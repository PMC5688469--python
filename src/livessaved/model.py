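"""Deterministic cohort engine for maternal and newborn lives-saved estimation.

The engine projects annual births and cause-specific maternal and neonatal
deaths for a *scenario* — a country baseline plus intervention-coverage and
contraceptive-prevalence trajectories — and differences paired scenarios
(with-funder vs counterfactual) to obtain lives saved.

Model sketch
------------
Births follow the baseline total fertility rate converted to an annual birth
cohort (TFR divided by a 35-year reproductive span, times women of
reproductive age), scaled by the ratio of the Bongaarts index of
contraception ``C = 1 - 1.08 * u * e`` between the scenario's contraceptive
prevalence ``u_t`` and the 2010 baseline ``u_0``.

Cause-specific deaths start from the baseline rate (NMR per 1000 live
births, MMR per 100,000 live births) split by cause-of-death fractions, and
move with the ratio of *residual mortality* factors

    R(cov) = prod_i (1 - effectiveness_i * affected_fraction_i * cov_i)

between the scenario coverage and the baseline coverage.  The ratio form
means a scenario that never departs from the 2010 baseline reproduces the
baseline death counts exactly, and each single intervention acts linearly in
its own coverage, while the multiplicative cascade keeps combined effects
below 100%.  Interventions are ordered along the continuum of care
(pre-pregnancy, pregnancy, childbirth, postnatal; preventive before
curative) for reporting; the product itself is order-invariant.

Maternal risk is denominated per live birth, so fertility declines reduce
maternal deaths automatically; the fertility-mediated share is separated
from the direct-health share by a secondary scenario pair that holds
contraceptive prevalence fixed (see :func:`decompose_fp_health`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

logger = logging.getLogger(__name__)

NEONATAL = "neonatal"
MATERNAL = "maternal"
TARGET_GROUPS = (NEONATAL, MATERNAL)

PERIODS = ("pre-pregnancy", "pregnancy", "childbirth", "postnatal")
CATEGORIES = ("preventive", "curative")
SCENARIO_LABELS = ("with_funder", "without_funder")

#: years a woman is exposed to childbearing; converts TFR to an annual rate
REPRODUCTIVE_SPAN_YEARS = 35.0
#: sterility/overlap adjustment in the Bongaarts index of contraception
BONGAARTS_OVERLAP = 1.08

_TOL = 1e-9


class ValidationError(ValueError):
    """An input object violates a model invariant or precondition."""


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


def _fraction(value: float, name: str) -> None:
    _check(0.0 <= value <= 1.0, f"{name} must lie in [0, 1], got {value!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountryProfile:
    """Demographic and epidemiological baseline for one country.

    Parameters
    ----------
    tfr0 : total fertility rate at baseline (births per woman).
    women_reproductive_age : women aged 15-49, assumed constant over the
        projection (the horizon is five years).
    nmr0 : neonatal deaths per 1000 live births at baseline.
    mmr0 : maternal deaths per 100,000 live births at baseline.
    neonatal_cause_fractions, maternal_cause_fractions : cause-of-death
        fractions; each map must sum to 1.
    baseline_coverage : 2010 coverage per intervention id.
    cp0 : baseline contraceptive prevalence.
    contraceptive_effectiveness : use-effectiveness of the method mix.
    mortality_source : label of the NMR/MMR source (IGME, IHME, DHS, ...).
    """

    country_id: str
    tfr0: float
    women_reproductive_age: float
    nmr0: float
    mmr0: float
    neonatal_cause_fractions: Mapping[str, float]
    maternal_cause_fractions: Mapping[str, float]
    baseline_coverage: Mapping[str, float]
    cp0: float
    contraceptive_effectiveness: float = 0.9
    baseline_year: int = 2010
    horizon_year: int = 2015
    mortality_source: str = "IGME"

    def __post_init__(self) -> None:
        _check(self.tfr0 >= 0, "tfr0 must be non-negative")
        _check(self.nmr0 >= 0, "nmr0 must be non-negative")
        _check(self.mmr0 >= 0, "mmr0 must be non-negative")
        _check(self.women_reproductive_age >= 0,
               "women_reproductive_age must be non-negative")
        _check(self.baseline_year < self.horizon_year,
               "baseline_year must precede horizon_year")
        _fraction(self.cp0, "cp0")
        _fraction(self.contraceptive_effectiveness, "contraceptive_effectiveness")
        for name, fractions in (("neonatal", self.neonatal_cause_fractions),
                                ("maternal", self.maternal_cause_fractions)):
            _check(len(fractions) > 0, f"{name} cause fractions are empty")
            total = sum(fractions.values())
            _check(abs(total - 1.0) <= _TOL,
                   f"{name} cause fractions sum to {total}, expected 1")
            for cause, frac in fractions.items():
                _fraction(frac, f"{name} cause fraction {cause!r}")
        for iid, cov in self.baseline_coverage.items():
            _fraction(cov, f"baseline coverage for {iid!r}")

    @property
    def years(self) -> List[int]:
        return list(range(self.baseline_year, self.horizon_year + 1))


@dataclass(frozen=True)
class Effect:
    """One cause-specific mortality effect of an intervention.

    ``effectiveness`` is the proportional mortality reduction at full
    coverage; ``affected_fraction`` damps it to the share of deaths from
    this cause the intervention can address.
    """

    target_group: str
    cause: str
    effectiveness: float
    affected_fraction: float = 1.0

    def __post_init__(self) -> None:
        _check(self.target_group in TARGET_GROUPS,
               f"unknown target group {self.target_group!r}")
        _fraction(self.effectiveness, "effectiveness")
        _fraction(self.affected_fraction, "affected_fraction")


@dataclass(frozen=True)
class InterventionSpec:
    """One intervention in the configurable effectiveness library."""

    intervention_id: str
    name: str
    period: str
    category: str
    effects: Tuple[Effect, ...] = ()
    is_family_planning: bool = False

    def __post_init__(self) -> None:
        _check(self.period in PERIODS, f"unknown period {self.period!r}")
        _check(self.category in CATEGORIES, f"unknown category {self.category!r}")
        object.__setattr__(self, "effects", tuple(self.effects))
        if not self.is_family_planning:
            _check(len(self.effects) > 0,
                   f"intervention {self.intervention_id!r} has no effects")

    def matching_effects(self, target_group: str, cause: str) -> List[Effect]:
        return [e for e in self.effects
                if e.target_group == target_group and e.cause == cause]


def ordered_specs(specs: Iterable[InterventionSpec]) -> List[InterventionSpec]:
    """Continuum-of-care ordering: by period, preventive before curative."""
    return sorted(specs, key=lambda s: (PERIODS.index(s.period),
                                        CATEGORIES.index(s.category),
                                        s.intervention_id))


@dataclass
class CoverageTrajectory:
    """Annual coverage per intervention plus contraceptive prevalence.

    ``values`` maps ``(intervention_id, year)`` to a coverage fraction and
    must be dense over the years of ``cp`` for every intervention present.
    """

    values: Dict[Tuple[str, int], float]
    cp: Dict[int, float]

    def __post_init__(self) -> None:
        for (iid, year), cov in self.values.items():
            _fraction(cov, f"coverage for {iid!r} in {year}")
        for year, u in self.cp.items():
            _fraction(u, f"contraceptive prevalence in {year}")
        _check(len(self.cp) > 0, "trajectory has no years")

    @property
    def years(self) -> List[int]:
        return sorted(self.cp)

    @property
    def interventions(self) -> List[str]:
        return sorted({iid for iid, _ in self.values})

    def coverage_at(self, year: int) -> Dict[str, float]:
        out = {}
        for iid in self.interventions:
            key = (iid, year)
            if key not in self.values:
                raise ValidationError(
                    f"trajectory missing coverage for {iid!r} in year {year}")
            out[iid] = self.values[key]
        return out


@dataclass
class Scenario:
    """One projection input: profile, trajectory, and its role label."""

    profile: CountryProfile
    trajectory: CoverageTrajectory
    label: str
    population_share: float = 1.0

    def __post_init__(self) -> None:
        _check(self.label in SCENARIO_LABELS, f"unknown label {self.label!r}")
        _check(0.0 < self.population_share <= 1.0,
               "population_share must lie in (0, 1]")
        years = self.trajectory.years
        _check(min(years) >= self.profile.baseline_year
               and max(years) <= self.profile.horizon_year,
               "trajectory years fall outside the projection window")
        _check(years[0] == self.profile.baseline_year,
               "trajectory must start at the baseline year")
        base = years[0]
        for iid in self.trajectory.interventions:
            if iid in self.profile.baseline_coverage:
                expected = self.profile.baseline_coverage[iid]
                got = self.trajectory.values.get((iid, base))
                _check(got is not None and abs(got - expected) <= _TOL,
                       f"baseline-year coverage for {iid!r} ({got}) does not "
                       f"match the profile baseline ({expected})")


@dataclass
class ProjectionResult:
    """Annual births and cause-specific death counts for one scenario."""

    country_id: str
    label: str
    births: Dict[int, float]
    neonatal_deaths: Dict[Tuple[int, str], float]
    maternal_deaths: Dict[Tuple[int, str], float]

    def deaths(self, target_group: str) -> Dict[Tuple[int, str], float]:
        return self.neonatal_deaths if target_group == NEONATAL else self.maternal_deaths

    def deaths_by_year(self, target_group: str) -> Dict[int, float]:
        out: Dict[int, float] = {year: 0.0 for year in self.births}
        for (year, _cause), count in self.deaths(target_group).items():
            out[year] += count
        return out


@dataclass
class ScenarioPair:
    """Primary with/without pair plus the health-only secondary pair.

    The secondary pair holds contraceptive prevalence at the with-funder
    values in both members, isolating the direct-health impact; the
    fertility-mediated impact is the remainder.
    """

    with_funder: Scenario
    without_funder: Scenario
    health_only_with: Scenario
    health_only_without: Scenario

    def __post_init__(self) -> None:
        scenarios = (self.with_funder, self.without_funder,
                     self.health_only_with, self.health_only_without)
        ids = {s.profile.country_id for s in scenarios}
        _check(len(ids) == 1, "scenario pair mixes country profiles")
        shares = {round(s.population_share, 12) for s in scenarios}
        _check(len(shares) == 1, "scenario pair mixes population shares")

    @property
    def profile(self) -> CountryProfile:
        return self.with_funder.profile

    @property
    def population_share(self) -> float:
        return self.with_funder.population_share


_SERIES = ("maternal_total", "maternal_fp", "maternal_health",
           "newborn_primary", "newborn_fertility")


@dataclass
class LivesSavedResult:
    """Annual and total lives saved for one analysis unit, country or globe.

    Annual maps cover the years strictly after the baseline year; the
    baseline year itself contributes zero by the normalization of the
    engine.  ``newborn_fertility`` is auxiliary (excluded from headline
    totals and from per-intervention attribution).
    """

    country_id: str
    baseline_year: int
    maternal_total: Dict[int, float] = field(default_factory=dict)
    maternal_fp: Dict[int, float] = field(default_factory=dict)
    maternal_health: Dict[int, float] = field(default_factory=dict)
    newborn_primary: Dict[int, float] = field(default_factory=dict)
    newborn_fertility: Dict[int, float] = field(default_factory=dict)
    per_intervention: Dict[str, float] = field(default_factory=dict)

    SERIES = _SERIES

    def series(self, name: str) -> Dict[int, float]:
        _check(name in _SERIES, f"unknown series {name!r}")
        return getattr(self, name)

    @property
    def totals(self) -> Dict[str, float]:
        return {name: sum(self.series(name).values()) for name in _SERIES}

    def __add__(self, other: "LivesSavedResult") -> "LivesSavedResult":
        cid = self.country_id if self.country_id == other.country_id else "combined"
        out = LivesSavedResult(country_id=cid,
                               baseline_year=min(self.baseline_year,
                                                 other.baseline_year))
        for name in _SERIES:
            merged: Dict[int, float] = dict(self.series(name))
            for year, v in other.series(name).items():
                merged[year] = merged.get(year, 0.0) + v
            setattr(out, name, merged)
        merged_pi = dict(self.per_intervention)
        for iid, v in other.per_intervention.items():
            merged_pi[iid] = merged_pi.get(iid, 0.0) + v
        out.per_intervention = merged_pi
        return out


def sum_results(results: Sequence[LivesSavedResult],
                country_id: str) -> LivesSavedResult:
    """Elementwise sum of lives-saved results (units → country → global)."""
    if not results:
        raise ValidationError("cannot sum an empty result list")
    total = results[0]
    for res in results[1:]:
        total = total + res
    total.country_id = country_id
    return total


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def bongaarts_index(cp: float, eff: float) -> float:
    """Bongaarts index of contraception ``C = 1 - 1.08 * cp * eff``.

    The 1.08 factor adjusts for contraceptive use among fecund women.  The
    index multiplies potential fertility, so higher prevalence means fewer
    births.
    """
    _fraction(cp, "contraceptive prevalence")
    _fraction(eff, "contraceptive effectiveness")
    index = 1.0 - BONGAARTS_OVERLAP * cp * eff
    if index <= 0.0:
        raise ValidationError(
            "contraception parameters imply a non-positive fertility index "
            f"(cp={cp}, eff={eff})")
    return index


def project_births(profile: CountryProfile,
                   cp: Mapping[int, float],
                   population_share: float,
                   years: Optional[Sequence[int]] = None) -> Dict[int, float]:
    """Annual births under a contraceptive-prevalence trajectory.

    births_t = W * (TFR0 / 35) * C(cp_t) / C(cp_0) * share.  With prevalence
    held at baseline the annual cohort is constant.
    """
    _check(0.0 < population_share <= 1.0, "population_share must lie in (0, 1]")
    eff = profile.contraceptive_effectiveness
    base_index = bongaarts_index(profile.cp0, eff)
    cohort0 = (profile.women_reproductive_age * profile.tfr0
               / REPRODUCTIVE_SPAN_YEARS)
    if years is None:
        years = sorted(cp)
    births: Dict[int, float] = {}
    for year in years:
        if year not in cp:
            raise ValidationError(
                f"contraceptive prevalence missing for year {year}")
        births[year] = (cohort0 * bongaarts_index(cp[year], eff) / base_index
                        * population_share)
    return births


def residual_factor(specs: Sequence[InterventionSpec],
                    coverage: Mapping[str, float],
                    target_group: str,
                    cause: str) -> float:
    """Residual mortality multiplier ``prod (1 - E * AF * cov)``.

    Interventions without an effect matching (target_group, cause)
    contribute a factor of one.  The product is evaluated in continuum-of-
    care order, which matters only for reporting: the result is exactly
    order-invariant.
    """
    known = {s.intervention_id for s in specs}
    for iid in coverage:
        if iid not in known:
            raise ValidationError(
                f"coverage given for unknown intervention {iid!r}")
    factor = 1.0
    for spec in ordered_specs(specs):
        cov = coverage.get(spec.intervention_id, 0.0)
        _fraction(cov, f"coverage for {spec.intervention_id!r}")
        for effect in spec.matching_effects(target_group, cause):
            factor *= 1.0 - effect.effectiveness * effect.affected_fraction * cov
    return factor


def run_projection(scenario: Scenario,
                   specs: Mapping[str, InterventionSpec]) -> ProjectionResult:
    """Project annual births and cause-specific deaths for one scenario.

    Deaths per (year, cause) are the baseline cause-specific rate applied to
    the projected births, scaled by the ratio of residual factors at the
    scenario coverage versus the 2010 baseline coverage; zero coverage
    change therefore reproduces baseline rates exactly.
    """
    profile = scenario.profile
    traj = scenario.trajectory
    spec_list: List[InterventionSpec] = []
    for iid in traj.interventions:
        if iid not in specs:
            raise ValidationError(
                f"trajectory references unknown intervention {iid!r}")
        spec_list.append(specs[iid])

    years = traj.years
    births = project_births(profile, traj.cp, scenario.population_share,
                            years=years)
    base_cov = {s.intervention_id:
                profile.baseline_coverage.get(s.intervention_id, 0.0)
                for s in spec_list}
    coverage_by_year = {year: traj.coverage_at(year) for year in years}

    group_tables = ((NEONATAL, profile.neonatal_cause_fractions,
                     profile.nmr0 / 1000.0),
                    (MATERNAL, profile.maternal_cause_fractions,
                     profile.mmr0 / 100000.0))
    deaths = {NEONATAL: {}, MATERNAL: {}}
    for group, cause_fractions, rate in group_tables:
        for cause, frac in cause_fractions.items():
            r0 = residual_factor(spec_list, base_cov, group, cause)
            if r0 == 0.0:
                raise ValidationError(
                    "baseline coverage saturates an effect: residual factor "
                    f"is zero for {group}/{cause}")
            for year in years:
                rt = residual_factor(spec_list, coverage_by_year[year],
                                     group, cause)
                deaths[group][(year, cause)] = (
                    births[year] * rate * frac * rt / r0)
    return ProjectionResult(country_id=profile.country_id,
                            label=scenario.label,
                            births=births,
                            neonatal_deaths=deaths[NEONATAL],
                            maternal_deaths=deaths[MATERNAL])


def lives_saved(with_result: ProjectionResult,
                without_result: ProjectionResult) -> Dict[str, Dict[int, float]]:
    """Annual lives saved: deaths(without) - deaths(with), by target group.

    Negative values (a funder scenario with higher mortality) are reported
    and flagged with a warning, never clipped.
    """
    if set(with_result.births) != set(without_result.births):
        raise ValidationError("paired projections cover different years")
    out: Dict[str, Dict[int, float]] = {}
    for group in TARGET_GROUPS:
        w = with_result.deaths(group)
        wo = without_result.deaths(group)
        if set(w) != set(wo):
            raise ValidationError(
                f"paired projections have mismatched {group} cause-years")
        annual: Dict[int, float] = {year: 0.0 for year in with_result.births}
        for (year, cause), count in wo.items():
            annual[year] += count - w[(year, cause)]
        out[group] = annual
    if any(v < -_TOL for annual in out.values() for v in annual.values()):
        logger.warning("negative lives saved for %s: funder scenario has "
                       "higher mortality in at least one year",
                       with_result.country_id)
    return out


def decompose_fp_health(
        full_pair: Tuple[ProjectionResult, ProjectionResult],
        health_only_pair: Tuple[ProjectionResult, ProjectionResult],
) -> Dict[str, Dict[int, float]]:
    """Split lives saved into family-planning and direct-health components.

    The health-only pair holds contraceptive prevalence at the with-funder
    values in both members, so its difference is the direct-health impact;
    the family-planning component is the remainder of the full pair (the
    FP-health interaction is folded into the FP component by construction).
    Newborn fertility-mediated savings are returned separately and excluded
    from headline totals.
    """
    results = (*full_pair, *health_only_pair)
    if len({r.country_id for r in results}) != 1:
        raise ValidationError("pairs built from different profiles")
    full = lives_saved(*full_pair)
    health = lives_saved(*health_only_pair)
    if set(full[MATERNAL]) != set(health[MATERNAL]):
        raise ValidationError("pairs cover different years")
    years = sorted(full[MATERNAL])
    return {
        "maternal_total": {y: full[MATERNAL][y] for y in years},
        "maternal_health": {y: health[MATERNAL][y] for y in years},
        "maternal_fp": {y: full[MATERNAL][y] - health[MATERNAL][y]
                        for y in years},
        "newborn_primary": {y: health[NEONATAL][y] for y in years},
        "newborn_fertility": {y: full[NEONATAL][y] - health[NEONATAL][y]
                              for y in years},
    }


_LOG_CLAMP = 1e-12


def _log_weight(spec: InterventionSpec, target_group: str, cause: str,
                cov_with: float, cov_without: float) -> float:
    """Log-residual attribution weight for one intervention and cause."""
    weight = 0.0
    for effect in spec.matching_effects(target_group, cause):
        x = effect.effectiveness * effect.affected_fraction
        fw = max(1.0 - x * cov_with, _LOG_CLAMP)
        fwo = max(1.0 - x * cov_without, _LOG_CLAMP)
        weight += math.log(fwo) - math.log(fw)
    return weight


def per_intervention_attribution(
        pair: ScenarioPair,
        specs: Mapping[str, InterventionSpec],
        _projections: Optional[Mapping[str, ProjectionResult]] = None,
) -> Dict[str, float]:
    """Share total lives saved across interventions.

    Direct-health deaths averted are shared, per target group, cause and
    year, proportionally to each intervention's log-residual change
    ``-log(1 - E*AF*cov_with) + log(1 - E*AF*cov_without)``; the shares sum
    exactly to the averted deaths.  The fertility-mediated maternal
    component is assigned to the family-planning interventions (split
    equally if several are present).  The auxiliary newborn fertility
    component is excluded, so the shares sum to the headline total
    (maternal_total + newborn_primary).
    """
    if _projections is None:
        _projections = {
            "with": run_projection(pair.with_funder, specs),
            "without": run_projection(pair.without_funder, specs),
            "health_with": run_projection(pair.health_only_with, specs),
            "health_without": run_projection(pair.health_only_without, specs),
        }
    hw = _projections["health_with"]
    hwo = _projections["health_without"]
    traj_with = pair.health_only_with.trajectory
    traj_without = pair.health_only_without.trajectory
    iids = traj_with.interventions
    out: Dict[str, float] = {iid: 0.0 for iid in iids}

    for group in TARGET_GROUPS:
        w_deaths = hw.deaths(group)
        wo_deaths = hwo.deaths(group)
        for (year, cause), wo_count in wo_deaths.items():
            averted = wo_count - w_deaths[(year, cause)]
            if averted == 0.0:
                continue
            weights = {}
            for iid in iids:
                weight = _log_weight(specs[iid], group, cause,
                                     traj_with.values[(iid, year)],
                                     traj_without.values[(iid, year)])
                if weight != 0.0:
                    weights[iid] = weight
            total_weight = sum(weights.values())
            if not weights or total_weight == 0.0:
                # coverage changes cancelled in the log scale; split equally
                # among the interventions that touch this cause
                touching = [iid for iid in iids
                            if specs[iid].matching_effects(group, cause)]
                if not touching:
                    continue
                for iid in touching:
                    out[iid] += averted / len(touching)
                continue
            for iid, weight in weights.items():
                out[iid] += averted * weight / total_weight

    # fertility-mediated maternal savings go to the family-planning specs
    full = lives_saved(_projections["with"], _projections["without"])
    health = lives_saved(hw, hwo)
    fp_total = sum(full[MATERNAL][y] - health[MATERNAL][y]
                   for y in full[MATERNAL])
    fp_iids = [iid for iid in iids if specs[iid].is_family_planning]
    if fp_iids:
        for iid in fp_iids:
            out[iid] += fp_total / len(fp_iids)
    elif abs(fp_total) > _TOL:
        logger.warning("fertility-mediated maternal savings (%.3f) with no "
                       "family-planning intervention in the unit", fp_total)
        out["<unattributed_fertility>"] = fp_total
    return out


def analyze_pair(pair: ScenarioPair,
                 specs: Mapping[str, InterventionSpec]) -> LivesSavedResult:
    """Run all four projections of a pair and assemble a LivesSavedResult."""
    projections = {
        "with": run_projection(pair.with_funder, specs),
        "without": run_projection(pair.without_funder, specs),
        "health_with": run_projection(pair.health_only_with, specs),
        "health_without": run_projection(pair.health_only_without, specs),
    }
    parts = decompose_fp_health(
        (projections["with"], projections["without"]),
        (projections["health_with"], projections["health_without"]))
    baseline_year = pair.profile.baseline_year
    result = LivesSavedResult(country_id=pair.profile.country_id,
                              baseline_year=baseline_year)
    for name in _SERIES:
        setattr(result, name, {year: v for year, v in parts[name].items()
                               if year > baseline_year})
    result.per_intervention = per_intervention_attribution(
        pair, specs, _projections=projections)
    return result
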
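"""Synthetic study-condition generators and the microsimulation oracle.

The generators emulate the heterogeneity of a donor country-office register:
coverage vs services-delivered vs commodities vs message-exposure vs
milestone indicators, achieved vs forecast provenance, national and
subnational geographies, overlapping (duplicated) reporting, centrally
managed projects and non-modelable programmes — with every injected
feature's count recorded so tests can recover it exactly.  The expected
pipeline output ships with each register, computed by the independent
closed-form re-derivation in :mod:`livessaved.truth`.

The per-birth Monte-Carlo microsimulation (:func:`microsim_oracle`) is a
stochastic re-implementation of the deterministic engine's death model and
serves as its validation oracle; it shares no computation code with the
engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model import (
    BONGAARTS_OVERLAP,
    MATERNAL,
    NEONATAL,
    REPRODUCTIVE_SPAN_YEARS,
    CountryProfile,
    CoverageTrajectory,
    Effect,
    InterventionSpec,
    LivesSavedResult,
    Scenario,
    ValidationError,
)
from .protocol import InterventionEntry, ProjectRecord, YearValue
from .truth import closed_form_truth

NEONATAL_CAUSES = ("birth_asphyxia", "prematurity", "sepsis", "pneumonia",
                   "tetanus", "other")
MATERNAL_CAUSES = ("haemorrhage", "hypertensive_disorders", "sepsis",
                   "obstructed_labour", "abortion", "other")

#: intervention ids that never map to the effectiveness library
UNMODELABLE_IDS = ("training_programme", "womens_empowerment",
                   "health_financing", "transport_vouchers")

_MAX_SEED = 2**31 - 1


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, _MAX_SEED))


# ---------------------------------------------------------------------------
# country profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileParams:
    """Bounds for the sampled country baselines (high-burden settings)."""

    nmr_range: Tuple[float, float] = (15.0, 60.0)
    mmr_range: Tuple[float, float] = (100.0, 900.0)
    tfr_range: Tuple[float, float] = (2.0, 7.0)
    n_causes_range: Tuple[int, int] = (3, 6)
    cp0_range: Tuple[float, float] = (0.05, 0.40)
    women_range: Tuple[float, float] = (300_000.0, 3_000_000.0)
    baseline_coverage_range: Tuple[float, float] = (0.10, 0.60)
    contraceptive_effectiveness_range: Tuple[float, float] = (0.85, 0.95)

    def __post_init__(self) -> None:
        bounds = {"nmr_range": (15.0, 60.0), "mmr_range": (100.0, 900.0),
                  "tfr_range": (2.0, 7.0), "n_causes_range": (3, 6)}
        for name, (lo, hi) in bounds.items():
            got_lo, got_hi = getattr(self, name)
            if got_lo < lo or got_hi > hi or got_lo > got_hi:
                raise ValidationError(
                    f"{name}={getattr(self, name)} outside [{lo}, {hi}]")


def _cause_fractions(rng: np.random.Generator,
                     pool: Sequence[str],
                     n_causes: int) -> Dict[str, float]:
    causes = [str(c) for c in rng.choice(pool, size=n_causes, replace=False)]
    weights = rng.dirichlet(np.ones(n_causes))
    weights = weights / weights.sum()
    return {cause: float(w) for cause, w in zip(causes, weights)}


def make_country_profile(seed: int,
                         params: Optional[ProfileParams] = None,
                         country_id: Optional[str] = None,
                         intervention_ids: Sequence[str] = ()) -> CountryProfile:
    """Sample a valid, reproducible country baseline."""
    params = params or ProfileParams()
    rng = np.random.default_rng(seed)
    n_lo, n_hi = params.n_causes_range
    lo_cov, hi_cov = params.baseline_coverage_range
    return CountryProfile(
        country_id=country_id or f"country_{seed}",
        tfr0=float(rng.uniform(*params.tfr_range)),
        women_reproductive_age=float(rng.uniform(*params.women_range)),
        nmr0=float(rng.uniform(*params.nmr_range)),
        mmr0=float(rng.uniform(*params.mmr_range)),
        neonatal_cause_fractions=_cause_fractions(
            rng, NEONATAL_CAUSES, int(rng.integers(n_lo, n_hi + 1))),
        maternal_cause_fractions=_cause_fractions(
            rng, MATERNAL_CAUSES, int(rng.integers(n_lo, n_hi + 1))),
        baseline_coverage={iid: float(rng.uniform(lo_cov, hi_cov))
                           for iid in intervention_ids},
        cp0=float(rng.uniform(*params.cp0_range)),
        contraceptive_effectiveness=float(
            rng.uniform(*params.contraceptive_effectiveness_range)),
    )


# ---------------------------------------------------------------------------
# intervention library
# ---------------------------------------------------------------------------

# (id, period, category, [(target_group, cause), ...])
_LIBRARY_POOL = (
    ("tetanus_toxoid", "pregnancy", "preventive",
     ((NEONATAL, "tetanus"),)),
    ("iptp_malaria", "pregnancy", "preventive",
     ((NEONATAL, "prematurity"), (MATERNAL, "other"))),
    ("itn_bednets", "pregnancy", "preventive",
     ((NEONATAL, "prematurity"),)),
    ("calcium_supplementation", "pregnancy", "preventive",
     ((MATERNAL, "hypertensive_disorders"),)),
    ("skilled_birth_attendance", "childbirth", "curative",
     ((NEONATAL, "birth_asphyxia"), (MATERNAL, "haemorrhage"),
      (MATERNAL, "obstructed_labour"))),
    ("emergency_obstetric_care", "childbirth", "curative",
     ((MATERNAL, "haemorrhage"), (MATERNAL, "sepsis"),
      (NEONATAL, "birth_asphyxia"))),
    ("clean_delivery_practices", "childbirth", "preventive",
     ((NEONATAL, "sepsis"), (MATERNAL, "sepsis"))),
    ("uterotonics", "childbirth", "curative",
     ((MATERNAL, "haemorrhage"),)),
    ("magnesium_sulfate", "childbirth", "curative",
     ((MATERNAL, "hypertensive_disorders"),)),
    ("neonatal_resuscitation", "childbirth", "curative",
     ((NEONATAL, "birth_asphyxia"),)),
    ("chlorhexidine_cord_care", "postnatal", "preventive",
     ((NEONATAL, "sepsis"),)),
    ("kangaroo_mother_care", "postnatal", "preventive",
     ((NEONATAL, "prematurity"),)),
    ("neonatal_sepsis_antibiotics", "postnatal", "curative",
     ((NEONATAL, "sepsis"), (NEONATAL, "pneumonia"))),
    ("early_breastfeeding_promotion", "postnatal", "preventive",
     ((NEONATAL, "sepsis"), (NEONATAL, "other"))),
)

FP_ID = "contraception"


def make_intervention_library(
        seed: int,
        n_interventions: Optional[int] = None) -> Dict[str, InterventionSpec]:
    """Sample 8-15 interventions spanning all periods and both categories.

    Always includes one family-planning intervention (modern contraception,
    pre-pregnancy) whose coverage is interpreted as contraceptive
    prevalence.  Effectiveness values are drawn in [0.05, 0.95], affected
    fractions in [0.5, 1].
    """
    rng = np.random.default_rng(seed)
    n = n_interventions or int(rng.integers(8, 16))
    if not 8 <= n <= 15:
        raise ValidationError("library size must lie in [8, 15]")
    while True:
        chosen = rng.choice(len(_LIBRARY_POOL), size=n - 1, replace=False)
        picked = [_LIBRARY_POOL[i] for i in sorted(chosen)]
        periods = {p[1] for p in picked} | {"pre-pregnancy"}
        categories = {p[2] for p in picked}
        if len(periods) == 4 and len(categories) == 2:
            break
    specs: Dict[str, InterventionSpec] = {}
    for iid, period, category, effect_targets in picked:
        effects = tuple(
            Effect(target_group=group, cause=cause,
                   effectiveness=float(rng.uniform(0.05, 0.95)),
                   affected_fraction=float(rng.uniform(0.5, 1.0)))
            for group, cause in effect_targets)
        specs[iid] = InterventionSpec(
            intervention_id=iid, name=iid.replace("_", " "),
            period=period, category=category, effects=effects)
    specs[FP_ID] = InterventionSpec(
        intervention_id=FP_ID, name="modern contraception",
        period="pre-pregnancy", category="preventive",
        effects=(), is_family_planning=True)
    return specs


# ---------------------------------------------------------------------------
# project register
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegisterParams:
    """Injection fractions and indicator mix for register generation.

    Defaults emulate a final-round donor register: roughly 17% of reported
    projects unanalysable (no data or not modelable), a twentieth centrally
    managed or multilateral, a sixth of countries reporting forecasts only,
    a third of projects subnational, and a modest rate of duplicated
    reporting of one activity by overlapping projects.
    """

    frac_central_multilateral: float = 0.05
    frac_unmodelable: float = 0.10
    frac_no_data: float = 0.07
    frac_duplicate: float = 0.06
    frac_subnational: float = 0.30
    frac_forecast_only_countries: float = 1.0 / 6.0
    p_fp_entry: float = 0.25
    indicator_mix: Tuple[Tuple[str, float], ...] = (
        ("coverage", 0.40), ("services_delivered", 0.25),
        ("commodities", 0.15), ("message_exposure", 0.10),
        ("milestone", 0.10))

    def __post_init__(self) -> None:
        injected = (self.frac_central_multilateral + self.frac_unmodelable
                    + self.frac_no_data + self.frac_duplicate)
        if injected >= 0.9:
            raise ValidationError(
                "injected project fractions leave too few normal projects")
        for name in ("frac_central_multilateral", "frac_unmodelable",
                     "frac_no_data", "frac_duplicate", "frac_subnational",
                     "frac_forecast_only_countries", "p_fp_entry"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name}={value} outside [0, 1]")
        total = sum(w for _, w in self.indicator_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("indicator mix must sum to 1")


@dataclass
class SyntheticTruth:
    """Independently computed expected output plus construction metadata."""

    results: Dict[str, Dict[str, LivesSavedResult]]  # mode -> country/global
    profiles: Dict[str, CountryProfile]
    library: Dict[str, InterventionSpec]
    seed: int
    n_central_multilateral: int = 0
    n_no_data: int = 0
    n_unmodelable: int = 0
    n_duplicates: int = 0
    n_duplicate_cells: int = 0
    expected_units: Dict[str, int] = field(default_factory=dict)
    countries_with_achieved: List[str] = field(default_factory=list)


def _entry_values(rng: np.random.Generator,
                  years: Sequence[int],
                  baseline: float,
                  achieved_through: Optional[int],
                  slope_range: Tuple[float, float] = (0.02, 0.10),
                  cap: float = 0.95) -> Dict[int, YearValue]:
    """Rising coverage path with achieved/forecast provenance split."""
    slope = rng.uniform(*slope_range)
    values: Dict[int, YearValue] = {}
    for year in years:
        cov = min(cap, baseline + slope * (year - 2010))
        yv = YearValue()
        if achieved_through is not None and year <= achieved_through:
            yv.achieved = round(float(cov), 6)
        else:
            yv.forecast = round(float(cov), 6)
        values[year] = yv
    return values


def make_project_register(
        seed: int,
        n_countries: int = 24,
        n_projects: int = 182,
        params: Optional[RegisterParams] = None,
) -> Tuple[List[ProjectRecord], SyntheticTruth]:
    """Generate a register with known injected features and ground truth.

    Returns the register and a :class:`SyntheticTruth` whose expected
    results (achieved and forecast modes, per country and global) come from
    the independent closed-form re-derivation, and whose metadata records
    every injected feature so screening, grouping and merge bookkeeping can
    be verified exactly.
    """
    params = params or RegisterParams()
    if n_countries < 1 or n_projects < n_countries:
        raise ValidationError("need at least one project per country")
    rng = np.random.default_rng(seed)
    library = make_intervention_library(_child_seed(rng))
    non_fp_ids = sorted(iid for iid in library if iid != FP_ID)

    countries = [f"C{i:02d}" for i in range(n_countries)]
    profiles = {cid: make_country_profile(_child_seed(rng), country_id=cid,
                                          intervention_ids=non_fp_ids)
                for cid in countries}
    n_forecast_only = round(params.frac_forecast_only_countries * n_countries)
    forecast_only = set(rng.choice(countries, size=n_forecast_only,
                                   replace=False)) if n_forecast_only else set()
    geographies = {cid: {f"{cid}_north": float(rng.uniform(0.15, 0.40)),
                         f"{cid}_south": float(rng.uniform(0.15, 0.40))}
                   for cid in countries}

    n_multi = round(params.frac_central_multilateral * n_projects)
    n_unmod = round(params.frac_unmodelable * n_projects)
    n_nodata = round(params.frac_no_data * n_projects)
    n_dup = round(params.frac_duplicate * n_projects)
    n_normal = n_projects - n_multi - n_unmod - n_nodata - n_dup
    if n_normal < max(n_dup, n_countries):
        raise ValidationError("injection fractions leave too few normal "
                              "projects for the requested register")

    mix_labels = [label for label, _ in params.indicator_mix]
    mix_weights = np.array([w for _, w in params.indicator_mix])
    register: List[ProjectRecord] = []
    normals: List[ProjectRecord] = []
    # fragment bookkeeping for exact duplicate-cell recovery:
    # (country, geography, iid, year) -> count among eligible projects
    fragment_counts: Dict[Tuple[str, str, str, int], int] = {}

    def _geography(cid: str) -> Tuple[str, float]:
        if rng.uniform() < params.frac_subnational:
            geo = str(rng.choice(sorted(geographies[cid])))
            return geo, geographies[cid][geo]
        return "national", 1.0

    def _project_shell(idx: int, cid: str,
                       management: str = "bilateral") -> dict:
        geo, share = _geography(cid)
        start = int(rng.integers(2011, 2014))
        end = int(min(2015, start + rng.integers(1, 5)))
        return {"project_id": f"P{idx:04d}", "country_id": cid,
                "management": management, "start_year": start,
                "end_year": end,
                "total_funding": float(rng.uniform(1e6, 3e7)),
                "attribution": round(float(rng.uniform(0.2, 0.8)), 2),
                "geography_id": geo, "population_share": share}

    def _make_entry(profile: CountryProfile, iid: str,
                    start: int, end: int,
                    achieved_through: Optional[int]) -> InterventionEntry:
        years = list(range(start, end + 1))
        spec = library[iid]
        if spec.is_family_planning:
            base = profile.cp0
            path = _entry_values(rng, years, base, achieved_through,
                                 slope_range=(0.01, 0.04), cap=0.60)
            return InterventionEntry(iid, "coverage", path)
        base = profile.baseline_coverage.get(iid, 0.0)
        indicator = str(rng.choice(mix_labels, p=mix_weights))
        if indicator == "milestone":
            flag_year = int(rng.choice(years))
            yv = YearValue()
            if achieved_through is not None and flag_year <= achieved_through:
                yv.achieved = 1.0
            else:
                yv.forecast = 1.0
            return InterventionEntry(iid, "milestone", {flag_year: yv})
        path = _entry_values(rng, years, base, achieved_through)
        if indicator == "coverage":
            return InterventionEntry(iid, "coverage", path)
        target = float(rng.integers(20_000, 500_000))
        scaled: Dict[int, YearValue] = {}
        overshoot = (indicator == "commodities" and rng.uniform() < 0.05)
        for year, yv in path.items():
            factor = 1.2 if overshoot else 1.0
            out = YearValue()
            if yv.achieved is not None:
                out.achieved = round(yv.achieved * factor * target, 3)
            if yv.forecast is not None:
                out.forecast = round(yv.forecast * factor * target, 3)
            scaled[year] = out
        return InterventionEntry(iid, indicator, scaled,
                                 target_population=target)

    idx = 0
    # normal, modelable bilateral projects (round-robin over countries)
    for k in range(n_normal):
        cid = countries[k % n_countries]
        shell = _project_shell(idx, cid)
        idx += 1
        profile = profiles[cid]
        achieved_through = None
        if cid not in forecast_only:
            achieved_through = int(rng.integers(shell["start_year"],
                                                min(shell["end_year"], 2014)
                                                + 1))
        n_entries = int(rng.integers(1, 4))
        entry_ids = [str(i) for i in rng.choice(non_fp_ids, size=n_entries,
                                                replace=False)]
        if rng.uniform() < params.p_fp_entry:
            entry_ids[0] = FP_ID
        entries = [_make_entry(profile, iid, shell["start_year"],
                               shell["end_year"], achieved_through)
                   for iid in entry_ids]
        project = ProjectRecord(**shell, entries=entries)
        normals.append(project)
        register.append(project)
        for entry in entries:
            if entry.indicator_type == "milestone":
                continue
            for year in entry.annual_values:
                key = (cid, shell["geography_id"],
                       entry.intervention_id, year)
                fragment_counts[key] = fragment_counts.get(key, 0) + 1

    # duplicate reporting of a single activity by an overlapping project
    dup_candidates = [i for i, p in enumerate(normals)
                      if any(e.indicator_type != "milestone"
                             for e in p.entries)]
    if len(dup_candidates) < n_dup:
        raise ValidationError("too few coverage-bearing projects to "
                              "duplicate")
    dup_sources = rng.choice(dup_candidates, size=n_dup, replace=False)
    for k in sorted(int(i) for i in dup_sources):
        source = normals[k]
        entry = next(e for e in source.entries
                     if e.indicator_type != "milestone")
        scale = float(rng.uniform(0.5, 0.9))
        annual: Dict[int, YearValue] = {}
        for year, yv in entry.annual_values.items():
            out = YearValue()
            if yv.achieved is not None:
                out.achieved = round(yv.achieved * scale, 6)
            if yv.forecast is not None:
                out.forecast = round(yv.forecast * scale, 6)
            annual[year] = out
        dup_entry = InterventionEntry(entry.intervention_id,
                                      entry.indicator_type, annual,
                                      target_population=entry.target_population)
        register.append(ProjectRecord(
            project_id=f"P{idx:04d}", country_id=source.country_id,
            management="bilateral", start_year=source.start_year,
            end_year=source.end_year,
            total_funding=float(rng.uniform(5e5, 5e6)),
            attribution=source.attribution,
            geography_id=source.geography_id,
            population_share=source.population_share,
            entries=[dup_entry]))
        idx += 1
        for year in annual:
            key = (source.country_id, source.geography_id,
                   entry.intervention_id, year)
            fragment_counts[key] = fragment_counts.get(key, 0) + 1

    # centrally managed / multilateral projects (excluded at screening)
    for k in range(n_multi):
        cid = countries[int(rng.integers(0, n_countries))]
        management = "multilateral" if k % 2 == 0 else "central_multicountry"
        shell = _project_shell(idx, cid, management=management)
        idx += 1
        iid = str(rng.choice(non_fp_ids))
        achieved_through = (None if cid in forecast_only
                            else shell["start_year"])
        entries = [_make_entry(profiles[cid], iid, shell["start_year"],
                               shell["end_year"], achieved_through)]
        register.append(ProjectRecord(**shell, entries=entries))

    # projects with no intervention compatible with the library
    for _ in range(n_unmod):
        cid = countries[int(rng.integers(0, n_countries))]
        shell = _project_shell(idx, cid)
        idx += 1
        iid = str(rng.choice(UNMODELABLE_IDS))
        years = list(range(shell["start_year"], shell["end_year"] + 1))
        annual = {}
        for year in years:
            value = round(float(rng.uniform(0.1, 0.9)), 6)
            annual[year] = (YearValue(forecast=value)
                            if cid in forecast_only
                            else YearValue(achieved=value))
        register.append(ProjectRecord(
            **shell, entries=[InterventionEntry(iid, "coverage", annual)]))

    # projects registered with no data yet
    for _ in range(n_nodata):
        cid = countries[int(rng.integers(0, n_countries))]
        shell = _project_shell(idx, cid)
        idx += 1
        register.append(ProjectRecord(**shell, entries=[]))

    truth = SyntheticTruth(
        results={mode: closed_form_truth(register, profiles, library, mode)
                 for mode in ("achieved", "forecast")},
        profiles=profiles, library=library, seed=seed,
        n_central_multilateral=n_multi,
        n_no_data=n_nodata,
        n_unmodelable=n_unmod,
        n_duplicates=n_dup,
        n_duplicate_cells=sum(1 for c in fragment_counts.values() if c > 1),
        expected_units={cid: len({(p.country_id, p.geography_id)
                                  for p in normals + register[len(normals):
                                                              len(normals)
                                                              + n_dup]
                                  if p.country_id == cid})
                        for cid in countries},
        countries_with_achieved=sorted(set(countries) - forecast_only),
    )
    return register, truth


# ---------------------------------------------------------------------------
# random single scenarios (for engine-vs-microsim checks)
# ---------------------------------------------------------------------------


def make_random_scenario(
        seed: int) -> Tuple[Scenario, Dict[str, InterventionSpec]]:
    """A random with-funder scenario over the full projection window."""
    rng = np.random.default_rng(seed)
    library = make_intervention_library(_child_seed(rng))
    non_fp = sorted(iid for iid in library if iid != FP_ID)
    profile = make_country_profile(_child_seed(rng),
                                   intervention_ids=non_fp)
    years = profile.years
    used = [str(i) for i in rng.choice(non_fp, size=int(rng.integers(3, 7)),
                                       replace=False)] + [FP_ID]
    values: Dict[Tuple[str, int], float] = {}
    cp: Dict[int, float] = {}
    for iid in used:
        base = (profile.cp0 if iid == FP_ID
                else profile.baseline_coverage.get(iid, 0.0))
        slope = rng.uniform(0.01, 0.04) if iid == FP_ID else rng.uniform(
            0.02, 0.10)
        for year in years:
            cov = min(0.95, base + slope * (year - profile.baseline_year))
            values[(iid, year)] = float(cov)
            if iid == FP_ID:
                cp[year] = float(cov)
    scenario = Scenario(profile=profile,
                        trajectory=CoverageTrajectory(values=values, cp=cp),
                        label="with_funder", population_share=1.0)
    return scenario, library


# ---------------------------------------------------------------------------
# Monte-Carlo microsimulation oracle
# ---------------------------------------------------------------------------


@dataclass
class MicrosimResult:
    """Per-birth simulation estimate of a projection, with standard errors."""

    country_id: str
    births: Dict[int, float]
    neonatal_deaths: Dict[Tuple[int, str], float]
    maternal_deaths: Dict[Tuple[int, str], float]
    neonatal_se: Dict[Tuple[int, str], float]
    maternal_se: Dict[Tuple[int, str], float]

    def deaths(self, group: str) -> Dict[Tuple[int, str], float]:
        return (self.neonatal_deaths if group == NEONATAL
                else self.maternal_deaths)

    def se(self, group: str) -> Dict[Tuple[int, str], float]:
        return self.neonatal_se if group == NEONATAL else self.maternal_se


def microsim_oracle(scenario: Scenario,
                    specs: Mapping[str, InterventionSpec],
                    n_births_per_year: int = 200_000,
                    seed: int = 0) -> MicrosimResult:
    """Per-birth Monte-Carlo estimate of the deterministic projection.

    Each simulated birth draws its cause-specific death from the baseline
    rate times the cause fraction; every matching intervention effect then
    draws a coverage-exposure Bernoulli and, if exposed, averts the death
    with probability effectiveness x affected_fraction.  Counts are
    normalized by the baseline-residual denominator exactly as the engine's
    are, so agreement checks the engine's multiplicative cascade, not just
    its scale.
    """
    if n_births_per_year < 1:
        raise ValidationError("n_births_per_year must be at least 1")
    rng = np.random.default_rng(seed)
    profile = scenario.profile
    traj = scenario.trajectory
    years = traj.years

    # births via the closed demographic form (local re-derivation)
    eff = profile.contraceptive_effectiveness
    base_index = 1.0 - BONGAARTS_OVERLAP * profile.cp0 * eff
    cohort0 = (profile.women_reproductive_age * profile.tfr0
               / REPRODUCTIVE_SPAN_YEARS)
    births = {year: cohort0 * (1.0 - BONGAARTS_OVERLAP * traj.cp[year] * eff)
              / base_index * scenario.population_share
              for year in years}

    used = traj.interventions
    deaths = {NEONATAL: {}, MATERNAL: {}}
    ses = {NEONATAL: {}, MATERNAL: {}}
    group_tables = ((NEONATAL, profile.neonatal_cause_fractions,
                     profile.nmr0 / 1000.0),
                    (MATERNAL, profile.maternal_cause_fractions,
                     profile.mmr0 / 100000.0))
    for group, cause_fractions, rate in group_tables:
        for cause, frac in cause_fractions.items():
            p0 = rate * frac
            r_base = 1.0
            matching: List[Tuple[str, float]] = []
            for iid in used:
                for effect in specs[iid].effects:
                    if (effect.target_group, effect.cause) != (group, cause):
                        continue
                    x = effect.effectiveness * effect.affected_fraction
                    matching.append((iid, x))
                    r_base *= (1.0 - x
                               * profile.baseline_coverage.get(iid, 0.0))
            for year in years:
                n = n_births_per_year
                at_risk = int((rng.random(n) < p0).sum())
                averted = np.zeros(at_risk, dtype=bool)
                for iid, x in matching:
                    cov = traj.values[(iid, year)]
                    exposed = rng.random(at_risk) < cov
                    averted |= exposed & (rng.random(at_risk) < x)
                died = at_risk - int(averted.sum())
                p_hat = died / n
                scale = births[year] / r_base
                deaths[group][(year, cause)] = p_hat * scale
                ses[group][(year, cause)] = (
                    math.sqrt(p_hat * (1.0 - p_hat) / n) * scale)
    return MicrosimResult(country_id=profile.country_id, births=births,
                          neonatal_deaths=deaths[NEONATAL],
                          maternal_deaths=deaths[MATERNAL],
                          neonatal_se=ses[NEONATAL],
                          maternal_se=ses[MATERNAL])
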
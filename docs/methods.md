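# Methods

## Model

The engine is a deterministic annual cohort model over a 2010 baseline and
a 2015 horizon.

**Births.** The annual birth cohort is `W × TFR₀ / 35` (women of
reproductive age times total fertility rate over a fixed 35-year
reproductive span), scaled each year by the ratio of the Bongaarts index of
contraception `C = 1 − 1.08·u·e` at the year's contraceptive prevalence to
its baseline value. This is the simplest proximate-determinants form
consistent with how family-planning modules link prevalence to fertility.
Women of reproductive age are held constant over the five-year window; the
1.08 overlap factor is the standard adjustment for contraceptive use among
fecund women. Parameters that imply a non-positive index are rejected.

**Deaths.** Cause-specific deaths are
`births × rate₀ × frac_c × R(cov_t)/R(cov₂₀₁₀)` with
`R(cov) = ∏ (1 − E·AF·cov)` over every intervention effect matching the
target group and cause. The ratio normalization makes the no-change
scenario reproduce baseline mortality exactly and keeps the model's
behaviour linear in any single intervention's coverage while bounding
combined effects below 100%. The continuum-of-care ordering
(pre-pregnancy → pregnancy → childbirth → postnatal, preventive before
curative) is retained for reporting only: the product is exactly
order-invariant, so "sequential application" is a presentation device, not
a numerical one. A baseline residual of zero (an effectiveness-1 effect
already at full coverage) is an error, since the normalization is then
undefined.

**Maternal risk is per live birth** (the MMR base), so fertility declines
reduce maternal deaths mechanically; per-pregnancy refinements (abortion
and stillbirth denominators) are out of scope. Neonatal risk is per live
birth by definition of the NMR.

**Decomposition.** Each analysis runs two scenario pairs. The primary pair
varies everything; the secondary pair holds contraceptive prevalence (and
family-planning coverage) at the with-funder values in both members.
Direct-health impact is the secondary pair's difference; family-planning
impact is the remainder of the primary pair, which deliberately folds the
FP × health interaction into the FP component (one isolated choice, easy
to revisit). Newborn lives saved via fertility reduction are computed and
reported but excluded from headline totals and attribution — fewer births
is not the sense of "newborn lives saved" a funder reports.

**Attribution across interventions.** Within the direct-health component,
deaths averted per (group, cause, year) are shared proportionally to each
intervention's log-residual change `log(1−E·AF·cov_cf) − log(1−E·AF·cov)`.
Log shares are exact for the multiplicative cascade (factors add in log
space) and always sum to the averted deaths; a leave-one-out recomputation
gives slightly different splits but the same total, which the tests check.
The fertility-mediated maternal component goes to the family-planning
interventions, split equally if a unit has several. Negative lives saved
(a with-funder scenario worse than its counterfactual) are reported with a
warning, never clipped.

## Register protocol

- **Screening.** Centrally managed and multilateral projects are excluded
  (double-counting risk), as are projects with no reported values and
  projects none of whose interventions map to the effectiveness library.
  Screening partitions the register; it never hard-fails.
- **Grouping.** Projects sharing a geography label within a country form
  one analysis unit; `national` projects form the national unit with
  population share 1, subnational units carry their stated share
  (conflicting shares are an error). Partially overlapping geographies
  beyond shared labels are out of scope (no GIS).
- **Indicator conversion.** Coverage passes through; services delivered
  and commodities divide by the target population (assuming all supplies
  reach their targets) and clip to [0, 1] with a warning; message exposure
  additionally multiplies by a behaviour-change conversion factor
  (default 1.0, configurable to model drop-off between hearing a message
  and acting on it); milestones are 0/1 flags with no coverage, reported
  only.
- **Provenance.** Achieved values win over forecasts wherever both exist.
  Achieved mode truncates each unit's horizon at its latest achieved year;
  forecast mode extends to 2015 using forecasts where achieved values are
  absent. A unit with no achieved value at all is unusable in achieved
  mode and is skipped with a logged warning (countries can report without
  being analysable), while all other errors propagate.
- **Counterfactual.** `cov_cf = cov₀ + (1 − a)·(cov − cov₀)` per project
  fragment, with the project's attribution fraction `a` (a per-entry
  override is supported). This reproduces both limiting behaviours —
  attribution 1 recovers the baseline, attribution 0 removes the project —
  and never crosses the 2010 baseline.
- **De-duplication.** Overlapping fragments for one
  (intervention, geography, year) merge by the **maximum**, never the sum —
  conservative against double-counting one activity reported by several
  projects. The with-funder and counterfactual values are merged
  independently, each by its own maximum.
- **Trajectories.** Reported values are carried forward between reporting
  years, starting from the 2010 baseline coverage (profile value; the
  baseline contraceptive prevalence for family-planning entries). Years
  are calendar years; lives saved are summed strictly over 2011–horizon.

## Reporting

The mortality-source sensitivity reruns the whole pipeline with only
NMR/MMR substituted (IGME is the default label when present, else the
first source). Because coverage is unchanged, newborn totals scale exactly
linearly with the substituted NMR and maternal totals with the MMR — an
assertable property, used as a test. Ranges are computed per source label
after summation (sum-then-range), not as sums of per-country minima.
Inclusion percentages round half away from zero to integers. Output CSVs
are deterministically ordered and round-trip exactly.

## Synthetic study conditions

`make_project_register` defaults emulate a final analysis round: 24
countries and 182 reported projects, with ~5% centrally
managed/multilateral, ~10% not modelable (training and empowerment
programmes), ~7% with no data (≈78% analysed), 6% duplicate reporting of
an existing activity, ~30% subnational projects (two subnational
geographies per country), and a sixth of countries reporting forecasts
only (≈83% of countries with achieved data). The indicator mix is 40%
coverage, 25% services delivered, 15% commodities, 10% message exposure
and 10% milestones; no published breakdown exists, so these were fixed
once as a plausible register composition. Coverage paths rise a few
percentage points per year from the sampled baselines; attribution
fractions are uniform on [0.2, 0.8]. Country baselines are sampled in
high-burden ranges (NMR 15–60, MMR 100–900, TFR 2–7, contraceptive
prevalence 5–40%) with Dirichlet cause-of-death fractions over fixed
neonatal and maternal cause pools, and the intervention library samples
8–15 entries spanning the four periods and both categories, always
including modern contraception as the family-planning entry.

What the generator does **not** emulate: real country calibration,
reporting noise and revisions between rounds, partially overlapping
geographies, sector-specific attribution practice, or correlation between
funding size and coverage change. Passing tests therefore demonstrate that
the pipeline computes its defined quantities correctly under the
template's structural heterogeneity — not that the model is a validated
estimate of any real portfolio's impact.

## Oracles

Two independent checks guard the implementation:

1. **Closed-form truth** (`livessaved.truth`) recomputes the full expected
   output of a register — screening through attribution — with plain
   loops, sharing only data containers with the pipeline. The pipeline
   must agree within 1e-6 absolute on every annual series; the suite
   checks twenty seeded registers (2 countries × 12 projects each, both
   run modes), a size chosen to keep the check exhaustive yet quick.
2. **Per-birth microsimulation** (`microsim_oracle`) draws each simulated
   birth's cause-specific death and, per matching intervention effect, a
   coverage-exposure Bernoulli and an aversion Bernoulli, normalized by
   the same baseline-residual denominator as the engine. One exposure is
   drawn per *effect* so the expectation matches the engine's product form
   exactly even for multi-effect interventions. The suite compares ten
   random scenarios at 200,000 simulated births per year and requires
   agreement within three combined standard errors per target group, with
   fixed seeds for reproducibility.

## Numerical choices and degenerate inputs

- Conservation assertions (attribution sums, FP + health = total,
  aggregation additivity) use 1e-6 absolute tolerance on counts;
  structural validations use 1e-9.
- Log-share weights clamp residual factors at 1e-12 before taking logs; a
  zero total weight with nonzero averted deaths (possible only through
  cancellation) falls back to an equal split among the interventions
  touching that cause.
- Cause-fraction maps must sum to 1 within 1e-9; coverage, prevalence,
  attribution and shares are validated into their unit ranges at
  construction.
- Affected fraction defaults to 1.0 when a library entry omits it.
- Duplicate register rows for one (project, intervention, year,
  provenance) keep the maximum, consistent with the merge rule.

## Limitations

Beyond the generator's simplifications above: the intervention library is
a compact configurable stand-in for a full effectiveness database;
stillbirths, child (1–59 months) mortality, HIV programme linkage,
nutrition pathways and quality-of-care adjustments are out of scope; no
uncertainty intervals are produced beyond the mortality-source range; and
whether counterfactual coverage should ever fall below the 2010 baseline
is unresolved in the protocol — this implementation never lets it.
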
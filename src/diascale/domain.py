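"""Domain types for the diarrheal-mortality scale-up analysis.

The analysis projects annual diarrheal deaths among children under five for a
set of countries over 2010-2015, under scenarios in which coverage of ten
prevention and treatment interventions rises linearly from country baselines
to scenario targets.  These types carry the inputs (country demography and
baseline mortality, intervention parameters, coverage, breastfeeding practice
prevalences) and the outputs (deaths, deaths averted, costs).

Conventions
-----------
* Coverage is stored in **percent** (as published) at every I/O boundary and
  converted to a proportion in [0, 1] exactly once, on entry to the engine
  (:func:`diascale.scaleup.build_trajectories`).
* Ages are in completed months.  Deaths are distributed over five age bands
  ``0mo, 1-5mo, 6-11mo, 12-23mo, 24-59mo``; breastfeeding practice is
  tracked over three bands ``0-5mo, 6-11mo, 12-23mo``.
* Deaths are kept as unrounded floats internally; rounding to whole persons
  happens only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

#: Projection horizon: 2010 is both the baseline year and the first projection
#: year; scale-up completes in 2015.
START_YEAR = 2010
END_YEAR = 2015
YEARS = tuple(range(START_YEAR, END_YEAR + 1))

#: Age bands over which diarrheal deaths are distributed, as (lo, hi) in
#: completed months, inclusive.
AGE_BANDS: Dict[str, tuple] = {
    "0mo": (0, 0),
    "1-5mo": (1, 5),
    "6-11mo": (6, 11),
    "12-23mo": (12, 23),
    "24-59mo": (24, 59),
}

#: Age bands for which breastfeeding practice is tracked, and the mapping from
#: death band to breastfeeding band (None: no breastfeeding effect).
BF_BANDS = ("0-5mo", "6-11mo", "12-23mo")
BF_CATEGORIES = ("exclusive", "predominant", "partial", "none")
DEATH_BAND_TO_BF_BAND: Dict[str, Optional[str]] = {
    "0mo": "0-5mo",
    "1-5mo": "0-5mo",
    "6-11mo": "6-11mo",
    "12-23mo": "12-23mo",
    "24-59mo": None,
}

#: Default distribution of baseline diarrheal deaths over age bands.  The
#: published cause-of-death profiles do not break deaths down by month band,
#: so this is a documented configurable reflecting the concentration of
#: diarrheal mortality in the post-neonatal period.
DEFAULT_AGE_BAND_DEATH_SHARES: Dict[str, float] = {
    "0mo": 0.05,
    "1-5mo": 0.25,
    "6-11mo": 0.30,
    "12-23mo": 0.25,
    "24-59mo": 0.15,
}

Region = Literal["Africa", "Asia", "Other"]

_SHARE_TOL = 1e-9


class CountryProfile(BaseModel):
    """Demography and baseline diarrheal mortality for one country.

    ``baseline_diarrheal_deaths`` is the annual number of under-5 diarrheal
    deaths at baseline (2010) coverage; absent any coverage change it is held
    constant through 2015, so population growth affects only per-capita cost
    denominators.
    """

    model_config = ConfigDict(frozen=True)

    country_id: str
    region: Region
    total_population: Dict[int, float]
    under5_population: Dict[int, float]
    baseline_diarrheal_deaths: float = Field(ge=0)
    age_band_death_shares: Dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_AGE_BAND_DEATH_SHARES)
    )
    vitamin_a_deficient: bool = True

    @model_validator(mode="after")
    def _check_invariants(self) -> "CountryProfile":
        for year in YEARS:
            if year not in self.total_population or year not in self.under5_population:
                raise ValueError(f"{self.country_id}: missing population for year {year}")
        for year, pop in self.total_population.items():
            if pop <= 0:
                raise ValueError(f"{self.country_id}: total population must be > 0 in {year}")
        for year, pop in self.under5_population.items():
            if pop <= 0:
                raise ValueError(f"{self.country_id}: under-5 population must be > 0 in {year}")
            if pop > self.total_population[year]:
                raise ValueError(
                    f"{self.country_id}: under-5 population exceeds total population in {year}"
                )
        if set(self.age_band_death_shares) != set(AGE_BANDS):
            raise ValueError(
                f"{self.country_id}: age band shares must cover exactly {sorted(AGE_BANDS)}"
            )
        if any(s < 0 for s in self.age_band_death_shares.values()):
            raise ValueError(f"{self.country_id}: age band shares must be non-negative")
        total = sum(self.age_band_death_shares.values())
        if abs(total - 1.0) > _SHARE_TOL:
            raise ValueError(
                f"{self.country_id}: age band death shares sum to {total}, expected 1"
            )
        return self


class InterventionSpec(BaseModel):
    """Effectiveness and scope parameters for one intervention.

    ``effectiveness`` (E) is the proportional reduction in diarrheal deaths
    among children the intervention reaches and can affect; the
    ``affected_fraction`` (A) is the share of diarrheal deaths it can act on
    at all (e.g. rotavirus vaccine acts only on the ~39% of diarrheal deaths
    attributable to rotavirus).  The age range bounds which death bands the
    intervention applies to.
    """

    model_config = ConfigDict(frozen=True)

    intervention_id: str
    effectiveness: float = Field(ge=0, le=1)
    affected_fraction: float = Field(ge=0, le=1)
    age_min_months: int = Field(ge=0, le=59)
    age_max_months: int = Field(ge=0, le=59)
    is_wash: bool = False
    is_treatment: bool = False

    def covers_band(self, band: str) -> bool:
        lo, hi = AGE_BANDS[band]
        return self.age_min_months <= lo and hi <= self.age_max_months


class CoverageRecord(BaseModel):
    """Baseline coverage (percent) of one intervention in one country.

    Countries not considered vitamin-A deficient carry ``excluded=True`` for
    the vitamin A row: the intervention is skipped entirely for them rather
    than treated as zero coverage.
    """

    model_config = ConfigDict(frozen=True)

    country_id: str
    intervention_id: str
    year: int = START_YEAR
    coverage: Optional[float] = None
    excluded: bool = False

    @model_validator(mode="after")
    def _check(self) -> "CoverageRecord":
        if self.excluded:
            if self.coverage is not None:
                raise ValueError("excluded coverage record must not carry a value")
        else:
            if self.coverage is None:
                raise ValueError(
                    f"({self.country_id}, {self.intervention_id}): coverage value required"
                )
            if not 0 <= self.coverage <= 100:
                raise ValueError(
                    f"({self.country_id}, {self.intervention_id}): "
                    f"coverage {self.coverage} outside [0, 100]"
                )
        return self


class BreastfeedingState(BaseModel):
    """Breastfeeding practice prevalences (proportions) per age band.

    Each band's prevalences over the four exclusivity categories sum to 1.
    The relative risks attached to the categories live in the parameter
    fixture (:func:`diascale.fixtures.load_breastfeeding_rr`), not here.
    """

    model_config = ConfigDict(frozen=True)

    prevalence: Dict[str, Dict[str, float]]

    @model_validator(mode="after")
    def _check(self) -> "BreastfeedingState":
        for band in BF_BANDS:
            if band not in self.prevalence:
                raise ValueError(f"missing breastfeeding band {band}")
            p = self.prevalence[band]
            if set(p) != set(BF_CATEGORIES):
                raise ValueError(
                    f"band {band}: categories must be exactly {sorted(BF_CATEGORIES)}"
                )
            if any(v < 0 for v in p.values()):
                raise ValueError(f"band {band}: prevalences must be non-negative")
            total = sum(p.values())
            if abs(total - 1.0) > _SHARE_TOL:
                raise ValueError(f"band {band}: prevalences sum to {total}, expected 1")
        return self


class ScenarioSpec(BaseModel):
    """Coverage targets for one scale-up scenario.

    ``target_coverage`` maps intervention id to the 2015 target in percent;
    ``regional_targets`` overrides it per region where the published targets
    are region-specific (ambitious safe water).  The ``baseline`` scenario
    carries no targets: coverage is held at its 2010 value.
    ``breastfeeding_targets`` gives percent prevalence targets for the named
    categories per band; the ``none`` category is the residual.
    """

    model_config = ConfigDict(frozen=True)

    name: Literal["baseline", "ambitious", "universal"]
    target_coverage: Dict[str, float] = Field(default_factory=dict)
    regional_targets: Dict[str, Dict[str, float]] = Field(default_factory=dict)
    breastfeeding_targets: Dict[str, Dict[str, float]] = Field(default_factory=dict)
    start_year: int = START_YEAR
    end_year: int = END_YEAR

    @model_validator(mode="after")
    def _check(self) -> "ScenarioSpec":
        for iid, t in self.target_coverage.items():
            if not 0 <= t <= 100:
                raise ValueError(f"target for {iid} outside [0, 100]: {t}")
        for iid, per_region in self.regional_targets.items():
            for region, t in per_region.items():
                if not 0 <= t <= 100:
                    raise ValueError(f"target for {iid}/{region} outside [0, 100]: {t}")
        for band, cats in self.breastfeeding_targets.items():
            if any(not 0 <= v <= 100 for v in cats.values()):
                raise ValueError(f"breastfeeding targets for {band} outside [0, 100]")
            if sum(cats.values()) > 100 + 1e-9:
                raise ValueError(
                    f"breastfeeding targets for {band} sum above 100: {cats}"
                )
        return self

    def target_for(self, intervention_id: str, region: str) -> Optional[float]:
        """2015 target in percent for an intervention in a region, or None
        when the scenario holds baseline coverage (no target defined)."""
        if intervention_id in self.regional_targets:
            per_region = self.regional_targets[intervention_id]
            if region in per_region:
                return per_region[region]
        return self.target_coverage.get(intervention_id)


@dataclass
class ProjectionResult:
    """Projected deaths and deaths averted per country x year x scenario.

    ``deaths`` is a tidy frame with columns
    ``country_id, year, scenario, deaths, deaths_averted`` where
    ``deaths_averted`` compares against the baseline-continuation scenario.
    """

    deaths: pd.DataFrame

    def proportion_of_baseline(self) -> pd.DataFrame:
        """Annual total deaths relative to the 2010 baseline, per scenario."""
        totals = self.deaths.groupby(["scenario", "year"], as_index=False)["deaths"].sum()
        base = totals.loc[totals["year"] == START_YEAR].set_index("scenario")["deaths"]
        totals["proportion_of_baseline"] = totals.apply(
            lambda r: r["deaths"] / base[r["scenario"]], axis=1
        )
        return totals


@dataclass
class CostResult:
    """Ingredients-based costs per country x year x scenario.

    ``costs`` has columns ``country_id, year, scenario, non_wash_cost,
    wash_cost, total_cost`` in currency units (default USD); the WASH stream
    (water, sanitation, hygiene interventions) is kept separate from
    individual-level prevention and treatment throughout.
    """

    costs: pd.DataFrame
    currency: str = "USD"


def validate_profile(profile: CountryProfile) -> CountryProfile:
    """Re-assert every invariant on a profile and return it.

    Profiles validate on construction; this entry point exists for data read
    back from disk or constructed via ``model_construct``.  Violations raise
    ``pydantic.ValidationError`` enumerating every failed constraint.
    """
    return CountryProfile.model_validate(profile.model_dump())
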
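"""Seeded synthetic inputs mirroring the structure of the published tables.

The projection engine is deterministic given its inputs, so these generators
aim for structural fidelity, not distributional realism: coverage is sampled
uniformly within each intervention's published min-max span, demography and
baseline mortality within plausible high-burden-country ranges, and
breastfeeding practice mixes from a Dirichlet on the four exclusivity
categories.  Cross-country correlations present in real data (e.g. between
water and sanitation coverage) are not modeled.

A single integer seed governs everything through named sub-streams (one RNG
per quantity, keyed by a stable hash of the stream name), so adding a new
generator later does not perturb existing draws.
"""

from __future__ import annotations

import hashlib
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .domain import (
    AGE_BANDS,
    BF_BANDS,
    DEFAULT_AGE_BAND_DEATH_SHARES,
    END_YEAR,
    START_YEAR,
    YEARS,
    BreastfeedingState,
    CountryProfile,
    CoverageRecord,
    InterventionSpec,
    ScenarioSpec,
)
from .engine import reduction_factor
from .fixtures import INTERVENTION_IDS
from .scaleup import interpolate_linear

#: Per-intervention baseline coverage spans (percent), matching the min-max
#: observed across the 68 published country rows.
DEFAULT_COVERAGE_RANGES: Dict[str, Tuple[float, float]] = {
    "improved_water": (30, 100),
    "treated_water": (2, 92),
    "improved_sanitation": (9, 95),
    "handwashing": (3, 42),
    "ors": (4, 86),
    "antibiotics_dysentery": (5, 82),
    "zinc": (0, 23),
    "rotavirus": (0, 71),
    "vitamin_a": (0, 100),
}

#: Region mix of the 68 priority countries (44 Africa, 18 Asia, 6 Other).
DEFAULT_REGION_MIX: Dict[str, float] = {
    "Africa": 44 / 68,
    "Asia": 18 / 68,
    "Other": 6 / 68,
}


class GeneratorConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_countries: int = Field(default=68, ge=1)
    seed: int = 0
    coverage_ranges: Dict[str, Tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_COVERAGE_RANGES)
    )
    #: under-5 population span, persons
    under5_range: Tuple[float, float] = (200_000.0, 25_000_000.0)
    #: under-5 share of total population
    under5_fraction_range: Tuple[float, float] = (0.12, 0.18)
    #: annual population growth
    growth_rate_range: Tuple[float, float] = (0.01, 0.03)
    #: annual diarrheal deaths per 1000 under-5 children
    diarrhea_mortality_range: Tuple[float, float] = (0.2, 4.0)
    region_mix: Dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_REGION_MIX))
    #: probability a country is not vitamin-A deficient (excluded)
    vitamin_a_na_probability: float = Field(default=1 / 68, ge=0, le=1)
    age_band_death_shares: Dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_AGE_BAND_DEATH_SHARES)
    )

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        for iid, (lo, hi) in self.coverage_ranges.items():
            if not (0 <= lo <= hi <= 100):
                raise ValueError(f"coverage range for {iid} invalid: ({lo}, {hi})")
        for name in ("under5_range", "under5_fraction_range", "growth_rate_range",
                     "diarrhea_mortality_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} invalid: ({lo}, {hi})")
        if abs(sum(self.region_mix.values()) - 1.0) > 1e-9:
            raise ValueError("region mix must sum to 1")
        return self


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG keyed by (seed, stable hash of stream name)."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


class SyntheticBundle(BaseModel):
    """Everything one analysis run consumes, generated from one seed."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    profiles: List[CountryProfile]
    coverage: List[CoverageRecord]
    regions: Dict[str, str]
    breastfeeding: Dict[str, BreastfeedingState]


def _region_counts(n: int, mix: Mapping[str, float]) -> Dict[str, int]:
    """Largest-remainder apportionment of n countries over regions."""
    raw = {r: n * w for r, w in mix.items()}
    counts = {r: int(v) for r, v in raw.items()}
    short = n - sum(counts.values())
    for r in sorted(raw, key=lambda r: raw[r] - counts[r], reverse=True)[:short]:
        counts[r] += 1
    return counts


def generate_countries(config: GeneratorConfig) -> SyntheticBundle:
    """Profiles, coverage records and breastfeeding states for ``n_countries``
    synthetic countries; byte-identical for a fixed seed."""
    seed = config.seed
    n = config.n_countries
    ids = [f"SYN{i:03d}" for i in range(1, n + 1)]

    counts = _region_counts(n, config.region_mix)
    regions: Dict[str, str] = {}
    i = 0
    for region in ("Africa", "Asia", "Other"):
        for _ in range(counts.get(region, 0)):
            regions[ids[i]] = region
            i += 1

    rng_pop = _substream(seed, "under5_population")
    rng_frac = _substream(seed, "under5_fraction")
    rng_growth = _substream(seed, "growth_rate")
    rng_mort = _substream(seed, "diarrhea_mortality")
    rng_vita = _substream(seed, "vitamin_a_na")
    rng_bf05 = _substream(seed, "breastfeeding_0_5")
    rng_bfold = _substream(seed, "breastfeeding_6_23")

    under5_2010 = rng_pop.uniform(*config.under5_range, size=n)
    under5_frac = rng_frac.uniform(*config.under5_fraction_range, size=n)
    growth = rng_growth.uniform(*config.growth_rate_range, size=n)
    mort = rng_mort.uniform(*config.diarrhea_mortality_range, size=n)
    vita_na = rng_vita.random(size=n) < config.vitamin_a_na_probability

    profiles = []
    for k, cid in enumerate(ids):
        u5 = {
            year: float(under5_2010[k] * (1 + growth[k]) ** (year - START_YEAR))
            for year in YEARS
        }
        total = {year: float(u5[year] / under5_frac[k]) for year in YEARS}
        profiles.append(
            CountryProfile(
                country_id=cid,
                region=regions[cid],
                total_population=total,
                under5_population=u5,
                baseline_diarrheal_deaths=float(mort[k] * under5_2010[k] / 1000.0),
                age_band_death_shares=dict(config.age_band_death_shares),
                vitamin_a_deficient=not bool(vita_na[k]),
            )
        )

    records: List[CoverageRecord] = []
    for iid in INTERVENTION_IDS:
        rng_cov = _substream(seed, f"coverage:{iid}")
        lo, hi = config.coverage_ranges[iid]
        values = rng_cov.uniform(lo, hi, size=n)
        for k, cid in enumerate(ids):
            if iid == "vitamin_a" and vita_na[k]:
                records.append(
                    CoverageRecord(country_id=cid, intervention_id=iid, excluded=True)
                )
            else:
                records.append(
                    CoverageRecord(
                        country_id=cid,
                        intervention_id=iid,
                        coverage=float(np.round(values[k], 6)),
                        year=START_YEAR,
                    )
                )

    breastfeeding: Dict[str, BreastfeedingState] = {}
    # mean mix ~ (0.35, 0.15, 0.35, 0.15) at 0-5 mo; any-breastfeeding
    # 55-95% at 6-23 mo, split between partial and none
    alpha = np.array([3.5, 1.5, 3.5, 1.5])
    for cid in ids:
        p05 = rng_bf05.dirichlet(alpha)
        prevalence = {
            "0-5mo": {
                "exclusive": float(p05[0]),
                "predominant": float(p05[1]),
                "partial": float(p05[2]),
                "none": float(1.0 - p05[0] - p05[1] - p05[2]),
            }
        }
        for band in ("6-11mo", "12-23mo"):
            partial = float(rng_bfold.uniform(0.55, 0.95))
            prevalence[band] = {
                "exclusive": 0.0,
                "predominant": 0.0,
                "partial": partial,
                "none": 1.0 - partial,
            }
        breastfeeding[cid] = BreastfeedingState(prevalence=prevalence)

    return SyntheticBundle(
        profiles=profiles, coverage=records, regions=regions, breastfeeding=breastfeeding
    )


# ---------------------------------------------------------------------------
# Known-answer construction (parameter-recovery harness)
# ---------------------------------------------------------------------------

class KnownAnswerCase(BaseModel):
    """A one-country bundle whose combined 2015 cascade scalar is known by
    construction, with the expected deaths series."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    bundle: SyntheticBundle
    scenario_name: str
    target_scalar: float
    expected_deaths: Dict[int, float]
    baseline_deaths: float


def generate_known_answer_case(
    target_scalar: float,
    seed: int,
    scenario: ScenarioSpec,
    specs: Mapping[str, InterventionSpec],
    regions_target_region: str = "Asia",
) -> KnownAnswerCase:
    """Construct inputs whose 2015 deaths equal ``target_scalar`` x baseline.

    All deaths are placed in the 6-11 mo band, which every intervention
    covers, and the breastfeeding baseline is set equal to the scenario's
    2015 target state so its multiplier is exactly 1.  Baseline coverages are
    then solved intervention-by-intervention so the 2015 reduction factors
    multiply to ``target_scalar``: each factor is capped below by its value
    at zero baseline coverage, and any factor set to 1 gets baseline equal to
    the target (maintenance holds it constant).

    Raises when the scalar is outside what the scenario's targets can reach.
    """
    if not 0.0 < target_scalar <= 1.0:
        raise ValueError("target scalar must be in (0, 1]")
    cid = "KA001"
    region = regions_target_region
    order = [iid for iid in INTERVENTION_IDS]
    floors = {}
    targets = {}
    for iid in order:
        spec = specs[iid]
        t_pct = scenario.target_for(iid, region)
        t = 0.0 if t_pct is None else t_pct / 100.0
        targets[iid] = t
        floors[iid] = 1.0 - spec.effectiveness * spec.affected_fraction * t
    attainable = float(np.prod(list(floors.values())))
    if target_scalar < attainable - 1e-12:
        raise ValueError(
            f"scalar {target_scalar} unattainable: floor with these targets is "
            f"{attainable:.6f}"
        )

    remaining = target_scalar
    baselines_pct: Dict[str, float] = {}
    factors_2015: Dict[str, float] = {}
    for iid in order:
        spec = specs[iid]
        ea = spec.effectiveness * spec.affected_fraction
        t = targets[iid]
        f = max(floors[iid], min(1.0, remaining))
        remaining /= f
        # f = (1 - ea*t) / (1 - ea*c0)  =>  c0 = (1 - (1 - ea*t)/f) / ea
        c0 = t if ea == 0.0 else (1.0 - (1.0 - ea * t) / f) / ea
        c0 = min(max(c0, 0.0), t)
        baselines_pct[iid] = c0 * 100.0
        factors_2015[iid] = reduction_factor(spec.effectiveness, spec.affected_fraction, c0, max(c0, t))

    rng = _substream(seed, "known_answer")
    under5 = float(rng.uniform(5e5, 5e6))
    d0 = float(rng.uniform(1e4, 2e5))
    profile = CountryProfile(
        country_id=cid,
        region=region,
        total_population={y: under5 / 0.15 for y in YEARS},
        under5_population={y: under5 for y in YEARS},
        baseline_diarrheal_deaths=d0,
        age_band_death_shares={b: (1.0 if b == "6-11mo" else 0.0) for b in AGE_BANDS},
        vitamin_a_deficient=True,
    )
    records = [
        CoverageRecord(
            country_id=cid, intervention_id=iid, coverage=baselines_pct[iid],
            year=START_YEAR,
        )
        for iid in order
    ]
    # breastfeeding baseline == scenario 2015 target state => multiplier 1
    prevalence = {}
    for band in BF_BANDS:
        named = {
            cat: scenario.breastfeeding_targets.get(band, {}).get(cat, 0.0) / 100.0
            for cat in ("exclusive", "predominant", "partial")
        }
        named["none"] = 1.0 - sum(named.values())
        prevalence[band] = named
    bf = BreastfeedingState(prevalence=prevalence)

    expected: Dict[int, float] = {}
    for year in YEARS:
        scalar = 1.0
        for iid in order:
            spec = specs[iid]
            c0 = baselines_pct[iid] / 100.0
            c1 = interpolate_linear(c0, max(c0, targets[iid]), year)
            scalar *= reduction_factor(spec.effectiveness, spec.affected_fraction, c0, c1)
        expected[year] = d0 * scalar

    bundle = SyntheticBundle(
        profiles=[profile],
        coverage=records,
        regions={cid: region},
        breastfeeding={cid: bf},
    )
    return KnownAnswerCase(
        bundle=bundle,
        scenario_name=scenario.name,
        target_scalar=target_scalar,
        expected_deaths=expected,
        baseline_deaths=d0,
    )
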
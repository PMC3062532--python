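"""The residual-effectiveness cascade: coverage trajectories to deaths.

Baseline diarrheal mortality already reflects baseline intervention coverage,
so raising coverage of an intervention with effectiveness E and affected
fraction A from c0 to c1 scales cause-specific deaths by the ratio of
surviving fractions::

    deaths_new / deaths_old = (1 - E*A*c1) / (1 - E*A*c0)

Each intervention's effect applies only to the residual deaths left by the
others — the factors multiply, which makes the cascade order-independent and
rules out double counting: with every coverage at 100% the residual is still
``prod_i (1 - E_i*A_i) > 0``.

Breastfeeding enters as a relative-risk sub-model rather than an (E, A) pair:
shifting the practice-category mix multiplies band mortality by the ratio of
prevalence-weighted relative risks under the new versus the old mix.

Deaths are distributed over five age bands and each intervention acts only on
the bands inside its age range (ORS 0-59 mo, vitamin A 6-59 mo, the rest
1-59 mo); the breastfeeding multiplier applies below 24 mo only.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional

import pandas as pd

from .domain import (
    AGE_BANDS,
    DEATH_BAND_TO_BF_BAND,
    START_YEAR,
    YEARS,
    BreastfeedingState,
    CountryProfile,
    InterventionSpec,
    ProjectionResult,
    ScenarioSpec,
)
from .scaleup import build_breastfeeding_trajectory, trajectory_lookup


def reduction_factor(E: float, A: float, c0: float, c1: float) -> float:
    """Ratio of diarrheal deaths at coverage ``c1`` to deaths at baseline
    coverage ``c0`` for one intervention (E effectiveness, A affected
    fraction), all inputs proportions in [0, 1]."""
    for name, v in (("E", E), ("A", A), ("c0", c0), ("c1", c1)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    denom = 1.0 - E * A * c0
    if denom == 0.0:
        raise ZeroDivisionError(
            "baseline coverage already averts every affected death (E*A*c0 = 1)"
        )
    return (1.0 - E * A * c1) / denom


def breastfeeding_multiplier(
    p0: Mapping[str, float],
    p1: Mapping[str, float],
    rr: Mapping[str, float],
) -> float:
    """Mortality multiplier from shifting breastfeeding practice prevalences
    ``p0`` to ``p1`` within one age band, given the band's relative risks.

    Equals the ratio of prevalence-weighted mean relative risks — i.e. the
    population-attributable risk under the new mix relative to the old.
    """
    for name, p in (("p0", p0), ("p1", p1)):
        total = sum(p.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{name} prevalences sum to {total}, expected 1")
        missing = set(p) - set(rr)
        if missing:
            raise ValueError(f"no relative risk for categories {sorted(missing)}")
    weighted0 = sum(p0[k] * rr[k] for k in p0)
    weighted1 = sum(p1[k] * rr[k] for k in p1)
    return weighted1 / weighted0


def combined_scalar(
    factors: Iterable[float], bf_multiplier: float = 1.0
) -> float:
    """Product of per-intervention reduction factors and the breastfeeding
    multiplier; order-independent, 1.0 for the empty cascade."""
    out = bf_multiplier
    for f in factors:
        out *= f
    return out


def band_scalar(
    band: str,
    year: int,
    coverage: Mapping[str, Mapping[int, float]],
    specs: Mapping[str, InterventionSpec],
    bf_multipliers: Optional[Mapping[str, float]] = None,
) -> float:
    """Combined cascade scalar for one age band in one year.

    ``coverage`` maps intervention id -> year -> proportion (the 2010 entry
    is the baseline); interventions absent from ``coverage`` (excluded for
    this country) contribute nothing.  ``bf_multipliers`` maps breastfeeding
    band -> multiplier for this year.
    """
    factors = []
    for iid, series in coverage.items():
        spec = specs[iid]
        if not spec.covers_band(band):
            continue
        factors.append(
            reduction_factor(
                spec.effectiveness,
                spec.affected_fraction,
                series[START_YEAR],
                series[year],
            )
        )
    bf_band = DEATH_BAND_TO_BF_BAND[band]
    bf_mult = 1.0
    if bf_band is not None and bf_multipliers is not None:
        bf_mult = bf_multipliers.get(bf_band, 1.0)
    return combined_scalar(factors, bf_mult)


def project_deaths(
    profile: CountryProfile,
    trajectories: pd.DataFrame,
    specs: Mapping[str, InterventionSpec],
    scenario: ScenarioSpec,
    bf_baseline: Optional[BreastfeedingState] = None,
    bf_rr: Optional[Mapping[str, Mapping[str, float]]] = None,
    indirect_wash_multiplier: float = 1.0,
) -> ProjectionResult:
    """Annual diarrheal deaths for one country under one scenario.

    For each year, every age band's baseline deaths are scaled by the product
    of the reduction factors of the interventions covering that band plus the
    band's breastfeeding multiplier; deaths averted compare against constant
    baseline mortality.  ``indirect_wash_multiplier`` is an extension hook
    for a user-supplied stunting-mediated indirect effect of the WASH
    interventions; it ships disabled (1.0) because no effect size is modeled.

    Raises if the trajectory frame lacks an intervention the country needs
    (exclusions are legitimate absences and simply contribute no factor).
    """
    coverage = trajectory_lookup(trajectories, profile.country_id)
    unknown = set(coverage) - set(specs)
    if unknown:
        raise ValueError(f"{profile.country_id}: no spec for interventions {sorted(unknown)}")
    bf_by_year: Dict[int, Dict[str, float]] = {}
    if bf_baseline is not None and bf_rr is not None:
        for year in YEARS:
            state = build_breastfeeding_trajectory(
                bf_baseline, scenario.breastfeeding_targets, year
            )
            bf_by_year[year] = {
                band: breastfeeding_multiplier(
                    bf_baseline.prevalence[band], state.prevalence[band], bf_rr[band]
                )
                for band in bf_rr
            }
    rows = []
    d0 = profile.baseline_diarrheal_deaths
    for year in YEARS:
        # accumulate averted deaths (exactly 0 per band when coverage is
        # unchanged) so the baseline scenario reproduces d0 exactly
        averted = 0.0
        for band, share in profile.age_band_death_shares.items():
            scalar = band_scalar(band, year, coverage, specs, bf_by_year.get(year))
            averted += d0 * share * (1.0 - scalar)
        deaths = (d0 - averted) * indirect_wash_multiplier
        rows.append(
            {
                "country_id": profile.country_id,
                "year": year,
                "scenario": scenario.name,
                "deaths": deaths,
                "deaths_averted": d0 - deaths,
            }
        )
    return ProjectionResult(deaths=pd.DataFrame(rows))


def project_all(
    profiles: List[CountryProfile],
    trajectories: pd.DataFrame,
    specs: Mapping[str, InterventionSpec],
    scenario: ScenarioSpec,
    bf_baselines: Optional[Mapping[str, BreastfeedingState]] = None,
    bf_rr: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> ProjectionResult:
    """Concatenate :func:`project_deaths` over countries (sorted by id for
    deterministic output)."""
    frames = []
    for profile in sorted(profiles, key=lambda p: p.country_id):
        bf = bf_baselines.get(profile.country_id) if bf_baselines else None
        frames.append(
            project_deaths(profile, trajectories, specs, scenario, bf, bf_rr).deaths
        )
    return ProjectionResult(deaths=pd.concat(frames, ignore_index=True))


def aggregate_results(result: ProjectionResult, top_k: int = 5) -> dict:
    """Totals, cumulative deaths averted, and country shares of averted
    deaths.

    Shares are of cumulative averted deaths over 2011-2015 (2010 is the
    baseline year, averted is zero by construction); ties rank by country id.
    """
    df = result.deaths
    totals_by_year = df.groupby("year")["deaths"].sum().to_dict()
    averted_by_year = df.groupby("year")["deaths_averted"].sum().to_dict()
    post = df[df["year"] > START_YEAR]
    cumulative_averted = float(post["deaths_averted"].sum())
    by_country = (
        post.groupby("country_id")["deaths_averted"]
        .sum()
        .reset_index()
        .sort_values(["deaths_averted", "country_id"], ascending=[False, True])
    )
    if cumulative_averted > 0:
        by_country["share_pct"] = 100.0 * by_country["deaths_averted"] / cumulative_averted
    else:
        by_country["share_pct"] = 0.0
    top = by_country.head(top_k)
    return {
        "totals_by_year": {int(y): float(v) for y, v in totals_by_year.items()},
        "averted_by_year": {int(y): float(v) for y, v in averted_by_year.items()},
        "cumulative_averted": cumulative_averted,
        "country_shares": by_country.reset_index(drop=True),
        "top_k": int(top_k),
        "top_k_countries": top["country_id"].tolist(),
        "top_k_share_pct": float(top["share_pct"].sum()),
    }
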
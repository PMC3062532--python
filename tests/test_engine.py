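"""The residual-effectiveness cascade and the breastfeeding RR sub-model."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diascale import (
    InterventionSpec,
    ScenarioSpec,
    aggregate_results,
    breastfeeding_multiplier,
    combined_scalar,
    project_deaths,
    reduction_factor,
)
from diascale.domain import ProjectionResult

from conftest import make_profile

proportions = st.floats(0, 1, allow_nan=False)


def sequential_residual(d0, params):
    """Independent oracle: apply each intervention to the residual deaths in
    sequence, one at a time."""
    deaths = d0
    for E, A, c0, c1 in params:
        deaths = deaths * (1 - E * A * c1) / (1 - E * A * c0)
    return deaths


class TestReductionFactor:
    def test_ors_scale_up_example(self):
        # E=0.93, A=0.95, coverage 30% -> 75%
        assert reduction_factor(0.93, 0.95, 0.30, 0.75) == pytest.approx(
            0.337375 / 0.73495, abs=1e-12
        )

    def test_no_coverage_change_is_identity(self):
        assert reduction_factor(0.5, 0.8, 0.4, 0.4) == 1.0

    def test_rotavirus_introduction_from_zero(self):
        # E=0.74, A=0.39, 0 -> 90%
        assert reduction_factor(0.74, 0.39, 0.0, 0.90) == pytest.approx(
            1 - 0.2886 * 0.9, abs=1e-12
        )

    def test_saturated_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            reduction_factor(1.0, 1.0, 1.0, 0.5)

    def test_out_of_range_input_rejected(self):
        with pytest.raises(ValueError, match="c1"):
            reduction_factor(0.5, 0.5, 0.5, 1.2)

    @settings(derandomize=True, max_examples=300)
    @given(proportions, proportions, proportions, proportions)
    def test_bounded_by_one_when_coverage_rises(self, E, A, c0, c1):
        lo, hi = min(c0, c1), max(c0, c1)
        if E * A * lo == 1.0:
            return
        assert reduction_factor(E, A, lo, hi) <= 1.0


class TestBreastfeedingMultiplier:
    RR_YOUNG = {"exclusive": 1.0, "predominant": 2.28, "partial": 4.62, "none": 10.53}
    RR_OLD = {"breastfed": 1.0, "none": 2.28}

    def test_young_band_example(self):
        p0 = {"exclusive": 0.25, "predominant": 0.25, "partial": 0.40, "none": 0.10}
        p1 = {"exclusive": 0.90, "predominant": 0.05, "partial": 0.00, "none": 0.05}
        assert breastfeeding_multiplier(p0, p1, self.RR_YOUNG) == pytest.approx(
            1.5405 / 3.721, abs=1e-12
        )

    def test_identity_mix_gives_one(self):
        p = {"exclusive": 0.25, "predominant": 0.25, "partial": 0.40, "none": 0.10}
        assert breastfeeding_multiplier(p, dict(p), self.RR_YOUNG) == 1.0

    def test_older_band_example(self):
        p0 = {"breastfed": 0.80, "none": 0.20}
        p1 = {"breastfed": 0.95, "none": 0.05}
        assert breastfeeding_multiplier(p0, p1, self.RR_OLD) == pytest.approx(
            1.064 / 1.256, abs=1e-12
        )

    def test_unnormalized_prevalences_rejected(self):
        p0 = {"breastfed": 0.80, "none": 0.10}
        with pytest.raises(ValueError, match="sum"):
            breastfeeding_multiplier(p0, p0, self.RR_OLD)

    @settings(derandomize=True, max_examples=300)
    @given(st.lists(st.floats(0.01, 1), min_size=4, max_size=4),
           st.lists(st.floats(0.01, 1), min_size=4, max_size=4))
    def test_equals_weighted_rr_ratio_oracle(self, w0, w1):
        cats = list(self.RR_YOUNG)
        p0 = {c: w / sum(w0) for c, w in zip(cats, w0)}
        p1 = {c: w / sum(w1) for c, w in zip(cats, w1)}
        oracle = sum(p1[c] * self.RR_YOUNG[c] for c in cats) / sum(
            p0[c] * self.RR_YOUNG[c] for c in cats
        )
        assert breastfeeding_multiplier(p0, p1, self.RR_YOUNG) == pytest.approx(
            oracle, abs=1e-12
        )


class TestCombinedScalar:
    def test_example_product(self):
        f1 = 0.337375 / 0.73495
        f2 = 1.5405 / 3.721
        assert combined_scalar([f1], f2) == pytest.approx(f1 * f2, abs=1e-12)

    def test_empty_cascade_is_identity(self):
        assert combined_scalar([]) == 1.0

    def test_order_invariance(self):
        factors = [0.45905, 0.885, 0.7402, 0.962875]
        results = {combined_scalar(p) for p in itertools.permutations(factors)}
        assert max(results) - min(results) < 1e-12


def single_intervention_setup(E, A, c0, target, d0=100_000.0):
    """One intervention covering every band, one country, linear scale-up."""
    spec = InterventionSpec(
        intervention_id="tx", effectiveness=E, affected_fraction=A,
        age_min_months=0, age_max_months=59,
    )
    profile = make_profile(deaths=d0)
    effective = max(c0, target)
    rows = [
        {"country_id": "X", "intervention_id": "tx", "year": y,
         "coverage": c0 + (effective - c0) * (y - 2010) / 5}
        for y in range(2010, 2016)
    ]
    scenario = ScenarioSpec(name="ambitious", target_coverage={"tx": target * 100})
    return profile, pd.DataFrame(rows), {"tx": spec}, scenario


class TestProjectDeaths:
    def test_single_intervention_year_by_year_oracle(self):
        profile, traj, specs, scenario = single_intervention_setup(0.93, 0.95, 0.30, 0.75)
        result = project_deaths(profile, traj, specs, scenario)
        deaths = result.deaths.set_index("year")["deaths"]
        # independent arithmetic oracle, year by year
        for year in range(2010, 2016):
            c1 = 0.30 + (0.75 - 0.30) * (year - 2010) / 5
            expected = 100_000 * (1 - 0.8835 * c1) / (1 - 0.8835 * 0.30)
            assert deaths[year] == pytest.approx(expected, abs=1e-9)
        assert deaths[2013] == pytest.approx(67_543, abs=1.0)

    def test_cumulative_averted_matches_linearity(self):
        profile, traj, specs, scenario = single_intervention_setup(0.93, 0.95, 0.30, 0.75)
        result = project_deaths(profile, traj, specs, scenario)
        post = result.deaths[result.deaths.year > 2010]
        # averted is linear in the year, so the 5-year sum is 5x the midpoint
        averted_2013 = post.set_index("year")["deaths_averted"][2013]
        assert post["deaths_averted"].sum() == pytest.approx(5 * averted_2013, rel=1e-9)
        assert post["deaths_averted"].sum() == pytest.approx(162_286, abs=2.0)

    def test_unchanged_coverage_averts_nothing(self):
        profile, traj, specs, scenario = single_intervention_setup(0.93, 0.95, 0.30, 0.30)
        result = project_deaths(profile, traj, specs, scenario)
        assert (result.deaths["deaths_averted"] == 0.0).all()

    def test_equivalence_with_sequential_residual_application(self):
        """Product formulation equals applying interventions one at a time to
        the residual, in any order."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(1, 6)
            params = [
                (rng.uniform(0.1, 0.99), rng.uniform(0.1, 1.0),
                 rng.uniform(0, 0.8), rng.uniform(0, 1.0))
                for _ in range(n)
            ]
            specs = {
                f"i{k}": InterventionSpec(
                    intervention_id=f"i{k}", effectiveness=E, affected_fraction=A,
                    age_min_months=0, age_max_months=59,
                )
                for k, (E, A, _, _) in enumerate(params)
            }
            rows = []
            for k, (_, _, c0, c1) in enumerate(params):
                for y in range(2010, 2016):
                    cov = c0 if y == 2010 else c1
                    rows.append({"country_id": "X", "intervention_id": f"i{k}",
                                 "year": y, "coverage": cov})
            profile = make_profile(deaths=50_000.0)
            scenario = ScenarioSpec(name="universal")
            result = project_deaths(profile, pd.DataFrame(rows), specs, scenario)
            got = result.deaths.set_index("year")["deaths"][2015]
            perm = list(params)
            rng.shuffle(perm)
            assert got == pytest.approx(sequential_residual(50_000.0, perm), rel=1e-12)

    def test_deaths_monotone_in_target_coverage(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            E, A = rng.uniform(0.1, 0.99), rng.uniform(0.1, 1.0)
            c0 = rng.uniform(0, 0.7)
            t_lo = rng.uniform(c0, 1.0)
            t_hi = rng.uniform(t_lo, 1.0)
            lo = project_deaths(*single_intervention_setup(E, A, c0, t_lo)).deaths
            hi = project_deaths(*single_intervention_setup(E, A, c0, t_hi)).deaths
            assert (hi["deaths"] <= lo["deaths"] + 1e-9).all()

    def test_residual_floor_never_crossed(self):
        """Even at full coverage of everything, deaths stay above
        d0 * prod(1 - E_i A_i)."""
        rng = np.random.default_rng(23)
        for _ in range(25):
            n = rng.integers(1, 6)
            eas = [(rng.uniform(0, 1), rng.uniform(0, 1)) for _ in range(n)]
            specs = {
                f"i{k}": InterventionSpec(
                    intervention_id=f"i{k}", effectiveness=E, affected_fraction=A,
                    age_min_months=0, age_max_months=59,
                )
                for k, (E, A) in enumerate(eas)
            }
            rows = [
                {"country_id": "X", "intervention_id": f"i{k}", "year": y,
                 "coverage": 0.0 if y == 2010 else 1.0}
                for k in range(n) for y in range(2010, 2016)
            ]
            d0 = 10_000.0
            result = project_deaths(
                make_profile(deaths=d0), pd.DataFrame(rows), specs,
                ScenarioSpec(name="universal"),
            )
            floor = d0 * float(np.prod([1 - E * A for E, A in eas]))
            assert (result.deaths["deaths"] >= floor - 1e-9).all()
            assert result.deaths["deaths_averted"].sum() <= 6 * d0


class TestAggregateResults:
    @staticmethod
    def _result(averted_by_country):
        rows = []
        for cid, averted in averted_by_country.items():
            for year in range(2010, 2016):
                a = 0.0 if year == 2010 else averted / 5
                rows.append({"country_id": cid, "year": year, "scenario": "universal",
                             "deaths": 1000.0 - a, "deaths_averted": a})
        return ProjectionResult(deaths=pd.DataFrame(rows))

    def test_top_one_share(self):
        agg = aggregate_results(self._result({"A": 30_000, "B": 10_000}), top_k=1)
        assert agg["top_k_share_pct"] == pytest.approx(75.0)
        assert agg["top_k_countries"] == ["A"]

    def test_single_country_share_is_total(self):
        agg = aggregate_results(self._result({"A": 1234.0}), top_k=5)
        assert agg["top_k_share_pct"] == pytest.approx(100.0)

    def test_shares_normalize(self):
        agg = aggregate_results(self._result({"A": 5.0, "B": 7.0, "C": 11.0}), top_k=3)
        assert agg["country_shares"]["share_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_ties_rank_by_country_id(self):
        agg = aggregate_results(self._result({"B": 10.0, "A": 10.0}), top_k=1)
        assert agg["top_k_countries"] == ["A"]
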
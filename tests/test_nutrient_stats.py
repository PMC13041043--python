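from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fjordflux import nutrient_stats as ns


def nutrient_frame(rows):
    defaults = {"station_id": "s1", "region": "K", "year": 2016,
                "depth_m": 10.0, "water_mass": "AW"}
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestDetectionFlags:
    def test_flag_below_limit_value_retained(self):
        df = nutrient_frame([{"nitrate_nitrite": 0.3}])
        out = ns.flag_below_detection(df)
        assert bool(out["nitrate_nitrite_bd"].iloc[0]) is True
        assert out["nitrate_nitrite"].iloc[0] == 0.3

    def test_boundary_strict_inequality(self):
        df = nutrient_frame([{"phosphate": 0.06}])
        out = ns.flag_below_detection(df)
        assert bool(out["phosphate_bd"].iloc[0]) is False

    def test_missing_propagates(self):
        df = nutrient_frame([{"phosphate": np.nan}])
        out = ns.flag_below_detection(df)
        assert pd.isna(out["phosphate_bd"].iloc[0])

    def test_nonpositive_limit_rejected(self):
        with pytest.raises(ValueError):
            ns.flag_below_detection(nutrient_frame([{}]), {"phosphate": 0.0})


class TestAggregation:
    def test_odd_median(self):
        df = nutrient_frame([{"ammonium": v} for v in (1.0, 2.0, 10.0)])
        cells = ns.aggregate_station_medians(df)
        assert len(cells) == 1
        assert cells["ammonium"].iloc[0] == 2.0

    def test_even_median_midpoint(self):
        df = nutrient_frame([{"ammonium": v} for v in (1.0, 3.0)])
        cells = ns.aggregate_station_medians(df)
        assert cells["ammonium"].iloc[0] == 2.0

    def test_stations_never_pooled(self):
        df = nutrient_frame([{"station_id": "s1", "ammonium": 1.0},
                             {"station_id": "s2", "ammonium": 5.0}])
        cells = ns.aggregate_station_medians(df)
        assert len(cells) == 2
        assert sorted(cells["ammonium"]) == [1.0, 5.0]

    def test_unclassified_excluded(self):
        df = nutrient_frame([{"ammonium": 1.0},
                             {"water_mass": "Unclassified", "ammonium": 9.0}])
        cells = ns.aggregate_station_medians(df)
        assert len(cells) == 1
        assert cells["ammonium"].iloc[0] == 1.0

    def test_empty_input(self):
        assert ns.aggregate_station_medians(pd.DataFrame()).empty

    def test_idempotent_on_singletons(self):
        df = nutrient_frame([
            {"station_id": f"s{i}", "ammonium": float(i)} for i in range(4)])
        once = ns.aggregate_station_medians(df)
        again = ns.aggregate_station_medians(
            once.assign(depth_m=0.0))
        assert list(once["ammonium"]) == list(again["ammonium"])


def mwu_oracle_p(x, y):
    """Exact p by enumerating all group assignments of the pooled values."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(ix):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        gt = sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
        return gt

    u_obs = u_stat(range(n1))
    us = [u_stat(ix) for ix in combinations(range(len(pooled)), n1)]
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_separated_groups(self):
        res = ns.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.p == pytest.approx(0.1)
        assert res.method == "exact"

    def test_symmetric_groups(self):
        res = ns.mann_whitney_u([1, 2], [1, 2])
        assert res.u == 2
        assert res.p == 1.0

    def test_swap_symmetry(self):
        x, y = [1.0, 2.5, 3.0], [2.0, 4.0, 5.0, 7.0]
        a = ns.mann_whitney_u(x, y)
        b = ns.mann_whitney_u(y, x)
        assert a.p == pytest.approx(b.p)
        assert b.u == pytest.approx(a.n1 * a.n2 - a.u)

    def test_degenerate_all_identical(self):
        with pytest.warns(UserWarning):
            res = ns.mann_whitney_u([5.0] * 15, [5.0] * 15)
        assert res.p == 1.0 and res.degenerate

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ns.mann_whitney_u([], [1.0])

    def test_exact_matches_enumeration_oracle(self, rng):
        # all tie-free splits with n1 + n2 <= 8 (random continuous values)
        for n1 in range(1, 7):
            for n2 in range(1, 8 - n1 + 1):
                vals = rng.normal(size=n1 + n2)
                x, y = vals[:n1], vals[n1:]
                res = ns.mann_whitney_u(x, y)
                assert res.method == "exact"
                assert res.p == pytest.approx(mwu_oracle_p(x, y), abs=1e-12)

    def test_null_rejection_rate(self, rng):
        rej = sum(
            ns.mann_whitney_u(rng.normal(size=10), rng.normal(size=10)).p
            <= 0.05
            for _ in range(1000))
        assert 0.025 <= rej / 1000 <= 0.065


class TestBenjaminiHochberg:
    def test_hand_oracle(self):
        out = ns.benjamini_hochberg([0.01, 0.04, 0.03, 0.02])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_identity(self):
        assert ns.benjamini_hochberg([0.5]) == pytest.approx([0.5])

    def test_empty(self):
        assert ns.benjamini_hochberg([]).size == 0

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            ns.benjamini_hochberg([0.5, 1.5])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=20))
    def test_dominance_and_monotonicity(self, pvals):
        p = np.asarray(pvals)
        adj = ns.benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=10)
        perm = rng.permutation(10)
        assert np.allclose(ns.benjamini_hochberg(p)[perm],
                           ns.benjamini_hochberg(p[perm]))


class TestBootstrap:
    def test_degenerate_data(self):
        assert ns.bootstrap_ci([7.0] * 5, b=500) == (7.0, 7.0)

    def test_seed_reproducible(self, rng):
        vals = rng.normal(size=30)
        assert ns.bootstrap_ci(vals, b=500, seed=4) == \
            ns.bootstrap_ci(vals, b=500, seed=4)

    def test_single_value_warns(self):
        with pytest.warns(UserWarning):
            lo, hi = ns.bootstrap_ci([3.0], b=500)
        assert lo == hi == 3.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            ns.bootstrap_ci([], b=500)

    def test_small_b_rejected(self):
        with pytest.raises(ValueError):
            ns.bootstrap_ci([1.0, 2.0], b=50)

    def test_coverage_simulation(self, rng):
        # scaled-down version of the spec's coverage study
        hits = 0
        reps = 200
        for i in range(reps):
            vals = rng.normal(size=50)
            lo, hi = ns.bootstrap_ci(vals, b=500, seed=int(rng.integers(1e9)))
            hits += lo <= 0.0 <= hi
        assert 0.88 <= hits / reps <= 0.99


class TestSummaries:
    def test_point_statistics(self):
        s = ns.summarize_water_mass([1.0, 2.0, 3.0], b=500)
        assert s.median == 2.0 and s.mean == 2.0 and s.n == 3

    def test_single_cell(self):
        s = ns.summarize_water_mass([4.2], b=500)
        assert s.median == s.mean == s.q25 == s.q75 == 4.2
        assert s.ci_low == s.ci_high == 4.2

    def test_type7_quartiles(self):
        s = ns.summarize_water_mass([1.0, 2.0, 3.0, 4.0], b=500)
        assert s.q25 == pytest.approx(1.75)
        assert s.q75 == pytest.approx(3.25)

    def test_order_invariance(self, rng):
        vals = rng.normal(size=9)
        a = ns.summarize_water_mass(vals, b=500)
        b = ns.summarize_water_mass(vals[::-1], b=500)
        assert a == b

    def test_quantile_ordering_invariant(self, rng):
        vals = rng.normal(size=15)
        s = ns.summarize_water_mass(vals, b=500)
        assert s.q25 <= s.median <= s.q75
        assert s.ci_low <= s.mean <= s.ci_high


class TestRatios:
    def test_redfield_boundary(self):
        out = ns.stoichiometric_ratios(
            {"nitrate_nitrite": 14.0, "ammonium": 2.0, "phosphate": 1.0,
             "silicic_acid": 8.0})
        assert out["din_p"] == pytest.approx(16.0)
        assert out["redfield_excess"] is False

    def test_din_si(self):
        out = ns.stoichiometric_ratios(
            {"nitrate_nitrite": 8.0, "ammonium": 2.0, "phosphate": 1.0,
             "silicic_acid": 5.0})
        assert out["din_si"] == pytest.approx(2.0)

    def test_zero_denominator_flagged(self):
        out = ns.stoichiometric_ratios(
            {"nitrate_nitrite": 8.0, "ammonium": 2.0, "phosphate": 0.0,
             "silicic_acid": 5.0})
        assert np.isnan(out["din_p"]) and out["din_p_undefined"]


class TestCompareRegions:
    def test_only_comparable_water_masses_tested(self):
        cells = pd.DataFrame({
            "region": ["K", "K", "K", "R", "R", "R", "K"],
            "year": [2016] * 7,
            "water_mass": ["AW", "AW", "AW", "AW", "AW", "AW", "WCW"],
            "station_id": list("abcdefg"),
            "ammonium": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 9.0],
        })
        results = ns.compare_regions(cells, "K", "R",
                                     analytes=("ammonium",))
        assert len(results) == 1  # WCW present only in K -> skipped
        r = results[0]
        assert r.water_mass == "AW"
        assert r.u_statistic == 0
        assert r.p_corr >= r.p
        assert r.direction == "R"
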
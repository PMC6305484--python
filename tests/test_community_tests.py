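import itertools
import math

import numpy as np
import pandas as pd
import pytest

from spoilcom.community_data import StationTable
from spoilcom.community_tests import (
    StatsTestError,
    mann_whitney_u,
    permanova,
    significance_stars,
    soil_comparison_table,
)
from spoilcom.ordination import DistanceMatrix
from spoilcom import synthetic as syn

from conftest import make_stations


def _dist(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"u{i}" for i in range(values.shape[0])]
    return DistanceMatrix(ids, values)


def _two_blocks(n_within_zero=True):
    """4 units, two groups of 2: within-group distance 0, between 1."""
    d = np.ones((4, 4)) - np.eye(4)
    d[0, 1] = d[1, 0] = 0.0
    d[2, 3] = d[3, 2] = 0.0
    return _dist(d)


class TestPermanova:
    def test_perfectly_separated_groups(self):
        d = _two_blocks()
        groups = pd.Series(["A", "A", "B", "B"], index=d.unit_ids)
        res = permanova(d, groups, n_perm=50, seed=0)
        assert res.ss_total == pytest.approx(1.0, abs=1e-12)
        assert res.ss_within == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert math.isinf(res.pseudo_f)
        assert 0 < res.p_value <= 1

    def test_partition_of_sums_of_squares(self):
        rng = np.random.default_rng(1)
        x = rng.random((8, 5))
        from scipy.spatial.distance import pdist, squareform

        d = _dist(squareform(pdist(x)))
        groups = pd.Series(list("AABBCCAB"), index=d.unit_ids)
        res = permanova(d, groups, n_perm=10, seed=0)
        assert res.ss_total == pytest.approx(res.ss_between + res.ss_within, rel=1e-9)
        assert 0 <= res.r_squared <= 1

    def test_equal_distances_give_flat_structure(self):
        """All pairwise distances equal: R2 matches its analytic value and
        every permutation gives the same F, so p = 1."""
        n, a = 6, 2
        d = _dist(np.ones((n, n)) - np.eye(n))
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=d.unit_ids)
        res = permanova(d, groups, n_perm=100, seed=3)
        # brute-force over all label permutations: SS_W identical for all
        assert res.p_value == pytest.approx(1.0)
        assert res.r_squared == pytest.approx((a - 1) / (n - 1), rel=1e-9)

    def test_minimum_attainable_p(self):
        """Strong separation with 200 permutations bottoms out at 1/201."""
        rng = np.random.default_rng(0)
        ga = rng.normal(0, 0.05, (6, 3))
        gb = rng.normal(10, 0.05, (6, 3))
        from scipy.spatial.distance import pdist, squareform

        d = _dist(squareform(pdist(np.vstack([ga, gb]))))
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=d.unit_ids)
        res = permanova(d, groups, n_perm=200, seed=1)
        assert res.p_value == pytest.approx(1 / 201)

    def test_r2_invariant_to_distance_scaling(self):
        rng = np.random.default_rng(5)
        x = rng.random((7, 4))
        from scipy.spatial.distance import pdist, squareform

        base = squareform(pdist(x))
        groups = pd.Series(list("AAABBBB"), index=[f"u{i}" for i in range(7)])
        r1 = permanova(_dist(base), groups, n_perm=10, seed=0).r_squared
        r2 = permanova(_dist(base * 7.3), groups, n_perm=10, seed=0).r_squared
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_enumeration_oracle_matches_monte_carlo(self):
        """For n = 6 the Monte-Carlo permutation p agrees with the exact
        tail probability over all 720 label permutations."""
        rng = np.random.default_rng(7)
        x = rng.random((6, 4))
        from scipy.spatial.distance import pdist, squareform

        dvals = squareform(pdist(x))
        d = _dist(dvals)
        codes = np.array([0, 0, 0, 1, 1, 1])
        groups = pd.Series(["A" if c == 0 else "B" for c in codes], index=d.unit_ids)

        def f_of(perm_codes):
            d2 = dvals ** 2
            n = 6
            ss_tot = d2.sum() / (2 * n)
            ssw = 0.0
            for g in (0, 1):
                mask = perm_codes == g
                ssw += d2[np.ix_(mask, mask)].sum() / (2 * mask.sum())
            return (ss_tot - ssw) / 1 / (ssw / 4)

        f_obs = f_of(codes)
        perms = list(itertools.permutations(range(6)))
        tail = np.mean([f_of(codes[list(p)]) >= f_obs for p in perms])
        n_perm = 2000
        res = permanova(d, groups, n_perm=n_perm, seed=11)
        se = math.sqrt(tail * (1 - tail) / n_perm)
        assert abs(res.p_value - tail) < 4 * se + 2 / n_perm

    def test_input_validation(self):
        d = _two_blocks()
        with pytest.raises(StatsTestError):
            permanova(d, pd.Series(["A"] * 4, index=d.unit_ids))
        with pytest.raises(StatsTestError):
            permanova(d, pd.Series(["A", "A", "A", "B"], index=d.unit_ids))
        with pytest.raises(StatsTestError):
            permanova(d, pd.Series(["A", "A", "B", "B"], index=d.unit_ids), n_perm=0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        from scipy.spatial.distance import pdist, squareform

        d = _dist(squareform(pdist(rng.random((10, 3)))))
        groups = pd.Series(list("AAAAABBBBB"), index=d.unit_ids)
        p1 = permanova(d, groups, n_perm=99, seed=42).p_value
        p2 = permanova(d, groups, n_perm=99, seed=42).p_value
        assert p1 == p2


def _enumerate_mwu_p(x, y):
    """Exact two-sided Mann-Whitney p by enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(combo)]
        ys = np.delete(pooled, list(combo))
        u = sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
        us.append(u)
    us = np.asarray(us)
    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    mean = len(x) * len(y) / 2
    dev = abs(u_obs - mean)
    return np.mean(np.abs(us - mean) >= dev - 1e-12)


class TestMannWhitney:
    def test_hand_example(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(2 / 6)
        assert res.method == "exact"

    def test_identical_multisets_give_central_u(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.u_statistic == pytest.approx(4.5)  # n1*n2/2

    def test_antisymmetry_under_swap(self):
        x, y = [1.0, 5.0, 9.0], [2.0, 3.0]
        a = mann_whitney_u(x, y)
        b = mann_whitney_u(y, x)
        assert a.u_statistic + b.u_statistic == pytest.approx(len(x) * len(y))
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning):
            res = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(StatsTestError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 3), (3, 3), (4, 4), (5, 5), (3, 7)])
    def test_exact_p_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            pooled = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            x, y = pooled[:n1], pooled[n1:]
            res = mann_whitney_u(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(_enumerate_mwu_p(x, y), abs=1e-12)

    def test_ties_fall_back_to_asymptotic(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [2.0, 4.0, 5.0, 6.0]
        res = mann_whitney_u(x, y)
        assert res.method == "asymptotic"
        assert 0 < res.p_value <= 1


class TestSoilComparisons:
    def test_planted_contrast_detected_and_layout(self):
        design = syn.generate_design({"ST": {"B": 10, "M": 10}, "PE": {"B": 10, "M": 10}})
        soil = syn.simulate_soil_table(design, seed=3)
        table = soil_comparison_table(soil, design.stations)
        overall = table[table["comparison"] == "overall"].set_index("variable")
        assert overall.loc["coarse_sand", "p"] < 0.05
        assert overall.loc["coarse_sand", "ST_mean"] > overall.loc["coarse_sand", "PE_mean"]
        # one row per variable per comparison: overall + 2 covers present
        assert set(table["comparison"]) == {"overall", "cover_B", "cover_M"}
        assert (table.groupby("comparison").size() == 9).all()

    def test_null_soil_mostly_nonsignificant(self):
        design = syn.generate_design({"ST": {"B": 15}, "PE": {"B": 15}})
        params = {"ST": syn.DEFAULT_SOIL_PARAMS["PE"], "PE": syn.DEFAULT_SOIL_PARAMS["PE"]}
        rates = []
        for seed in range(20):
            soil = syn.simulate_soil_table(design, seed=seed, group_params=params)
            table = soil_comparison_table(soil, design.stations, by_cover=False)
            rates.append((table["p"] < 0.05).mean())
        assert np.mean(rates) < 0.15

    def test_unknown_station_sample_skipped(self, caplog):
        design = syn.generate_design({"ST": {"B": 3}, "PE": {"B": 3}})
        soil = syn.simulate_soil_table(design, seed=1)
        soil.data.loc[soil.data.index[0], "station_id"] = "nowhere"
        table = soil_comparison_table(soil, design.stations, by_cover=False)
        assert len(table) == 9


def test_significance_star_tiers():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == "NS"
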
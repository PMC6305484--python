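import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from spoilcom import community_data as cd
from spoilcom import synthetic as syn
from spoilcom.indicator import (
    IndicatorError,
    binomial_preference,
    build_species_table,
    classify_cover,
    classify_species,
    classify_substrate,
    indval,
    indval_significance,
)

from conftest import make_matrix, make_stations


def entries_by_group(entries, species_id):
    return {e.group_id: e for e in entries if e.species_id == species_id}


class TestIndVal:
    def test_perfectly_exclusive_species_scores_100(self):
        # present in every station of group A, absent from group B
        m = make_matrix([[4], [2], [7], [0], [0]])
        groups = pd.Series(["A"] * 3 + ["B"] * 2, index=m.unit_ids)
        e = entries_by_group(indval(m, groups), "sp0")
        assert e["A"].indval == pytest.approx(100.0, abs=1e-12)
        assert e["B"].indval == 0.0
        assert e["A"].assigned and not e["B"].assigned

    def test_hand_worked_eight_station_example(self):
        """Group j holds 4 of 8 stations; the species has 30 of its 60
        individuals there, occupying 2 of j's 4 stations -> A=B=0.5,
        IndVal=25."""
        counts = [[20], [10], [0], [0],  # group j: 30 individuals, 2 occupied
                  [10], [10], [5], [5]]  # elsewhere: 30 individuals
        m = make_matrix(counts)
        groups = pd.Series(["j"] * 4 + ["k"] * 4, index=m.unit_ids)
        e = entries_by_group(indval(m, groups), "sp0")["j"]
        assert e.a == pytest.approx(0.5, abs=1e-12)
        assert e.b == pytest.approx(0.5, abs=1e-12)
        assert e.indval == pytest.approx(25.0, abs=1e-12)

    def test_absent_species_scores_zero(self):
        m = make_matrix([[3, 0], [5, 0], [0, 4], [0, 6]])
        groups = pd.Series(["A", "A", "B", "B"], index=m.unit_ids)
        e = entries_by_group(indval(m, groups), "sp0")
        assert e["B"].indval == 0.0

    def test_specificity_sums_to_one_across_groups(self, toy_matrix, toy_groups):
        entries = indval(toy_matrix, toy_groups)
        for sp in toy_matrix.species_ids:
            a_sum = sum(e.a for e in entries if e.species_id == sp)
            assert a_sum == pytest.approx(1.0, abs=1e-12)

    def test_indval_in_range_and_scale_invariant(self, toy_matrix, toy_groups):
        entries = indval(toy_matrix, toy_groups)
        assert all(0 <= e.indval <= 100 for e in entries)
        scaled = cd.CommunityMatrix(toy_matrix.data * 7, level=toy_matrix.level)
        entries_scaled = indval(scaled, toy_groups)
        for e1, e2 in zip(entries, entries_scaled):
            assert e1.indval == pytest.approx(e2.indval, abs=1e-12)

    def test_group_mean_denominator_variant(self):
        # unbalanced groups: total- and mean-based specificity disagree
        m = make_matrix([[10], [0], [0], [10]])
        groups = pd.Series(["A", "A", "A", "B"], index=m.unit_ids)
        tot = entries_by_group(indval(m, groups), "sp0")
        mean = entries_by_group(indval(m, groups, a_denominator="group_mean"), "sp0")
        assert tot["A"].a == pytest.approx(0.5)
        assert mean["A"].a == pytest.approx((10 / 3) / (10 / 3 + 10))

    def test_group_with_zero_stations_rejected(self, toy_matrix):
        groups = pd.Series(["A"] * 3, index=toy_matrix.unit_ids[:3])
        with pytest.raises(IndicatorError):
            indval(toy_matrix, groups)


class TestIndValSignificance:
    def test_exclusive_species_highly_significant(self):
        counts = [[5]] * 10 + [[0]] * 10
        m = make_matrix(counts)
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=m.unit_ids)
        p = indval_significance(m, groups, n_perm=999, seed=1)
        assert p["sp0"] <= 0.01

    def test_uniform_species_not_significant(self):
        counts = [[3]] * 12
        m = make_matrix(counts)
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=m.unit_ids)
        p = indval_significance(m, groups, n_perm=499, seed=2)
        assert p["sp0"] > 0.9

    def test_same_seed_identical_p_vector(self, toy_matrix, toy_groups):
        p1 = indval_significance(toy_matrix, toy_groups, n_perm=99, seed=7)
        p2 = indval_significance(toy_matrix, toy_groups, n_perm=99, seed=7)
        assert (p1 == p2).all()

    def test_super_uniform_under_null(self):
        """On label-shuffled data P(p <= alpha) stays near or below alpha."""
        rng = np.random.default_rng(3)
        rejections, trials = 0, 0
        for sim in range(30):
            counts = rng.poisson(3.0, size=(16, 5))
            m = make_matrix(counts + (counts.sum(axis=1, keepdims=True) == 0))
            groups = pd.Series(rng.permutation(["A"] * 8 + ["B"] * 8), index=m.unit_ids)
            p = indval_significance(m, groups, n_perm=199, seed=sim)
            rejections += int((p <= 0.05).sum())
            trials += len(p)
        assert rejections / trials <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / trials) + 0.02

    def test_n_perm_validation(self, toy_matrix, toy_groups):
        with pytest.raises(IndicatorError):
            indval_significance(toy_matrix, toy_groups, n_perm=0)


class TestBinomialPreference:
    def test_total_preference_hand_value(self):
        # 10 of 10 individuals in ST with equal station shares
        res = binomial_preference({"ST": 10, "PE": 0}, {"ST": 5, "PE": 5})
        assert res.favored_group == "ST"
        assert res.p0 == 0.5
        assert res.p_value == pytest.approx(2 * 2 ** -10, rel=1e-9)

    def test_proportional_counts_not_significant(self):
        # counts exactly at expectation under the station shares
        res = binomial_preference({"ST": 37, "PE": 44}, {"ST": 37, "PE": 44})
        assert res.p_value >= 0.99

    def test_station_share_correction(self):
        # 60% of individuals in a group holding 60% of stations: no signal
        res = binomial_preference({"ST": 60, "PE": 40}, {"ST": 60, "PE": 40})
        assert res.p_value > 0.5

    def test_zero_individuals_rejected(self):
        with pytest.raises(IndicatorError):
            binomial_preference({"ST": 0, "PE": 0}, {"ST": 5, "PE": 5})

    def test_matches_scipy_tail_construction(self):
        res = binomial_preference({"ST": 9, "PE": 3}, {"ST": 4, "PE": 8})
        from scipy.stats import binomtest

        assert res.p_value == pytest.approx(
            binomtest(9, 12, 4 / 12, alternative="two-sided").pvalue
        )


def _mk_entries(iv_by_group):
    from spoilcom.indicator import IndValEntry

    best = max(iv_by_group.values())
    return [
        IndValEntry("sp", g, a=0.0, b=0.0, indval=v, assigned=(v == best))
        for g, v in iv_by_group.items()
    ]


def _mk_binom(favored, p):
    from spoilcom.indicator import BinomialPreference

    return BinomialPreference(favored_group=favored, successes=1, n=1, p0=0.5, p_value=p)


class TestSubstrateTree:
    @pytest.mark.parametrize(
        "iv_p, argmax_st, binom_p, binom_fav, expected",
        [
            (0.01, True, 0.5, "ST", "pioneer"),
            (0.01, False, 0.5, "PE", "stenoecious"),
            (0.20, True, 0.01, "ST", "colonizing"),
            (0.20, False, 0.01, "PE", "opportunist"),
            (0.20, True, 0.40, "ST", "euryecious"),
        ],
    )
    def test_five_situations(self, iv_p, argmax_st, binom_p, binom_fav, expected):
        iv = {"ST": 60.0, "PE": 30.0} if argmax_st else {"ST": 30.0, "PE": 60.0}
        pref = classify_substrate(_mk_entries(iv), _mk_binom(binom_fav, binom_p), iv_p)
        assert pref.category == expected

    def test_missing_group_entry_rejected(self):
        with pytest.raises(IndicatorError):
            classify_substrate(_mk_entries({"ST": 50.0}), _mk_binom("ST", 0.5), 0.5)


class TestCoverTree:
    def test_exclusive(self):
        iv = {"B": 5.0, "M": 5.0, "S": 5.0, "T": 80.0}
        pref = classify_cover(_mk_entries(iv), _mk_binom("T", 0.3), 0.02, 4)
        assert pref.category == "exclusive"
        assert pref.favored == ("T",)

    def test_elective_two_covers(self):
        iv = {"B": 0.0, "M": 50.0, "S": 40.0, "T": 0.0}
        pref = classify_cover(_mk_entries(iv), _mk_binom("M", 0.01), 0.3, 2)
        assert pref.category == "elective"
        assert pref.favored == ("M",)

    def test_preferring_three_covers(self):
        iv = {"B": 30.0, "M": 40.0, "S": 0.0, "T": 20.0}
        pref = classify_cover(_mk_entries(iv), _mk_binom("M", 0.01), 0.3, 3)
        assert pref.category == "preferring"

    def test_indifferent(self):
        iv = {"B": 25.0, "M": 25.0, "S": 0.0, "T": 25.0}
        pref = classify_cover(_mk_entries(iv), _mk_binom("M", 0.2), 0.4, 3)
        assert pref.category == "indifferent"
        assert pref.favored == ()

    def test_zero_covers_rejected(self):
        with pytest.raises(IndicatorError):
            classify_cover(_mk_entries({"B": 0.0}), _mk_binom("B", 1.0), 1.0, 0)


class TestEndToEndClassification:
    @pytest.fixture(scope="class")
    @staticmethod
    def classified():
        design = syn.generate_design()
        pool = syn.strong_effect_pool()
        m, truth = syn.simulate_community(pool, design, seed=101)
        pooled = cd.pool_replicates(m, syn.replicate_mapping(design))
        pooled, _ = cd.filter_rare_species(pooled, 10)
        cls = classify_species(pooled, design.stations, n_perm=299, seed=5)
        return cls, truth

    def test_partition_one_label_each(self, classified):
        cls, _ = classified
        for c in cls:
            assert c.substrate.category in (
                "pioneer", "stenoecious", "colonizing", "opportunist", "euryecious"
            )
            assert c.cover.category in ("exclusive", "elective", "preferring", "indifferent")

    def test_planted_pioneer_recovered(self, classified):
        cls, truth = classified
        by_sp = {c.species_id: c for c in cls}
        pioneers = truth.index[truth["truth_substrate_label"] == "pioneer"]
        hits = [
            by_sp[sp].substrate.category == "pioneer"
            for sp in pioneers if sp in by_sp
        ]
        assert np.mean(hits) >= 0.8

    def test_species_table_layout(self, classified):
        cls, _ = classified
        table = build_species_table(cls)
        assert list(table.columns) == [
            "N", "substrate_pref", "substrate_stars", "substrate_qualif",
            "cover_code", "cover_stars", "cover_qualif",
        ]
        assert table.index.is_monotonic_increasing
        assert (table["N"] > 0).all()
        pioneers = table[table["substrate_qualif"] == "pioneer"]
        assert (pioneers["substrate_pref"] == "ST").all()
        assert (pioneers["substrate_stars"] != "").all()

    def test_empty_input_gives_empty_table(self):
        assert len(build_species_table([])) == 0


class TestAlphaMonotonicity:
    def test_stricter_alpha_only_demotes_significant_tiers(self, toy_matrix, toy_groups):
        st = make_stations(
            ["ST", "ST", "ST", "PE", "PE", "PE"],
            ["B", "M", "S", "B", "M", "S"],
            ids=toy_matrix.unit_ids,
        )
        loose = classify_species(toy_matrix, st, n_perm=199, alpha=0.5, seed=3)
        strict = classify_species(toy_matrix, st, n_perm=199, alpha=0.001, seed=3)
        sig = {"pioneer", "stenoecious"}
        for lo, hi in zip(loose, strict):
            if hi.substrate.category in sig:  # significant at strict alpha
                assert lo.substrate.category in sig  # must be significant at loose too
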
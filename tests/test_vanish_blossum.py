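"""Predictor unions, direction calls, threshold groups, outcome tests."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from gutshift import (assign_groups, classify_direction, compare_outcomes,
                      union_top_predictors)
from gutshift.io import SITE_ORDER


def ranking_of(ids):
    return pd.DataFrame({"feature": ids,
                         "mean_importance": np.linspace(1, 0.1, len(ids))})


def pa_with_prevalence(prev_by_site, n_per_site=20):
    """Deterministic presence-absence matrix hitting exact prevalences."""
    rows, sites = [], []
    for s_idx, site in enumerate(SITE_ORDER):
        for i in range(n_per_site):
            rows.append([1 if i < round(p[s_idx] * n_per_site) else 0
                         for p in prev_by_site.values()])
            sites.append(site)
    pa = pd.DataFrame(rows, columns=list(prev_by_site),
                      index=[f"s{i}" for i in range(len(rows))])
    meta = pd.DataFrame({"site": pd.Categorical(sites, categories=SITE_ORDER,
                                                ordered=True)}, index=pa.index)
    return pa, meta


class TestUnion:
    def test_one_overlap_gives_19(self):
        a = ranking_of([f"a{i}" for i in range(10)] + ["x1"])
        b = ranking_of(["a0"] + [f"b{i}" for i in range(9)] + ["x2"])
        assert len(union_top_predictors(a, b, k=10)) == 19

    def test_two_overlaps_give_18(self):
        a = ranking_of([f"a{i}" for i in range(10)])
        b = ranking_of(["a0", "a1"] + [f"b{i}" for i in range(8)])
        union = union_top_predictors(a, b, k=10)
        assert len(union) == 18
        assert union[:10] == [f"a{i}" for i in range(10)]  # first-seen order

    def test_identical_lists_give_10(self):
        a = ranking_of([f"a{i}" for i in range(10)])
        assert len(union_top_predictors(a, a.copy(), k=10)) == 10

    def test_short_ranking_rejected(self):
        a = ranking_of(["a", "b"])
        with pytest.raises(ValueError, match="need 10"):
            union_top_predictors(a, a, k=10)


class TestClassifyDirection:
    def test_directions_from_endpoint_prevalences(self):
        pa, meta = pa_with_prevalence({
            "down": (0.8, 0.5, 0.1), "up": (0.05, 0.3, 0.6), "flat": (0.5, 0.9, 0.5)})
        with pytest.warns(UserWarning, match="indeterminate"):
            out = classify_direction(["down", "up", "flat"], pa, meta)
        out = out.set_index("asv")
        assert out.loc["down", "direction"] == "vanish"
        assert out.loc["up", "direction"] == "blossum"
        assert "flat" not in out.index  # endpoint tie excluded
        assert out.loc["down", "prevalence_rural"] == pytest.approx(0.8)

    def test_missing_site_rejected(self):
        pa, meta = pa_with_prevalence({"a": (0.5, 0.5, 0.9)})
        meta = meta[meta["site"] != "urban"]
        with pytest.raises(ValueError, match="urban"):
            classify_direction(["a"], pa.loc[meta.index], meta)

    def test_recovers_generator_truth(self, small_cohort):
        c = small_cohort
        pa = (c.counts > 0).astype(int)
        planted = pd.concat([c.truth.vanish, c.truth.blossum])
        out = classify_direction(planted["asv"].tolist(), pa, c.metadata)
        out = out.set_index("asv")
        for asv in c.truth.vanish["asv"]:
            assert out.loc[asv, "direction"] == "vanish"
        for asv in c.truth.blossum["asv"]:
            assert out.loc[asv, "direction"] == "blossum"


def predictors_frame(vanish_ids, blossum_ids):
    return pd.DataFrame({
        "asv": list(vanish_ids) + list(blossum_ids),
        "direction": ["vanish"] * len(vanish_ids) + ["blossum"] * len(blossum_ids)})


class TestAssignGroups:
    def test_threshold_membership(self):
        vanish = [f"v{i}" for i in range(13)]
        pa = pd.DataFrame(1, index=["absent10", "allpresent"], columns=vanish)
        pa.loc["absent10", vanish[:10]] = 0
        groups = assign_groups(pa, predictors_frame(vanish, []),
                               vanish_min_absent=10, blossum_min_present=0)
        assert bool(groups.vanish["absent10"])
        assert not bool(groups.vanish["allpresent"])

    def test_threshold_exceeding_set_size_rejected(self):
        pa = pd.DataFrame(1, index=["s"], columns=["v0"])
        with pytest.raises(ValueError, match="exceeds"):
            assign_groups(pa, predictors_frame(["v0"], []), vanish_min_absent=2,
                          blossum_min_present=0)

    def test_column_order_invariance_and_monotone_threshold(self, rng):
        vanish = [f"v{i}" for i in range(6)]
        blossum = [f"b{i}" for i in range(4)]
        pa = pd.DataFrame(rng.integers(0, 2, size=(40, 10)),
                          columns=vanish + blossum)
        pred = predictors_frame(vanish, blossum)
        g1 = assign_groups(pa, pred, vanish_min_absent=3, blossum_min_present=2)
        shuffled = pa[list(rng.permutation(pa.columns))]
        g2 = assign_groups(shuffled, pred, vanish_min_absent=3, blossum_min_present=2)
        pd.testing.assert_series_equal(g1.vanish, g2.vanish)
        stricter = assign_groups(pa, pred, vanish_min_absent=4, blossum_min_present=2)
        assert stricter.vanish.sum() <= g1.vanish.sum()
        assert (stricter.vanish <= g1.vanish).all()  # strictly nested

    def test_qualifying_absence_patterns_count_378(self):
        # every 13-bit presence pattern as one sample
        vanish = [f"v{i}" for i in range(13)]
        patterns = list(product([0, 1], repeat=13))
        pa = pd.DataFrame(patterns, columns=vanish)
        groups = assign_groups(pa, predictors_frame(vanish, []),
                               vanish_min_absent=10, blossum_min_present=0)
        n_qualifying = int(groups.vanish.sum())
        assert n_qualifying == 378
        assert n_qualifying == sum(comb(13, k, exact=True) for k in range(10, 14))


class TestCompareOutcomes:
    def test_chi_square_matches_hand_formula(self, rng):
        # 2x2 table chi-square without continuity correction:
        # N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        n = 120
        index = [f"s{i}" for i in range(n)]
        meta = pd.DataFrame({
            "bmi": rng.normal(27, 4, n),
            "diabetes": rng.integers(0, 2, n)}, index=index)
        from gutshift.vanish_blossum import GroupAssignment
        membership = pd.Series(rng.integers(0, 2, n).astype(bool), index=index)
        groups = GroupAssignment(vanish=membership, blossum=~membership,
                                 vanish_min_absent=1, blossum_min_present=1,
                                 vanish_taxa=["v"], blossum_taxa=["b"])
        out = compare_outcomes(groups, meta, continuous=["bmi"], binary=["diabetes"])
        row = out[(out.group_axis == "vanish") & (out.variable == "diabetes")].iloc[0]
        a = int((membership & (meta.diabetes == 1)).sum())
        b = int((membership & (meta.diabetes == 0)).sum())
        c = int((~membership & (meta.diabetes == 1)).sum())
        d = int((~membership & (meta.diabetes == 0)).sum())
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert row["statistic"] == pytest.approx(expected)
        assert row["test"] == "chi-square"

    def test_zero_expected_cell_falls_back_to_fisher(self, rng):
        n = 40
        index = [f"s{i}" for i in range(n)]
        meta = pd.DataFrame({"diabetes": np.zeros(n, dtype=int)}, index=index)
        from gutshift.vanish_blossum import GroupAssignment
        membership = pd.Series([True] * 20 + [False] * 20, index=index)
        groups = GroupAssignment(vanish=membership, blossum=membership,
                                 vanish_min_absent=1, blossum_min_present=1,
                                 vanish_taxa=["v"], blossum_taxa=["b"])
        with pytest.warns(UserWarning, match="Fisher"):
            out = compare_outcomes(groups, meta, continuous=[], binary=["diabetes"])
        assert (out["test"] == "fisher-exact").all()

    def test_planted_bmi_shift_detected(self, rng):
        n = 300
        index = [f"s{i}" for i in range(n)]
        membership = pd.Series([True] * 150 + [False] * 150, index=index)
        meta = pd.DataFrame({"bmi": rng.normal(25, 5, n)}, index=index)
        meta.loc[membership, "bmi"] += 2.0
        from gutshift.vanish_blossum import GroupAssignment
        groups = GroupAssignment(vanish=membership, blossum=membership,
                                 vanish_min_absent=1, blossum_min_present=1,
                                 vanish_taxa=["v"], blossum_taxa=["b"])
        out = compare_outcomes(groups, meta, continuous=["bmi"], binary=[])
        assert (out.loc[out.group_axis == "vanish", "p"] < 0.05).all()
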
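import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

import semharm as sh
from semharm.errors import EmptyInputError
from semharm.rating_study import (
    GROUP_BOTTOM,
    GROUP_MID,
    GROUP_TOP,
    model_classes_from_threshold,
)


def pairs_for_instrument(scores, instrument="A", other="B"):
    n = len(scores)
    return pd.DataFrame(
        {
            "pair_id": [f"p{str(i).zfill(2)}" for i in range(n)],
            "item_a": [f"{instrument}#{i}" for i in range(n)],
            "item_b": [f"{other}#{i}" for i in range(n)],
            "instrument_a": instrument,
            "instrument_b": other,
            "cross_instrument": True,
            "score": scores,
        }
    )


class TestBuildCandidateGroups:
    def test_fifteen_distinct_scores_three_disjoint_groups(self):
        scores = np.linspace(-0.9, 0.9, 15)
        groups = sh.build_candidate_groups(pairs_for_instrument(scores), "A", group_size=5)
        top = set(groups.top["pair_id"])
        mid = set(groups.middle["pair_id"])
        bot = set(groups.bottom["pair_id"])
        assert len(top) == len(mid) == len(bot) == 5
        assert not (top & mid or top & bot or mid & bot)
        assert groups.top["score"].min() > groups.middle["score"].max()
        assert groups.middle["score"].min() > groups.bottom["score"].max()

    def test_seven_pairs_union_covers_all_after_dedup(self):
        # brute-force expectation on a printed toy score list
        scores = [0.9, 0.7, 0.5, 0.4, 0.3, 0.1, -0.2]
        groups = sh.build_candidate_groups(pairs_for_instrument(scores), "A", group_size=5)
        top = set(groups.top["pair_id"])
        bot = set(groups.bottom["pair_id"])
        mid = set(groups.middle["pair_id"])
        assert len(top) == 5
        assert top == {"p00", "p01", "p02", "p03", "p04"}  # 5 highest
        assert bot == {"p05", "p06"}  # lowest pairs not already claimed
        assert mid == set()  # nothing left
        assert top | bot | mid == {f"p0{i}" for i in range(7)}

    def test_middle_group_minimizes_distance_to_eligible_mean(self):
        scores = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
                           -0.4, -0.3, -0.2, -0.1])
        pairs = pairs_for_instrument(scores)
        groups = sh.build_candidate_groups(pairs, "A", group_size=5)
        mean = scores.mean()
        claimed = set(groups.top["pair_id"]) | set(groups.bottom["pair_id"])
        rest = pairs[~pairs["pair_id"].isin(claimed)]
        expected = set(
            rest.assign(dev=(rest["score"] - mean).abs())
            .sort_values(["dev", "pair_id"])
            .head(5)["pair_id"]
        )
        assert set(groups.middle["pair_id"]) == expected

    def test_tie_break_by_pair_id(self):
        scores = [0.5] * 15
        groups = sh.build_candidate_groups(pairs_for_instrument(scores), "A", group_size=5)
        assert list(groups.top["pair_id"]) == [f"p0{i}" for i in range(5)]
        assert list(groups.bottom["pair_id"]) == ["p05", "p06", "p07", "p08", "p09"]

    def test_eligibility_requires_membership(self):
        pairs = pairs_for_instrument([0.3, 0.6], instrument="A", other="B")
        with pytest.raises(EmptyInputError, match="C"):
            sh.build_candidate_groups(pairs, "C")

    def test_eligible_means_at_least_one_member(self):
        pairs = pd.concat(
            [
                pairs_for_instrument([0.2, 0.4], instrument="A", other="B"),
                pairs_for_instrument([0.6, 0.8], instrument="B", other="C").assign(
                    pair_id=["q0", "q1"]
                ),
            ],
            ignore_index=True,
        )
        groups = sh.build_candidate_groups(pairs, "B", group_size=5)
        union = pd.concat([groups.top, groups.middle, groups.bottom])
        assert set(union["pair_id"]) == {"p00", "p01", "q0", "q1"}


def full_groups(m_instruments=31, group_size=5, seed=0):
    """One instrument's worth of >=15 distinct-score pairs, for m instruments."""
    rng = np.random.default_rng(seed)
    groups = {}
    for i in range(m_instruments):
        inst = f"I{str(i).zfill(2)}"
        scores = np.sort(rng.uniform(-1, 1, 20))
        pairs = pairs_for_instrument(scores, instrument=inst, other=f"X{i}")
        pairs["pair_id"] = [f"{inst}-{j:02d}" for j in range(len(scores))]
        groups[inst] = sh.build_candidate_groups(pairs, inst, group_size=group_size)
    return groups


class TestSampleStudyPairs:
    def test_31_instruments_pool_of_155_sample_of_20(self):
        sample = sh.sample_study_pairs(full_groups(31), n_final=20, seed=123)
        assert sample.n_preselected == 155
        assert sample.n_final == 20
        assert sample.final["pair_id"].is_unique

    def test_pool_is_five_m_for_m_instruments(self):
        for m in (3, 10, 17):
            sample = sh.sample_study_pairs(full_groups(m), n_final=3, seed=5)
            assert sample.n_preselected == 5 * m

    def test_same_seed_reproducible(self):
        a = sh.sample_study_pairs(full_groups(10), n_final=8, seed=77)
        b = sh.sample_study_pairs(full_groups(10), n_final=8, seed=77)
        assert a.chosen_groups == b.chosen_groups
        assert a.final.equals(b.final)

    def test_chosen_groups_are_valid_names(self):
        sample = sh.sample_study_pairs(full_groups(12), n_final=5, seed=2)
        assert set(sample.chosen_groups.values()) <= {GROUP_TOP, GROUP_MID, GROUP_BOTTOM}

    def test_final_sample_traces_to_chosen_group(self):
        sample = sh.sample_study_pairs(full_groups(9), n_final=10, seed=8)
        for row in sample.final.itertuples(index=False):
            assert sample.chosen_groups[row.instrument] == row.group

    def test_oversized_final_request_raises(self):
        with pytest.raises(ValueError):
            sh.sample_study_pairs(full_groups(2), n_final=11, seed=0)


class TestMeanCI:
    def test_hand_computed_t_interval(self):
        # mean 2, sd 1, half-width t(0.975, df=2) / sqrt(3) = 4.3027 * 0.5774
        mean, lo, hi = sh.mean_ci([1, 2, 3])
        assert mean == pytest.approx(2.0)
        assert hi - mean == pytest.approx(4.3027 / np.sqrt(3), abs=1e-3)
        assert (lo, hi) == (pytest.approx(-0.4843, abs=1e-3), pytest.approx(4.4843, abs=1e-3))

    def test_constant_values_zero_width(self):
        mean, lo, hi = sh.mean_ci([5.0, 5.0, 5.0, 5.0])
        assert mean == lo == hi == 5.0

    def test_interval_contains_mean(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            vals = rng.normal(50, 10, int(rng.integers(2, 30)))
            mean, lo, hi = sh.mean_ci(vals)
            assert lo <= mean <= hi

    def test_untruncated_bounds_may_exceed_percent_range(self):
        _, _, hi = sh.mean_ci([95.0, 99.0, 100.0, 100.0])
        assert hi > 100.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            sh.mean_ci([1.0])


class TestSpearman:
    def test_perfect_monotone(self):
        assert sh.spearman([1, 2, 3], [10, 20, 30]) == (1.0, 0.0)
        assert sh.spearman([1, 2, 3], [3, 2, 1]) == (-1.0, 0.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = [1, 2, 2, 3]
        y = [2, 1, 3, 4]
        rho, _ = sh.spearman(x, y)
        rx = scipy_stats.rankdata(x)
        ry = scipy_stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 10, n).astype(float)  # ties likely
            y = x + rng.normal(0, 3, n)
            rho, p = sh.spearman(x, y)
            ref = scipy_stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            if abs(rho) < 1:
                assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(1, 5, 25)
        y = rng.uniform(1, 5, 25)
        rho, _ = sh.spearman(x, y)
        rho2, _ = sh.spearman(np.exp(x), y**3)
        assert rho2 == pytest.approx(rho, abs=1e-12)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            sh.spearman([1.0, 1.0, 1.0], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sh.spearman([1, 2], [3, 4])


def ratings_table():
    # 4 pairs x 3 raters; pairs p1,p2 model-positive, p3,p4 model-negative
    rows = []
    votes = {
        "p1": [True, True, True],  # 100% agreement with positive
        "p2": [True, True, False],  # 66.67%
        "p3": [False, False, False],  # 100% agreement with negative
        "p4": [False, True, False],  # 66.67%
    }
    pss = {"p1": [9, 8, 9], "p2": [7, 8, 3], "p3": [1, 2, 1], "p4": [2, 6, 3]}
    for pid in votes:
        for r, (s, score) in enumerate(zip(votes[pid], pss[pid])):
            rows.append({"pair_id": pid, "rater_id": f"r{r}", "suitable": s, "pss": score})
    return pd.DataFrame(rows)


MODEL = {"p1": "positive", "p2": "positive", "p3": "negative", "p4": "negative"}


class TestAgreementStats:
    def test_all_raters_agree_means_100(self):
        ratings = ratings_table()
        ratings = ratings[ratings["pair_id"].isin(["p1", "p3"])]
        stats = sh.agreement_stats(ratings, MODEL)
        assert stats.positive_mean == 100.0
        assert stats.negative_mean == 100.0

    def test_class_means_match_brute_force(self):
        stats = sh.agreement_stats(ratings_table(), MODEL)
        # exhaustive hand count: positive (100 + 66.67)/2, negative identical
        assert stats.positive_mean == pytest.approx((100 + 200 / 3) / 2)
        assert stats.negative_mean == pytest.approx((100 + 200 / 3) / 2)
        per_pair = stats.per_pair.set_index("pair_id")
        assert per_pair.loc["p2", "agreement_pct"] == pytest.approx(200 / 3)

    def test_six_of_seven_raters_is_85_714(self):
        rows = [
            {"pair_id": "q", "rater_id": f"r{i}", "suitable": i < 6, "pss": 8}
            for i in range(7)
        ]
        rows += [
            {"pair_id": "neg", "rater_id": f"r{i}", "suitable": False, "pss": 2}
            for i in range(7)
        ]
        stats = sh.agreement_stats(
            pd.DataFrame(rows), {"q": "positive", "neg": "negative"}
        )
        per_pair = stats.per_pair.set_index("pair_id")
        assert per_pair.loc["q", "agreement_pct"] == pytest.approx(600 / 7)

    def test_spearman_between_pss_and_ses(self):
        ses = {"p1": 0.9, "p2": 0.8, "p3": 0.2, "p4": 0.3}
        stats = sh.agreement_stats(ratings_table(), MODEL, ses=ses)
        pss_means = stats.per_pair.set_index("pair_id")["pss_mean"]
        expected, _ = sh.spearman(
            [pss_means[p] for p in sorted(MODEL)], [ses[p] for p in sorted(MODEL)]
        )
        assert stats.spearman_rho == pytest.approx(expected)

    def test_high_variance_pairs_flagged(self):
        stats = sh.agreement_stats(ratings_table(), MODEL)
        per_pair = stats.per_pair.set_index("pair_id")
        assert per_pair.loc["p2", "hard_to_rate"]  # pss 7,8,3
        assert not per_pair.loc["p1", "hard_to_rate"]  # pss 9,8,9

    def test_unclassified_pair_excluded_with_warning(self):
        ratings = ratings_table()
        with pytest.warns(UserWarning, match="excluded"):
            stats = sh.agreement_stats(
                ratings, {k: v for k, v in MODEL.items() if k != "p4"}
            )
        assert stats.excluded_pairs == ["p4"]

    def test_pss_bounds_enforced(self):
        bad = ratings_table()
        bad.loc[0, "pss"] = 11
        with pytest.raises(ValueError, match="1-10"):
            sh.agreement_stats(bad, MODEL)


def test_model_classes_positive_above_threshold():
    pairs = pairs_for_instrument([0.70, 0.751, 0.76])
    classes = model_classes_from_threshold(pairs, tau=0.751)
    assert classes == {"p00": "negative", "p01": "negative", "p02": "positive"}
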
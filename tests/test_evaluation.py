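import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l1mda.core import SolverConfig, predict
from l1mda.evaluation import (
    ablate_disease,
    global_loocv,
    local_loocv,
    rank_candidates,
    roc_auc,
)


def pairwise_auc(scores, labels):
    """Brute-force oracle: count positive-vs-negative wins, ties half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([0.5, 0.5, 0.5], [1, 0, 1]) == 0.5

    def test_mixed_three_point_case(self):
        # two positive-negative pairs: one win (0.8 > 0.6), one loss (0.4 < 0.6)
        scores, labels = [0.8, 0.6, 0.4], [1, 0, 1]
        assert pairwise_auc(scores, labels) == 0.5
        assert roc_auc(scores, labels) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive and one negative"):
            roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from([0.0, 0.25, 0.5, 0.5, 0.75, 1.0]),
                st.integers(0, 1),
            ),
            min_size=2,
            max_size=12,
        )
    )
    def test_matches_exhaustive_pair_counting(self, pairs):
        scores = [s for s, _ in pairs]
        labels = [y for _, y in pairs]
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(pairwise_auc(scores, labels))

    def test_score_negation_complements_auc_when_tie_free(self):
        rng = np.random.default_rng(3)
        scores = rng.permutation(np.linspace(0, 1, 10))
        labels = (rng.random(10) < 0.5).astype(int)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_agrees_with_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(4)
        scores = np.round(rng.random(40), 1)  # coarse grid forces ties
        labels = (rng.random(40) < 0.4).astype(int)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) == pytest.approx(
            sk.roc_auc_score(labels, scores)
        )


def tiny_instance():
    """Two mutually supporting miRNAs plus an isolated one, two diseases."""
    w_m = pd.DataFrame(
        [[1.0, 0.9, 0.05], [0.9, 1.0, 0.05], [0.05, 0.05, 1.0]],
        index=["m1", "m2", "m3"],
        columns=["m1", "m2", "m3"],
    )
    w_d = pd.DataFrame(
        [[1.0, 0.1], [0.1, 1.0]], index=["d1", "d2"], columns=["d1", "d2"]
    )
    a = pd.DataFrame(
        [[1, 1], [1, 1], [0, 0]], index=["m1", "m2", "m3"], columns=["d1", "d2"]
    )
    return w_m, w_d, a


class TestGlobalLoocv:
    def test_rejects_single_known_association(self):
        w_m, w_d, a = tiny_instance()
        a1 = a.copy()
        a1.loc[:, :] = 0
        a1.iloc[0, 0] = 1
        with pytest.raises(ValueError, match=">= 2 known"):
            global_loocv(w_m, w_d, a1)

    def test_hand_traceable_fold_ranks_first(self):
        # held-out (m1, d1) is supported by its similar partner's d1
        # association; the unconfirmed pairs all involve the isolated m3
        w_m, w_d, a = tiny_instance()
        result = global_loocv(w_m, w_d, a)
        fold = result.per_fold_ranks.set_index(["mirna_id", "disease_id"])
        assert fold.loc[("m1", "d1"), "rank"] == 1.0
        assert result.auc == 1.0

    def test_associations_restored_between_folds(self):
        w_m, w_d, a = tiny_instance()
        before = a.to_numpy().copy()
        global_loocv(w_m, w_d, a)
        assert np.array_equal(a.to_numpy(), before)

    def test_one_fold_per_known_association(self, planted, planted_global_cv):
        assert len(planted_global_cv.per_fold_ranks) == planted.A.to_numpy().sum()

    def test_auc_in_unit_interval(self, planted_global_cv):
        assert 0.0 <= planted_global_cv.auc <= 1.0

    def test_candidate_count_is_unconfirmed_pairs_plus_test(self, planted, planted_global_cv):
        n_zero = int((planted.A.to_numpy() == 0).sum())
        counts = planted_global_cv.per_fold_ranks["candidate_count"]
        assert (counts == n_zero + 1).all()


class TestLocalLoocv:
    def test_fold_without_negatives_is_skipped(self):
        # d1 is associated with every miRNA: its folds have no candidates
        w_m = pd.DataFrame(
            [[1.0, 0.9], [0.9, 1.0]], index=["m1", "m2"], columns=["m1", "m2"]
        )
        w_d = pd.DataFrame(
            [[1.0, 0.1], [0.1, 1.0]], index=["d1", "d2"], columns=["d1", "d2"]
        )
        a = pd.DataFrame([[1, 1], [1, 0]], index=["m1", "m2"], columns=["d1", "d2"])
        result = local_loocv(w_m, w_d, a)
        folds = result.per_fold_ranks
        assert (folds["disease_id"] == "d2").all()
        assert len(folds) == 1

    def test_per_disease_auc_keys_subset_of_ranked_diseases(self, planted_local_cv):
        folds = planted_local_cv.per_fold_ranks
        assert set(planted_local_cv.per_disease_auc) == set(folds["disease_id"])

    def test_per_disease_auc_pools_to_overall(self, planted_local_cv):
        folds = planted_local_cv.per_fold_ranks
        # overall pooled statistic is the candidate-weighted combination of
        # the per-disease pooled statistics
        total_wins = 0.0
        total_cand = 0.0
        for disease, auc in planted_local_cv.per_disease_auc.items():
            cand = (folds.loc[folds["disease_id"] == disease, "candidate_count"] - 1).sum()
            total_wins += auc * cand
            total_cand += cand
        assert planted_local_cv.auc == pytest.approx(total_wins / total_cand)

    def test_recovers_planted_structure(self, planted, planted_local_cv):
        folds = planted_local_cv.per_fold_ranks
        is_planted = [
            (m, d) in planted.planted_pairs
            for m, d in zip(folds["mirna_id"], folds["disease_id"])
        ]
        frac = (folds["rank"] / folds["candidate_count"])[is_planted]
        assert frac.median() <= 0.1


@pytest.fixture(scope="module")
def scored(toy_4x2):
    w_m, a = toy_4x2
    w_d = pd.DataFrame(
        [[1.0, 0.3], [0.3, 1.0]], index=a.columns, columns=a.columns
    )
    return predict(w_m, w_d, a, SolverConfig()), a


class TestRankCandidates:
    def test_ordering_matches_scores(self, scored):
        q, a = scored
        ranked = rank_candidates(q, a, "x", k=4)
        scores = [s for _, s, _ in ranked.entries]
        assert scores == sorted(scores, reverse=True)
        assert [r for _, _, r in ranked.entries] == [1, 2, 3, 4]
        # the solved scores put the held-in positive's similar partner high
        expected = q["x"].sort_values(ascending=False).index[:4]
        assert [m for m, _, _ in ranked.entries] == list(expected)

    def test_k_larger_than_candidates_returns_all(self, scored):
        q, a = scored
        assert len(rank_candidates(q, a, "x", k=99).entries) == 4

    def test_exclude_known_removes_exactly_the_positives(self, scored):
        q, a = scored
        ranked = rank_candidates(q, a, "x", k=99, exclude_known=True)
        returned = {m for m, _, _ in ranked.entries}
        known = set(a.index[a["x"] == 1])
        assert returned == set(a.index) - known
        assert ranked.known_excluded

    def test_ties_break_lexicographically(self):
        q = pd.DataFrame({"d": [0.5, 0.5, 0.9]}, index=["mb", "ma", "mc"])
        a = pd.DataFrame({"d": [0, 0, 0]}, index=["mb", "ma", "mc"])
        ranked = rank_candidates(q, a, "d", k=3)
        assert [m for m, _, _ in ranked.entries] == ["mc", "ma", "mb"]

    def test_unknown_disease_rejected(self, scored):
        q, a = scored
        with pytest.raises(KeyError):
            rank_candidates(q, a, "nope")


class TestAblateDisease:
    def test_column_zeroed_others_untouched(self, planted):
        a = planted.A
        disease = a.columns[0]
        ablated = ablate_disease(a, disease)
        assert (ablated[disease] == 0).all()
        others = [c for c in a.columns if c != disease]
        assert np.array_equal(ablated[others].to_numpy(), a[others].to_numpy())

    def test_original_untouched_and_count_conserved(self, planted):
        a = planted.A
        disease = a.columns[1]
        before = a.to_numpy().copy()
        col_sum = int(a[disease].sum())
        ablated = ablate_disease(a, disease)
        assert np.array_equal(a.to_numpy(), before)
        assert int(before.sum()) - int(ablated.to_numpy().sum()) == col_sum

    def test_zero_column_is_identity(self):
        a = pd.DataFrame({"d1": [0, 0], "d2": [1, 0]}, index=["m1", "m2"])
        assert ablate_disease(a, "d1").equals(a)

    def test_unknown_disease_rejected(self, planted):
        with pytest.raises(KeyError):
            ablate_disease(planted.A, "nope")
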
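"""Q2, permutation p, ROC/AUC, Youden, Fisher — against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plsprog.evaluation import (
    ContingencyTable2x2,
    auc_ci,
    fisher_exact_2x2,
    group_compare,
    loo_cv_q2,
    misclassification_error,
    permutation_pvalue,
    roc_auc,
    roc_curve_points,
    youden_threshold,
)


def pairwise_auc_oracle(scores, labels):
    """AUC by exhaustive (positive, negative) pair enumeration."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def point_prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = point_prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(point_prob(x) for x in range(lo, hi + 1) if point_prob(x) <= p_obs + 1e-12)


class TestQ2:
    def test_zero_signal_matches_mean_predictor_identity(self):
        """With featureless X, LOO predicts the fold mean and
        Q2 = 1 - (n/(n-1))^2 exactly."""
        for n in (5, 8, 12):
            X = np.ones((n, 2))  # no variation at all
            y = np.zeros(n)
            y[: n // 2] = 1.0
            q2s, _ = loo_cv_q2(X, y, max_components=1)
            assert q2s[0] == pytest.approx(1 - (n / (n - 1)) ** 2, abs=1e-12)

    def test_separable_data_near_one(self, rng):
        n = 40
        y = np.zeros(n)
        y[:20] = 1.0
        X = np.column_stack([y * 10 + rng.normal(0, 0.1, n), rng.normal(size=n)])
        q2s, sel = loo_cv_q2(X, y, max_components=2)
        assert q2s[sel - 1] > 0.9

    def test_null_simulation_mean_nonpositive(self, rng):
        """y independent of X: mean LOO Q2 over repetitions is <= 0."""
        vals = []
        for _ in range(200):
            X = rng.normal(size=(10, 3))
            y = np.zeros(10)
            y[:5] = 1.0
            rng.shuffle(y)
            q2s, _ = loo_cv_q2(X, y, max_components=1)
            vals.append(q2s[0])
        assert np.mean(vals) <= 0

    def test_selected_maximises(self, rng):
        X = rng.normal(size=(15, 4))
        y = np.zeros(15)
        y[:6] = 1.0
        q2s, sel = loo_cv_q2(X, y, max_components=3)
        assert q2s[sel - 1] == max(q2s)
        assert all(q <= 1 for q in q2s)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            loo_cv_q2(np.ones((3, 1)), np.array([0.0, 1, 0]), 1)


class TestPermutationP:
    @staticmethod
    def _first_call_statistic(observed_value, null_value):
        state = {"first": True}

        def stat(X, y):
            if state.pop("first", False):
                return observed_value
            return null_value

        return stat

    def test_observed_above_all_permuted(self):
        p, _ = permutation_pvalue(
            None, np.array([0.0, 0, 1, 1]), B=999, seed=0,
            statistic=self._first_call_statistic(1.0, 0.0),
        )
        assert p == pytest.approx(1 / 1000)

    def test_observed_below_all_permuted(self):
        p, _ = permutation_pvalue(
            None, np.array([0.0, 0, 1, 1]), B=99, seed=0,
            statistic=self._first_call_statistic(-1.0, 0.0),
        )
        assert p == 1.0

    def test_median_null_statistic_gives_half(self):
        """A statistic sitting at the null median yields p close to 0.5:
        observed 0.495 is the median of permuted values 0.01..0.99."""
        seq = iter([0.495] + [v / 100 for v in range(1, 100)])
        p, _ = permutation_pvalue(
            None, np.array([0.0, 0, 1, 1]), B=99, seed=0,
            statistic=lambda X, y: next(seq),
        )
        assert p == pytest.approx(0.5, abs=0.02)

    def test_reproducible_given_seed(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.zeros(10)
        y[:4] = 1.0
        p1 = permutation_pvalue(X, y, B=49, max_components=1, seed=7)
        p2 = permutation_pvalue(X, y, B=49, max_components=1, seed=7)
        assert p1 == p2


class TestAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 8, 9], [False, False, True, True]) == 1.0

    def test_all_ties(self):
        assert roc_auc([3, 3, 3, 3], [False, True, False, True]) == 0.5

    def test_enumeration_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    @settings(max_examples=50, deadline=None)
    @given(
        scores=st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=12),
        data=st.data(),
    )
    def test_matches_pairwise_oracle(self, scores, data):
        labels = data.draw(
            st.lists(st.booleans(), min_size=len(scores), max_size=len(scores))
        )
        if not (any(labels) and not all(labels)):
            labels[0], labels[-1] = False, True
        assert roc_auc(scores, labels) == pytest.approx(
            pairwise_auc_oracle(scores, labels), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        labels[0], labels[1] = True, False
        base = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(base)
        assert roc_auc(3 * scores - 7, labels) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])


class TestAucCI:
    def test_perfect_separation_upper_bound_one(self, rng):
        scores = np.concatenate([rng.normal(0, 0.1, 30), rng.normal(10, 0.1, 30)])
        labels = np.concatenate([np.zeros(30, bool), np.ones(30, bool)])
        low, high = auc_ci(scores, labels, B=500, seed=1)
        assert high == 1.0
        assert low <= 1.0

    def test_interval_contains_point_estimate(self, rng):
        hits = 0
        reps = 100
        for _ in range(reps):
            scores = rng.normal(size=24) + np.repeat([0, 1.0], 12)
            labels = np.repeat([False, True], 12)
            auc = roc_auc(scores, labels)
            low, high = auc_ci(scores, labels, B=200, seed=rng)
            hits += low - 1e-9 <= auc <= high + 1e-9
        assert hits >= 0.99 * reps

    def test_width_shrinks_with_n(self, rng):
        widths = []
        for n in (20, 80, 320):
            w = []
            for _ in range(20):
                scores = rng.normal(size=n) + np.repeat([0, 1.0], n // 2)
                labels = np.repeat([False, True], n // 2)
                lo, hi = auc_ci(scores, labels, B=200, seed=rng)
                w.append(hi - lo)
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]

    def test_reproducible(self, rng):
        scores = rng.normal(size=20)
        labels = np.repeat([False, True], 10)
        assert auc_ci(scores, labels, seed=5, B=100) == auc_ci(scores, labels, seed=5, B=100)


def youden_brute_force(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    best_j, best_t = -np.inf, None
    distinct = np.unique(scores)
    cands = [-np.inf, *((distinct[:-1] + distinct[1:]) / 2), np.inf]
    for t in cands:
        pred = scores >= t
        j = (pred & labels).sum() / labels.sum() + (~pred & ~labels).sum() / (~labels).sum() - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_t, best_j


class TestYouden:
    def test_clean_separation_midpoint(self):
        t, sens, spec = youden_threshold([0.2, 0.3, 0.6, 0.9], [0, 0, 1, 1])
        assert t == pytest.approx(0.45)
        assert sens == 1.0 and spec == 1.0

    def test_all_ties_j_zero(self):
        t, sens, spec = youden_threshold([1, 1, 1, 1], [0, 1, 0, 1])
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_tie_broken_toward_smallest_threshold(self):
        t, sens, spec = youden_threshold([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert sens + spec - 1 == pytest.approx(0.5)
        assert t == pytest.approx(0.225)  # the lower of the two maximisers

    @settings(max_examples=50, deadline=None)
    @given(
        scores=st.lists(
            st.floats(-3, 3, allow_nan=False).map(lambda x: round(x, 2)),
            min_size=4, max_size=10,
        ),
        data=st.data(),
    )
    def test_matches_brute_force(self, scores, data):
        labels = data.draw(
            st.lists(st.booleans(), min_size=len(scores), max_size=len(scores))
        )
        if not (any(labels) and not all(labels)):
            labels[0], labels[-1] = False, True
        t, sens, spec = youden_threshold(scores, labels)
        t_bf, j_bf = youden_brute_force(scores, labels)
        assert sens + spec - 1 == pytest.approx(j_bf, abs=1e-12)
        assert t == pytest.approx(t_bf)


class TestMisclassification:
    def test_perfect_classifier(self):
        err, ids = misclassification_error([0.1, 0.9], [False, True], 0.5)
        assert err == 0.0 and ids == []

    def test_four_wrong_of_forty(self):
        scores = np.array([0.9] * 4 + [0.1] * 36)
        labels = np.array([False] * 40)
        err, ids = misclassification_error(scores, labels, 0.5)
        assert err == pytest.approx(0.10)
        assert len(ids) == 4

    def test_one_wrong_of_sixteen(self):
        scores = np.array([0.9] + [0.1] * 7 + [0.9] * 8)
        labels = np.array([False] * 8 + [True] * 8)
        err, ids = misclassification_error(scores, labels, 0.5, ids=[f"s{i}" for i in range(16)])
        assert err == pytest.approx(0.0625)
        assert ids == ["s0"]


class TestFisher:
    def test_symmetric_table_is_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [(9, 3, 7, 21), (4, 8, 0, 28), (2, 5, 3, 1), (0, 6, 4, 2)])
    def test_matches_enumeration_oracle(self, table):
        p = fisher_exact_2x2(ContingencyTable2x2(*table))
        assert p == pytest.approx(fisher_enumeration_oracle(*table), abs=1e-12)

    def test_exhaustive_small_tables(self):
        """Every feasible table with n <= 12 agrees with enumeration."""
        for a, b, c, d in itertools.product(range(4), repeat=4):
            if a + b + c + d == 0:
                continue
            p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d), abs=1e-10)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 1, 1, 1)


class TestGroupCompare:
    def test_identical_groups(self):
        res = group_compare([1.0, 2, 3], [1.0, 2, 3])
        assert res["t_stat"] == pytest.approx(0.0)
        assert res["t_p"] == pytest.approx(1.0)

    def test_disjoint_support_extreme_u(self):
        a = np.arange(10, 20, dtype=float)
        b = np.arange(0, 10, dtype=float)
        res = group_compare(b, a)
        assert res["u_stat"] == 0.0

    def test_welch_t_matches_reference_formula(self, rng):
        a, b = rng.normal(0, 1, 14), rng.normal(0.5, 2, 9)
        res = group_compare(a, b)
        se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        t = (a.mean() - b.mean()) / se
        df = se**4 / (
            (a.var(ddof=1) / len(a)) ** 2 / (len(a) - 1)
            + (b.var(ddof=1) / len(b)) ** 2 / (len(b) - 1)
        )
        from scipy import stats as sps

        p = 2 * sps.t.sf(abs(t), df)
        assert res["t_stat"] == pytest.approx(t, abs=1e-9)
        assert res["t_p"] == pytest.approx(p, abs=1e-9)

    def test_dichotomous_uses_fisher(self):
        res = group_compare([1.0, 1, 1, 0], [0.0, 0, 0, 1], kind="dichotomous")
        assert 0 < res["fisher_p"] <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1.0, 2])


def test_roc_curve_points_hit_corners(rng):
    scores = rng.normal(size=20)
    labels = np.repeat([False, True], 10)
    fpr, tpr, _ = roc_curve_points(scores, labels)
    assert fpr.min() == 0.0 and tpr.max() == 1.0
    assert fpr.max() == 1.0
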
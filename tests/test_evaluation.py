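import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coughvc.evaluation import (
    bland_altman,
    delong_test,
    friedman,
    holm_adjust,
    mann_whitney,
    partial_correlation_matrix,
    roc_auc,
    screening_confusion,
    screening_score,
    spearman,
    squared_error_table,
    wilcoxon_signed_rank,
)


def brute_force_auc(scores, labels):
    """Pair-counting oracle with ties scored 1/2."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (pos.size * neg.size)


class TestSquaredErrorTable:
    def test_perfect_estimate(self):
        df = squared_error_table([1.0, 2.0], {"m": np.array([1.0, 2.0])})
        assert np.allclose(df["m"], 0.0)

    def test_hand_arithmetic(self):
        df = squared_error_table([4.0, 3.0], {"m": np.array([3.0, 5.0])})
        assert list(df["m"]) == [1.0, 4.0]
        assert df.attrs["mean"]["m"] == 2.5
        assert df.attrs["median"]["m"] == 2.5

    def test_constant_shift_brute_force(self):
        rng = np.random.default_rng(0)
        measured = rng.normal(3, 1, 20)
        est = measured + rng.normal(0, 0.5, 20)
        c = 0.7
        base = squared_error_table(measured, {"m": est})["m"].to_numpy()
        shifted = squared_error_table(measured, {"m": est + c})["m"].to_numpy()
        oracle = np.array([(e - m + c) ** 2 for e, m in zip(est, measured)])
        assert np.allclose(shifted, oracle)
        assert not np.allclose(shifted, base)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            squared_error_table([1.0], {"m": np.array([1.0, 2.0])})


class TestSpearman:
    def test_monotone_pairs(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_exact_permutation_oracle_n6(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([1.0, 3, 2, 4, 6, 5])
        rho, p = spearman(x, y)
        # exhaustive two-sided permutation p-value
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = sum(
            abs(np.corrcoef(rx[list(perm)], ry)[0, 1]) >= obs - 1e-12
            for perm in itertools.permutations(range(6))
        )
        assert p == pytest.approx(count / 720)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_large_n_t_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = x + rng.normal(0, 0.5, 30)
        rho, p = spearman(x, y)
        assert 0 < p < 0.05 and rho > 0.5


class TestBlandAltman:
    def test_identical_vectors(self):
        r = bland_altman([1.0, 2, 3], [1.0, 2, 3])
        assert r.mean_diff == 0.0
        assert r.limits == (0.0, 0.0)
        assert r.proportional_bias_r is None
        assert r.fixed_bias_t is None  # zero-variance diffs

    def test_perfect_proportional_bias(self):
        measured = np.array([1.0, 2, 3, 4, 5])
        estimated = measured * 0.5  # diffs proportional to means
        r = bland_altman(measured, estimated)
        assert abs(r.proportional_bias_r) == pytest.approx(1.0)

    def test_t_statistic_closed_form(self):
        rng = np.random.default_rng(2)
        measured = rng.normal(4, 1, 10)
        estimated = measured - rng.normal(0.3, 0.2, 10)
        r = bland_altman(measured, estimated)
        d = measured - estimated
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert r.fixed_bias_t == pytest.approx(expected_t, rel=1e-12)

    def test_limits_are_mean_pm_two_sd(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(3, 1, 15), rng.normal(3, 1, 15)
        r = bland_altman(a, b)
        d = a - b
        assert r.limits[0] == pytest.approx(d.mean() - 2 * d.std(ddof=1), rel=1e-12)
        assert r.limits[1] == pytest.approx(d.mean() + 2 * d.std(ddof=1), rel=1e-12)


class TestFriedman:
    def test_hand_computation(self):
        # every row ranked (1,2,3): chi2 = (12/(3*3*4)) * (9+36+81) - 3*3*4 = 6
        stat, p = friedman(np.array([[1.0, 2, 3], [1, 2, 3], [1, 2, 3]]))
        assert stat == pytest.approx(6.0)
        assert p == pytest.approx(0.0498, abs=1e-3)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(10, 4))
        s1, _ = friedman(m)
        s2, _ = friedman(m[:, [2, 0, 3, 1]])
        assert s1 == pytest.approx(s2)

    def test_identical_columns_zero(self):
        col = np.arange(5.0)
        stat, p = friedman(np.column_stack([col, col, col]))
        assert stat == 0.0 and p == 1.0

    def test_k2_errors(self):
        with pytest.raises(ValueError, match="paired"):
            friedman(np.ones((5, 2)))


class TestHolm:
    def test_hand_step_down(self):
        assert np.allclose(holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2])[0] == 0.2

    def test_all_equal_capped(self):
        assert np.allclose(holm_adjust([0.2, 0.2, 0.2]), [0.6, 0.6, 0.6])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
    def test_properties(self, ps):
        adj = holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)  # >= raw pointwise
        assert np.all(adj <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in sorted order


class TestRankTests:
    def test_signed_rank_minimum_attainable_p(self):
        x = np.arange(1.0, 9.0)
        _, p = wilcoxon_signed_rank(x, x + 1, alternative="less")
        assert p == pytest.approx(1 / 2**8)

    def test_signed_rank_symmetry(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = x + rng.normal(0.5, 0.3, 10)
        sx, px = wilcoxon_signed_rank(x, y)
        sy, py = wilcoxon_signed_rank(y, x)
        assert px == pytest.approx(py)

    def test_signed_rank_all_tied_errors(self):
        with pytest.raises(ValueError, match="tied"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_signed_rank_exact_enumeration_oracle(self):
        # n=5, distinct |d|: enumerate all 2^5 sign patterns
        x = np.array([1.0, 2, 3, 4, 5])
        y = x - np.array([0.5, 1.5, 2.5, 3.5, 4.5])
        stat, p = wilcoxon_signed_rank(x, y)
        d = x - y
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = 0
        for signs in itertools.product([1, -1], repeat=5):
            w = min(
                sum(r for r, s in zip(ranks, signs) if s > 0),
                sum(r for r, s in zip(ranks, signs) if s < 0),
            )
            count += w <= w_obs
        assert p == pytest.approx(count / 32)

    def test_mann_whitney_shift(self):
        x = np.array([1.0, 2, 3, 4])
        y = x + 10
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(2 / 70)  # 2 * 1/C(8,4) exact two-sided


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc(np.array([1.0, 2, 3, 10, 11]), np.array([0, 0, 0, 1, 1], bool))
        assert r.auc == 1.0

    def test_hand_fixture(self):
        labels = np.array([1, 1, 0, 0], dtype=bool)
        scores = np.array([0.9, 0.2, 0.8, 0.1])
        assert roc_auc(scores, labels).auc == pytest.approx(0.75)

    def test_all_ties_half(self):
        r = roc_auc(np.ones(6), np.array([1, 1, 1, 0, 0, 0], bool))
        assert r.auc == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.ones(4, bool))

    def test_curve_monotone(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=20)
        labels = rng.uniform(size=20) < 0.4
        r = roc_auc(scores, labels)
        assert np.all(np.diff(r.fpr) >= 0)
        assert np.all(np.diff(r.tpr) >= 0)

    @settings(max_examples=100, deadline=None)
    @given(
        n=st.integers(min_value=4, max_value=12),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_matches_brute_force(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, n).astype(float)  # force ties
        labels = np.zeros(n, bool)
        labels[: rng.integers(1, n)] = True
        rng.shuffle(labels)
        if labels.all() or not labels.any():
            return
        assert roc_auc(scores, labels).auc == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


def jackknife_variance(scores, labels):
    """Grouped delete-one jackknife AUC variance via brute-force pair counts."""
    var = 0.0
    for cls in (True, False):
        idx = np.flatnonzero(labels == cls)
        loo = []
        for i in idx:
            mask = np.ones(labels.size, bool)
            mask[i] = False
            loo.append(brute_force_auc(scores[mask], labels[mask]))
        loo = np.asarray(loo)
        g = idx.size
        var += (g - 1) / g * np.sum((loo - loo.mean()) ** 2)
    return var


class TestDeLong:
    def test_identical_scores_degenerate(self):
        scores = np.arange(10.0)
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 1, 0, 1], bool)
        r = delong_test(scores, scores, labels)
        assert r.degenerate and r.p == 1.0 and r.auc_a == r.auc_b

    def test_variance_matches_jackknife(self):
        rng = np.random.default_rng(7)
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], bool)
        a = rng.normal(size=10) + labels
        r = delong_test(a, rng.normal(size=10), labels)
        # single-curve variance: DeLong == grouped jackknife exactly
        import numpy.testing as npt

        from coughvc.evaluation import _placements

        v10, v01, auc = _placements(a[labels], a[~labels])
        delong_var = np.var(v10, ddof=1) / 4 + np.var(v01, ddof=1) / 6
        npt.assert_allclose(delong_var, jackknife_variance(a, labels), atol=1e-10)

    def test_antisymmetry(self):
        rng = np.random.default_rng(8)
        labels = np.array([1] * 5 + [0] * 7, bool)
        a = rng.normal(size=12) + labels
        b = rng.normal(size=12) + 0.3 * labels
        r1 = delong_test(a, b, labels)
        r2 = delong_test(b, a, labels)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)

    def test_internal_auc_matches_roc_auc(self):
        rng = np.random.default_rng(9)
        labels = np.array([1] * 6 + [0] * 6, bool)
        a = rng.normal(size=12) + labels
        b = rng.normal(size=12)
        r = delong_test(a, b, labels)
        assert r.auc_a == pytest.approx(roc_auc(a, labels).auc)
        assert r.auc_b == pytest.approx(roc_auc(b, labels).auc)


class TestScreening:
    def test_perfect_estimates(self):
        measured = np.array([2.0, 3.0, 4.0, 5.0])
        lln_values = np.array([3.5, 3.5, 3.5, 3.5])
        r = screening_confusion(measured, measured, lln_values)
        assert r["TPR"] == 1.0 and r["FPR"] == 0.0

    def test_estimates_all_above_lln(self):
        measured = np.array([2.0, 3.0, 4.0])
        lln_values = np.array([3.5, 3.5, 3.5])
        r = screening_confusion(lln_values + 0.1, measured, lln_values)
        assert r["TPR"] == 0.0 and r["FNR"] == 1.0

    def test_hand_tally_six_subjects(self):
        measured = np.array([2.0, 2.5, 3.0, 4.0, 4.5, 5.0])
        lln_vals = np.full(6, 3.2)
        estimates = np.array([2.1, 3.5, 2.9, 3.0, 4.8, 5.1])
        r = screening_confusion(estimates, measured, lln_vals)
        # positives (measured<3.2): idx 0,1,2 -> predicted: 0 yes, 1 no, 2 yes
        # negatives: idx 3,4,5 -> predicted positive: idx 3 only
        assert r["TPR"] == pytest.approx(2 / 3)
        assert r["FNR"] == pytest.approx(1 / 3)
        assert r["FPR"] == pytest.approx(1 / 3)
        assert r["TNR"] == pytest.approx(2 / 3)

    def test_rates_sum_to_one(self):
        rng = np.random.default_rng(10)
        measured = rng.normal(3, 1, 30)
        lln_vals = np.full(30, 3.0)
        estimates = measured + rng.normal(0, 0.5, 30)
        r = screening_confusion(estimates, measured, lln_vals)
        assert r["TPR"] + r["FNR"] == pytest.approx(1.0)
        assert r["FPR"] + r["TNR"] == pytest.approx(1.0)

    def test_no_positives_errors(self):
        with pytest.raises(ValueError, match="positive"):
            screening_confusion([4.0, 4.0], [4.0, 4.0], [3.0, 3.0])

    def test_score_orientation(self):
        # higher score = more abnormal; threshold 0 == 'estimate < LLN'
        s = screening_score([3.0, 2.0], [2.5, 2.5])
        assert s[0] < 0 < s[1]


class TestPartialCorrelation:
    def test_recovers_conditional_structure(self):
        rng = np.random.default_rng(11)
        z = rng.normal(size=500)
        x = z + rng.normal(0, 0.5, 500)
        y = z + rng.normal(0, 0.5, 500)
        import pandas as pd

        df = pd.DataFrame({"x": x, "y": y, "z": z})
        pc = partial_correlation_matrix(df)
        # x and y are independent given z
        assert abs(pc.loc["x", "y"]) < 0.15
        assert pc.loc["x", "z"] > 0.5
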
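import numpy as np
import pytest
from scipy import stats

from xtalfate.selection import (
    SelectionConfig,
    biserial_vector,
    cv_auc,
    point_biserial,
    redundancy_filter,
    relevance_filter,
    select_features,
    wrapper_select,
)
from xtalfate.synthetic import generate_feature_table


class TestPointBiserial:
    def test_hand_computed_example(self):
        # Pearson of [1,2,3,4] against [0,0,1,1]: 0.5 / (sqrt(1.25)*0.5)
        r = point_biserial([1, 2, 3, 4], [0, 0, 1, 1])
        assert r == pytest.approx(0.894427190999916, abs=1e-12)

    def test_self_correlation(self):
        y = [0, 1, 0, 1, 1]
        assert point_biserial(y, y) == pytest.approx(1.0)

    def test_constant_feature_falls_back_to_zero(self):
        assert point_biserial([3.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.0

    def test_single_class_labels_error(self):
        with pytest.raises(ValueError):
            point_biserial([1, 2, 3], [1, 1, 1])

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(50):
            x = rng.standard_normal(40)
            y = rng.integers(0, 2, 40)
            if np.unique(y).size < 2:
                continue
            expected = stats.pointbiserialr(y, x).statistic
            assert point_biserial(x, y) == pytest.approx(expected, abs=1e-12)

    def test_vectorized_form_matches_scalar(self, rng):
        X = rng.standard_normal((60, 15))
        X[:, 3] = 7.0  # constant column
        y = rng.integers(0, 2, 60)
        r = biserial_vector(X, y)
        for j in range(15):
            assert r[j] == pytest.approx(point_biserial(X[:, j], y), abs=1e-12)


class TestRelevanceFilter:
    X = np.zeros((4, 3))
    y = np.array([0, 0, 1, 1])

    def test_threshold_rule(self):
        # |r| = [0.9, 0.1, 0.2], mean 0.4, threshold 0.8 -> feature 0 only
        abs_r = np.array([0.9, 0.1, 0.2])
        config = SelectionConfig(min_retained=1)
        assert relevance_filter(self.X, self.y, config, abs_r=abs_r) == [0]

    def test_fallback_pads_small_survivor_sets(self):
        abs_r = np.array([0.9, 0.1, 0.2])
        config = SelectionConfig(min_retained=10)
        # only 1 primary survivor < 10 -> ranked fallback keeps min(10, 3) = 3
        assert relevance_filter(self.X, self.y, config, abs_r=abs_r) == [0, 1, 2]

    def test_identical_relevance_triggers_fallback(self):
        # threshold 2|r| > |r| keeps nothing; fallback ranks by catalog order
        abs_r = np.full(5, 0.3)
        config = SelectionConfig(min_retained=2)
        X = np.zeros((4, 5))
        assert relevance_filter(X, self.y, config, abs_r=abs_r) == [0, 1]

    def test_single_feature_kept_via_fallback(self):
        abs_r = np.array([0.4])
        assert relevance_filter(self.X[:, :1], self.y, abs_r=abs_r) == [0]


def exact_correlated_columns(R, n=24, seed=5):
    """Columns whose *sample* correlation matrix equals R exactly."""
    rng = np.random.default_rng(seed)
    k = R.shape[0]
    base = rng.standard_normal((n, k))
    base -= base.mean(axis=0)
    # Gram-Schmidt on centered columns stays centered
    for j in range(k):
        for i in range(j):
            base[:, j] -= (base[:, j] @ base[:, i]) * base[:, i]
        base[:, j] /= np.linalg.norm(base[:, j])
    return base @ np.linalg.cholesky(R).T


class TestRedundancyFilter:
    def test_identical_columns_keep_more_relevant(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([x, x])
        kept = redundancy_filter(X, [0, 1], np.array([0.5, 0.9]))
        assert kept == [1]

    def test_orthogonal_columns_all_survive(self):
        R = np.eye(3)
        X = exact_correlated_columns(R)
        kept = redundancy_filter(X, [0, 1, 2], np.array([0.9, 0.5, 0.3]))
        assert kept == [0, 1, 2]

    def test_correlation_chain(self):
        # A~B = B~C = 0.85 (> 0.7), A~C = 0.5 (<= 0.7), relevance A > B > C
        R = np.array([[1.0, 0.85, 0.5], [0.85, 1.0, 0.85], [0.5, 0.85, 1.0]])
        X = exact_correlated_columns(R)
        kept = redundancy_filter(X, [0, 1, 2], np.array([0.9, 0.8, 0.7]))
        assert kept == [0, 2]


class TestWrapper:
    def test_single_candidate_is_selected(self, rng):
        X, y = generate_feature_table(200, 3, 1, weights=[2.0], rng_seed=3)
        result = wrapper_select(X, y, [0], SelectionConfig(rng_seed=1))
        assert result.selected == (0,)
        assert result.cv_auc_trace[0].accepted

    def test_duplicated_candidate_is_rejected(self):
        X, y = generate_feature_table(300, 2, 1, weights=[2.0], rng_seed=4)
        X[:, 1] = X[:, 0]  # same information twice
        result = wrapper_select(X, y, [0, 1], SelectionConfig(rng_seed=1))
        assert result.selected == (0,)
        assert not result.cv_auc_trace[1].accepted

    def test_accepted_auc_trace_strictly_increases(self):
        X, y = generate_feature_table(400, 10, 3, weights=[2.0, -2.0, 1.5], rng_seed=6)
        result = wrapper_select(X, y, list(range(10)), SelectionConfig(rng_seed=2))
        accepted = [e.auc_after for e in result.cv_auc_trace if e.accepted]
        assert all(b > a for a, b in zip(accepted, accepted[1:]))

    def test_informative_feature_found_noise_mostly_rejected(self):
        # labels driven by one strong feature among 20 noise columns: the
        # informative feature is always kept, and each noise candidate is
        # accepted in a minority of its attempts
        hits, noise_accepts, noise_attempts = 0, 0, 0
        for seed in range(20):
            X, y = generate_feature_table(500, 21, 1, weights=[3.0], rng_seed=seed)
            r = np.abs(biserial_vector(X, y))
            ranked = sorted(range(21), key=lambda j: (-r[j], j))
            result = wrapper_select(X, y, ranked, SelectionConfig(rng_seed=seed))
            if 0 in result.selected:
                hits += 1
            noise_accepts += sum(1 for j in result.selected if j != 0)
            noise_attempts += 20
        assert hits == 20
        assert noise_accepts < 0.4 * noise_attempts

    def test_seeded_selection_is_reproducible(self):
        X, y = generate_feature_table(300, 8, 2, weights=[2.0, -1.5], rng_seed=9)
        config = SelectionConfig(rng_seed=11)
        r1 = wrapper_select(X, y, list(range(8)), config)
        r2 = wrapper_select(X, y, list(range(8)), config)
        assert r1 == r2


class TestFullPipeline:
    def test_monotone_stage_sizes_and_report(self, tmp_path):
        X, y = generate_feature_table(400, 30, 3, weights=[2.0, -2.0, 1.5], rng_seed=7)
        result = select_features(X, y, SelectionConfig(rng_seed=3))
        assert (
            len(result.selected)
            <= len(result.redundancy_survivors)
            <= len(result.relevance_survivors)
            <= 30
        )
        text = result.to_text()
        assert text.count("\n") == len(result.cv_auc_trace) + 5

    def test_cv_auc_detects_signal(self):
        X, y = generate_feature_table(400, 2, 1, weights=[3.0], rng_seed=8)
        config = SelectionConfig(rng_seed=5)
        assert cv_auc(X, y, [0], config) > 0.8
        assert abs(cv_auc(X, y, [1], config) - 0.5) < 0.15
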
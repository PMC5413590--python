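import itertools

import numpy as np
import pytest

from fewt import (
    bhattacharyya_distance,
    chernoff_distance,
    class_statistics,
    forward_select,
    lr_criterion,
    scatter_ratio,
)
from fewt.selection import _criterion_value


class TestClassStatistics:
    def test_hand_example(self):
        x = np.array([[0.0, 0.0], [2.0, 2.0], [10.0, 10.0], [12.0, 12.0]])
        y = np.array(["A", "A", "B", "B"])
        stats = class_statistics(x, y)
        np.testing.assert_allclose(stats.means[0], [1.0, 1.0])
        np.testing.assert_allclose(stats.means[1], [11.0, 11.0])
        np.testing.assert_allclose(stats.priors, [0.5, 0.5])
        np.testing.assert_allclose(stats.global_mean, [6.0, 6.0])

    def test_single_class(self, rng):
        x = rng.standard_normal((10, 2))
        stats = class_statistics(x, np.full(10, "A"))
        assert stats.n_classes == 1
        np.testing.assert_allclose(stats.priors, [1.0])
        np.testing.assert_allclose(stats.global_mean, stats.means[0])

    def test_duplication_invariance(self, rng):
        x = rng.standard_normal((12, 3))
        y = np.repeat(["A", "B"], 6)
        s1 = class_statistics(x, y)
        s2 = class_statistics(np.vstack([x, x]), np.concatenate([y, y]))
        np.testing.assert_allclose(s1.means, s2.means)
        np.testing.assert_allclose(s1.priors, s2.priors)

    def test_tiny_class_rejected(self):
        x = np.zeros((3, 1))
        with pytest.raises(ValueError):
            class_statistics(x, np.array(["A", "A", "B"]))

    def test_covariance_symmetric_psd(self, rng):
        x = rng.standard_normal((40, 4))
        y = np.repeat(["A", "B"], 20)
        stats = class_statistics(x, y)
        for cov in stats.covariances:
            np.testing.assert_allclose(cov, cov.T, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(cov) > -1e-10)


def _two_class_stats(mu1, mu2, cov1, cov2):
    """Build exact ClassStatistics without sampling."""
    from fewt.selection import ClassStatistics

    return ClassStatistics(
        classes=np.array(["A", "B"]),
        means=np.stack([np.atleast_1d(mu1), np.atleast_1d(mu2)]).astype(float),
        covariances=np.stack([np.atleast_2d(cov1), np.atleast_2d(cov2)]).astype(
            float
        ),
        priors=np.array([0.5, 0.5]),
        global_mean=(np.atleast_1d(mu1) + np.atleast_1d(mu2)) / 2.0,
    )


class TestChernoffBhattacharyya:
    def test_identical_summaries_zero(self):
        stats = _two_class_stats([0, 0], [0, 0], np.eye(2), np.eye(2))
        for beta in (0.2, 0.5, 0.8):
            assert chernoff_distance(stats, beta) == pytest.approx(0.0, abs=1e-14)

    def test_beta_half_equals_bd(self, rng):
        for _ in range(10):
            a = rng.standard_normal((3, 3))
            b = rng.standard_normal((3, 3))
            stats = _two_class_stats(
                rng.standard_normal(3),
                rng.standard_normal(3),
                a @ a.T + np.eye(3),
                b @ b.T + np.eye(3),
            )
            assert chernoff_distance(stats, 0.5) == bhattacharyya_distance(stats)

    def test_equal_covariance_closed_form(self):
        stats = _two_class_stats([0, 0], [2, 0], np.eye(2), np.eye(2))
        assert bhattacharyya_distance(stats) == pytest.approx(0.5, abs=1e-10)

    def test_one_dimensional_log_term(self):
        stats = _two_class_stats([0.0], [0.0], [[1.0]], [[4.0]])
        expected = 0.5 * np.log(2.5 / 2.0)
        assert bhattacharyya_distance(stats) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.11157, abs=1e-5)

    def test_class_swap_symmetry(self, rng):
        a = rng.standard_normal((2, 2))
        b = rng.standard_normal((2, 2))
        cov1, cov2 = a @ a.T + np.eye(2), b @ b.T + np.eye(2)
        mu1, mu2 = rng.standard_normal(2), rng.standard_normal(2)
        s12 = _two_class_stats(mu1, mu2, cov1, cov2)
        s21 = _two_class_stats(mu2, mu1, cov2, cov1)
        assert bhattacharyya_distance(s12) == pytest.approx(
            bhattacharyya_distance(s21), rel=1e-12
        )

    def test_nonnegative_zero_iff_identical(self, rng):
        for _ in range(20):
            a = rng.standard_normal((2, 2))
            cov = a @ a.T + 0.5 * np.eye(2)
            mu1 = rng.standard_normal(2)
            mu2 = mu1 + rng.standard_normal(2) * 0.5
            stats = _two_class_stats(mu1, mu2, cov, cov + 0.1 * np.eye(2))
            val = bhattacharyya_distance(stats)
            assert val >= 0
            if not np.allclose(mu1, mu2):
                assert val > 0

    def test_singular_covariances_ridged(self):
        # rank-deficient class covariances; ridge keeps it computable
        stats = _two_class_stats(
            [0, 0], [1, 1], np.zeros((2, 2)), np.zeros((2, 2))
        )
        val = bhattacharyya_distance(stats, ridge=1e-6)
        assert np.isfinite(val) and val > 0

    def test_requires_two_classes(self, rng):
        x = rng.standard_normal((10, 2))
        stats = class_statistics(x, np.full(10, "A"))
        with pytest.raises(ValueError):
            bhattacharyya_distance(stats)

    def test_beta_bounds(self):
        stats = _two_class_stats([0], [1], [[1.0]], [[1.0]])
        with pytest.raises(ValueError):
            chernoff_distance(stats, 0.0)


class TestScatterRatio:
    def test_hand_example(self):
        x = np.array([-1.0, 1.0, 9.0, 11.0])
        y = np.array(["A", "A", "B", "B"])
        assert scatter_ratio(x[:, None], y) == pytest.approx(25.0, abs=1e-12)

    def test_identical_means_zero(self, rng):
        x = np.array([[-1.0], [1.0], [-2.0], [2.0]])
        y = np.array(["A", "A", "B", "B"])
        assert scatter_ratio(x, y) == pytest.approx(0.0, abs=1e-14)

    def test_orthogonal_invariance(self, rng):
        x = rng.standard_normal((30, 4))
        y = np.repeat(["A", "B", "C"], 10)
        base = scatter_ratio(x, y)
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        assert scatter_ratio(x @ q, y) == pytest.approx(base, abs=1e-9)

    def test_zero_within_scatter_rejected(self):
        x = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array(["A", "A", "B", "B"])
        with pytest.raises(ValueError):
            scatter_ratio(x, y)

    def test_nonnegative(self, rng):
        for _ in range(10):
            x = rng.standard_normal((20, 3))
            y = rng.choice(["A", "B"], size=20)
            if len(np.unique(y)) < 2:
                continue
            assert scatter_ratio(x, y) >= 0


class TestLrCriterion:
    def test_exact_linear_fit(self, rng):
        x = rng.standard_normal((30, 3))
        y = 2.0 + x @ np.array([1.0, -2.0, 0.5])
        assert lr_criterion(x, y) == pytest.approx(1.0, abs=1e-10)

    def test_constant_feature_zero(self, rng):
        x = np.ones((20, 1))
        y = rng.standard_normal(20)
        assert lr_criterion(x, y) == pytest.approx(0.0, abs=1e-10)

    def test_population_r2(self):
        rng = np.random.default_rng(7)
        n = 500
        f1 = rng.standard_normal(n)
        sigma = 0.8
        y = f1 + sigma * rng.standard_normal(n)
        expected = 1.0 / (1.0 + sigma**2)
        assert lr_criterion(f1[:, None], y) == pytest.approx(expected, abs=0.05)

    def test_bounded_random_instances(self, rng):
        for _ in range(1000):
            n = int(rng.integers(8, 30))
            k = int(rng.integers(1, min(5, n - 2)))
            x = rng.standard_normal((n, k))
            y = rng.standard_normal(n)
            val = lr_criterion(x, y)
            assert 0.0 <= val <= 1.0

    def test_constant_target_rejected(self, rng):
        with pytest.raises(ValueError):
            lr_criterion(rng.standard_normal((10, 2)), np.ones(10))

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            lr_criterion(rng.standard_normal((4, 4)), rng.standard_normal(4))


def _separable_dataset(seed=0, n=60, n_noise=7):
    rng = np.random.default_rng(seed)
    y = np.repeat(["A", "B"], n // 2)
    informative = np.where(y == "A", -1.0, 1.0) + 0.05 * rng.standard_normal(n)
    noise = rng.standard_normal((n, n_noise))
    x = np.column_stack([noise[:, :3], informative, noise[:, 3:]])
    return x, y, 3  # informative column index


class TestForwardSelect:
    @pytest.mark.parametrize("criterion", ["bd", "sr", "lr"])
    def test_informative_column_first(self, criterion):
        x, y, informative = _separable_dataset()
        result = forward_select(x, y, criterion, k=3)
        assert result.ranked_indices[0] == informative

    def test_full_k_is_permutation(self, rng):
        x = rng.standard_normal((40, 5))
        y = np.repeat(["A", "B"], 20)
        result = forward_select(x, y, "sr", k=5)
        assert sorted(result.ranked_indices) == list(range(5))
        assert len(result.criterion_trace) == 5

    def test_k1_matches_exhaustive_argmax(self, rng):
        x = rng.standard_normal((30, 6))
        y = np.repeat(["A", "B"], 15)
        x[:, 2] += np.where(y == "A", 0.0, 1.5)
        for criterion in ("bd", "sr", "lr"):
            result = forward_select(x, y, criterion, k=1)
            vals = [
                _criterion_value(criterion, x[:, [j]], y, None) for j in range(6)
            ]
            assert result.ranked_indices[0] == int(np.argmax(vals))

    @pytest.mark.parametrize("criterion", ["bd", "sr", "lr"])
    def test_greedy_trace_matches_brute_force(self, criterion, rng):
        # <= 6 columns, k <= 3: replay the greedy search exhaustively
        x = rng.standard_normal((40, 6))
        y = np.repeat(["A", "B"], 20)
        x[:, 1] += np.where(y == "A", 0.0, 1.0)
        x[:, 4] += np.where(y == "A", 0.5, 0.0)
        result = forward_select(x, y, criterion, k=3)
        selected = []
        for step in range(3):
            best_col, best_val = None, -np.inf
            for col in range(6):
                if col in selected:
                    continue
                try:
                    val = _criterion_value(
                        criterion, x[:, selected + [col]], y, None
                    )
                except (ValueError, np.linalg.LinAlgError):
                    continue
                if val > best_val:
                    best_col, best_val = col, val
            selected.append(best_col)
            assert result.ranked_indices[step] == best_col
            assert result.criterion_trace[step] == pytest.approx(best_val)

    def test_duplicate_column_adds_nothing_under_sr(self):
        x, y, informative = _separable_dataset(seed=3)
        x = np.column_stack([x, x[:, informative]])  # exact duplicate at the end
        dup = x.shape[1] - 1
        result = forward_select(x, y, "sr", k=x.shape[1])
        assert result.ranked_indices[0] in (informative, dup)
        first_val = result.criterion_trace[0]
        dup_pos = result.ranked_indices.index(
            dup if result.ranked_indices[0] == informative else informative
        )
        # whenever the duplicate enters, the criterion gains ~nothing over
        # the step before it
        prev = result.criterion_trace[dup_pos - 1]
        gain = result.criterion_trace[dup_pos] - prev
        assert gain < 1e-9 * max(1.0, abs(first_val))

    def test_k_bounds(self, rng):
        x = rng.standard_normal((10, 3))
        y = np.repeat(["A", "B"], 5)
        with pytest.raises(ValueError):
            forward_select(x, y, "sr", k=4)
        with pytest.raises(ValueError):
            forward_select(x, y, "nope", k=1)
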
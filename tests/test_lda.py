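import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from mrsport.core_data import ValidationError
from mrsport.lda import (
    FisherLDA,
    ScoreCalibrator,
    VoxelScores,
    calibrate_scores,
    fit_lda,
    predict_lda,
    render_score_map,
    roc_auc,
    sport_score,
    two_layer_predict,
)


def _two_class(seed, n=40, p=10, delta=0.8):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, p)), rng.normal(delta, 1, (n, p))])
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestFisherFit:
    def test_equal_means_zero_between_scatter(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(30, 5))
        X = np.vstack([base, base])  # identical class distributions
        y = np.array(["a"] * 30 + ["b"] * 30)
        m = fit_lda(X, y)
        assert np.allclose(m.scatter_between_, 0, atol=1e-12)
        assert m.fisher_criterion(rng.normal(size=5)) == pytest.approx(0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_class_direction_matches_closed_form(self, seed):
        X, y = _two_class(seed)
        m = fit_lda(X, y)
        Sreg = m.scatter_within_ + m.ridge_ * np.eye(X.shape[1])
        d = np.linalg.solve(Sreg, m.means_[0] - m.means_[1])
        cos = abs(d @ m.scalings_[:, 0]) / np.linalg.norm(d)
        assert cos >= 0.999

    def test_three_separated_gaussians_high_accuracy(self):
        rng = np.random.default_rng(1)
        centers = np.array([[0, 0, 0], [6, 0, 0], [0, 6, 0]], dtype=float)
        X = np.vstack([c + rng.normal(0, 1, (50, 3)) for c in centers])
        y = np.repeat(["a", "b", "c"], 50)
        m = fit_lda(X, y)
        assert np.mean(m.predict(X) == y) >= 0.99

    def test_undersized_class_named_in_error(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValidationError, match="'b'"):
            fit_lda(X, y)

    def test_local_optimality_of_discriminant(self):
        """Fisher criterion at w beats 100 random unit directions."""
        X, y = _two_class(3)
        m = fit_lda(X, y)
        s_star = m.fisher_criterion(m.scalings_[:, 0])
        rng = np.random.default_rng(0)
        for _ in range(100):
            w = rng.normal(size=X.shape[1])
            assert s_star >= m.fisher_criterion(w / np.linalg.norm(w))


class TestPredict:
    def test_class_mean_classified_as_its_class(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(i * 4, 1, (30, 4)) for i in range(3)])
        y = np.repeat(["a", "b", "c"], 30)
        m = fit_lda(X, y)
        assert list(m.predict(m.means_)) == ["a", "b", "c"]

    def test_probabilities_sum_to_one(self):
        X, y = _two_class(4)
        scores = predict_lda(fit_lda(X, y), X)
        assert np.allclose(scores.probabilities.sum(axis=1), 1.0, atol=1e-8)

    def test_matches_density_evaluation_oracle(self):
        """Softmax probabilities equal normalized Gaussian densities."""
        from scipy.stats import multivariate_normal

        X, y = _two_class(5, p=6)
        m = fit_lda(X, y)
        pts = np.random.default_rng(9).normal(size=(10, 6))
        probs = m.predict_proba(pts)
        Z = pts @ m.scalings_
        dens = np.stack([
            multivariate_normal.pdf(Z, mean=m.proj_means_[i], cov=m.proj_cov_)
            for i in range(len(m.classes_))], axis=1)
        assert np.allclose(probs, dens / dens.sum(1, keepdims=True), atol=1e-8)

    def test_shape_mismatch_rejected(self):
        X, y = _two_class(0)
        m = fit_lda(X, y)
        with pytest.raises(ValidationError):
            m.predict(X[:, :5])


class TestCalibration:
    def _scores(self, seed=0, n=50, c=3):
        rng = np.random.default_rng(seed)
        s = rng.normal(2, 3, (n, c))
        p = np.exp(s) / np.exp(s).sum(1, keepdims=True)
        return VoxelScores(classes=tuple("abc"[:c]), scores=s, probabilities=p)

    def test_reference_becomes_standard_normal(self):
        cal, fitted = calibrate_scores(self._scores())
        assert np.allclose(cal.scores.mean(0), 0, atol=1e-8)
        assert np.allclose(cal.scores.std(0), 1, atol=1e-8)

    def test_stored_calibration_is_deterministic_on_reuse(self):
        scores = self._scores(1)
        _, fitted = calibrate_scores(scores)
        a = fitted.transform(scores)
        b = fitted.transform(scores)
        assert np.array_equal(a.scores, b.scores)

    def test_rankings_preserved_within_class(self):
        scores = self._scores(2)
        cal, _ = calibrate_scores(scores)
        for j in range(3):
            assert np.array_equal(np.argsort(scores.scores[:, j]),
                                  np.argsort(cal.scores[:, j]))

    def test_zero_variance_rejected(self):
        s = VoxelScores(("a", "b"), np.ones((20, 2)), np.full((20, 2), 0.5))
        with pytest.raises(ValidationError):
            ScoreCalibrator().fit(s)

    def test_small_reference_rejected(self):
        s = self._scores(n=5)
        with pytest.raises(ValidationError):
            ScoreCalibrator().fit(s)


class TestSportScore:
    def _vs(self, S):
        S = np.asarray(S, dtype=float)
        p = np.full_like(S, 1.0 / S.shape[1])
        return VoxelScores(tuple("abc"[:S.shape[1]]), S, p)

    def test_identical_voxels_return_their_vector(self):
        sc = sport_score(self._vs([[1.0, 2.0, 3.0]] * 6))
        assert sc == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_single_voxel(self):
        assert sport_score(self._vs([[0.5, -0.25]])) == {"a": 0.5, "b": -0.25}

    def test_matches_hand_summed_mean(self):
        rows = [[1, 0], [2, 1], [3, -1], [4, 2], [5, 0], [6, 1], [7, 4]]
        sc = sport_score(self._vs(rows))
        assert sc["a"] == pytest.approx(sum(r[0] for r in rows) / 7)
        assert sc["b"] == pytest.approx(sum(r[1] for r in rows) / 7)

    def test_empty_voxel_set_is_explicit_error(self):
        with pytest.raises(ValidationError, match="empty voxel set"):
            sport_score(self._vs(np.zeros((0, 2))))


class TestTwoLayer:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        nam = rng.normal(0, 1, (60, 8))
        tum = rng.normal(5, 1, (60, 8))
        X1 = np.vstack([nam, tum])
        y1 = np.array(["NAM"] * 60 + ["TUMOR"] * 60)
        layer1 = fit_lda(X1, y1)
        wt = rng.normal([5] * 4 + [8] * 4, 1, (40, 8))
        idh = rng.normal([8] * 4 + [5] * 4, 1, (40, 8))
        X2 = np.vstack([wt, idh])
        y2 = np.array(["wt"] * 40 + ["IDH"] * 40)
        layer2 = fit_lda(X2, y2)
        return layer1, layer2, rng

    def test_pure_nam_study_yields_no_tumor(self):
        layer1, layer2, rng = self._setup()
        Xnam = rng.normal(0, 1, (50, 8))
        pred = two_layer_predict(layer1, layer2, Xnam)
        assert pred.no_tumor_detected and pred.sport_scores is None
        assert pred.tumor_mask.sum() == 0

    def test_tumor_study_scored_and_argmaxed(self):
        layer1, layer2, rng = self._setup(1)
        Xwt = rng.normal([5] * 4 + [8] * 4, 1, (30, 8))
        pred = two_layer_predict(layer1, layer2, Xwt)
        assert pred.predicted == "wt"
        assert pred.tumor_mask.sum() > 20
        assert set(pred.sport_scores) == {"wt", "IDH"}


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_equal_scores_give_half(self):
        assert roc_auc([1.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2, 3], [1, 1, 1])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from([0.0, 0.25, 0.5, 1.0]),
                    min_size=2, max_size=8),
           st.integers(0, 2**8 - 2))
    def test_matches_pair_counting_and_sklearn(self, scores, label_bits):
        labels = [(label_bits >> i) & 1 for i in range(len(scores))]
        if sum(labels) in (0, len(labels)):
            labels[0] = 1 - labels[0]
        auc = roc_auc(scores, labels)
        # brute-force pair counting with half-credit ties
        num = total = 0
        for i, (si, li) in enumerate(zip(scores, labels)):
            for sj, lj in zip(scores, labels):
                if li == 1 and lj == 0:
                    total += 1
                    num += 1.0 if si > sj else (0.5 if si == sj else 0.0)
        assert auc == pytest.approx(num / total, abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestScoreMap:
    def test_constant_scores_constant_grid(self):
        grid = render_score_map(np.ones(4), [0, 0, 1, 1], [0, 1, 0, 1], 2, 2)
        assert np.all(grid == 1.0)

    def test_grid_shape_and_missing_voxels(self):
        grid = render_score_map(np.array([0.3]), [2], [5], 4, 8)
        assert grid.shape == (4, 8)
        assert np.isnan(grid).sum() == 31 and grid[2, 5] == 0.3

    def test_voxel_to_pixel_roundtrip(self, rng):
        order = rng.permutation(12)
        rows = np.repeat(np.arange(3), 4)[order]
        cols = np.tile(np.arange(4), 3)[order]
        vals = rng.random(12)
        grid = render_score_map(vals, rows, cols, 3, 4)
        for v, r, c in zip(vals, rows, cols):
            assert grid[r, c] == v
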
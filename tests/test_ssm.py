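import numpy as np
import pytest

from morphanat.io import SubjectCharacteristics
from morphanat.ssm import (
    CharacteristicRegression,
    LandmarkShapeModel,
    align_landmarks,
    fit_characteristic_regression,
    fit_pca,
    predict_landmarks,
    sample_design_grid,
)
from morphanat.synthetic import PopulationSpec, generate_population


def _rotation(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


class TestAlignment:
    def test_identical_arrays_zero_variance(self, rng):
        a = rng.normal(size=(10, 3))
        aligned, _ = align_landmarks([a, a.copy(), a.copy()])
        assert np.abs(np.var(np.stack(aligned), axis=0)).max() < 1e-18

    def test_rotated_copy_coincides(self, rng):
        a = rng.normal(size=(12, 3)) * 50
        R = _rotation([1, 2, 3], 0.7)
        b = a @ R.T + np.array([5.0, -3.0, 2.0])
        aligned, _ = align_landmarks([a, b])
        assert np.abs(aligned[0] - aligned[1]).max() < 1e-9

    def test_scale_difference_preserved(self, rng):
        a = rng.normal(size=(8, 3)) * 30
        b = 1.1 * a
        aligned, _ = align_landmarks([a, b])
        def size(x):
            return np.linalg.norm(x - x.mean(axis=0))
        assert size(aligned[1]) / size(aligned[0]) == pytest.approx(1.1, abs=1e-9)

    def test_collinear_raises(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            align_landmarks([line, line])

    def test_none_mode_is_identity(self, rng):
        a = rng.normal(size=(6, 3))
        aligned, transforms = align_landmarks([a], mode="none")
        assert np.array_equal(aligned[0], a)
        R, t = transforms[0]
        assert np.array_equal(R, np.eye(3)) and np.array_equal(t, np.zeros(3))


class TestPCA:
    def test_identical_subjects_zero_spectrum(self, rng):
        a = rng.normal(size=(10, 3))
        model = fit_pca([a] * 5, k=2)
        assert np.abs(model.explained_variance_).max() < 1e-20
        assert np.abs(model.scores_).max() < 1e-9

    def test_single_direction_matches_eigensolve(self, rng):
        # brute-force oracle: eigen-decomposition of the 3m x 3m covariance
        base = rng.normal(size=(7, 3))
        direction = rng.normal(size=(7, 3))
        direction /= np.linalg.norm(direction)
        arrays = [base + c * direction for c in (-1.0, 0.5, 0.5)]
        model = fit_pca(arrays, k=2)
        X = np.stack([a.ravel() for a in arrays])
        cov = np.cov(X.T, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert model.explained_variance_[0] == pytest.approx(evals[0], rel=1e-10)
        assert model.explained_variance_[1] == pytest.approx(0.0, abs=1e-12)
        # scores equal the centered data projected onto the top eigenvector
        ev = np.linalg.eigh(cov)[1][:, -1]
        expected = (X - X.mean(axis=0)) @ ev
        got = model.scores_[:, 0]
        assert np.allclose(np.abs(got), np.abs(expected), atol=1e-9)

    def test_population_scale_shapes(self, noiseless_population):
        model = fit_pca(noiseless_population.landmarks, k=40)
        assert model.scores_.shape == (124, 40)
        assert model.basis_.shape == (3 * 69, 40)

    def test_basis_orthonormal_scores_centered(self, noiseless_population):
        model = fit_pca(noiseless_population.landmarks, k=10)
        gram = model.basis_.T @ model.basis_
        assert np.abs(gram - np.eye(10)).max() < 1e-8
        assert np.abs(model.scores_.mean(axis=0)).max() < 1e-8
        assert (np.diff(model.explained_variance_) <= 1e-12).all()

    def test_full_rank_reconstruction_identity(self, rng):
        arrays = [rng.normal(size=(5, 3)) for _ in range(6)]
        model = fit_pca(arrays, k=5)  # k = n - 1
        assert model.reconstruction_error(arrays) < 1e-8

    def test_k_out_of_range(self, rng):
        arrays = [rng.normal(size=(5, 3)) for _ in range(4)]
        with pytest.raises(ValueError, match="n_components"):
            fit_pca(arrays, k=4)

    def test_translation_changes_only_mean(self, rng):
        arrays = [rng.normal(size=(6, 3)) for _ in range(8)]
        shifted = [a + np.array([10.0, -4.0, 2.0]) for a in arrays]
        m1 = fit_pca(arrays, k=3)
        m2 = fit_pca(shifted, k=3)
        assert np.allclose(m1.scores_, m2.scores_, atol=1e-9)
        assert np.allclose(
            m2.mean_shape_.reshape(-1, 3) - m1.mean_shape_.reshape(-1, 3),
            [10.0, -4.0, 2.0], atol=1e-9,
        )


class TestRegression:
    def test_zero_scores_give_zero_coefficients(self, rng):
        a = rng.normal(size=(8, 3))
        model = fit_pca([a] * 6, k=2)
        chars = np.column_stack([
            [0, 1, 0, 1, 0, 1],
            rng.uniform(20, 80, 6),
            rng.uniform(1.5, 1.9, 6),
            rng.uniform(18, 30, 6),
        ])
        reg = fit_characteristic_regression(model, chars)
        assert np.abs(reg.coef_).max() < 1e-9
        assert np.abs(reg.residuals_).max() < 1e-9

    def test_small_system_matches_normal_equations(self, rng):
        arrays = [rng.normal(size=(4, 3)) for _ in range(5)]
        model = fit_pca(arrays, k=1)
        chars = np.column_stack([
            [0, 1, 0, 1, 1],
            rng.uniform(20, 80, 5),
            rng.uniform(1.5, 1.9, 5),
            rng.uniform(18, 30, 5),
        ])
        reg = fit_characteristic_regression(model, chars)
        # independent normal-equations solve
        Xc = (chars - chars.mean(axis=0)) / chars.std(axis=0)
        A_oracle = np.linalg.solve(Xc.T @ Xc, Xc.T @ model.scores_).T
        assert np.allclose(reg.coef_, A_oracle, atol=1e-8)
        assert np.abs(reg.residuals_.mean(axis=0)).max() < 1e-8

    def test_constant_column_raises_named_error(self, rng):
        arrays = [rng.normal(size=(4, 3)) for _ in range(6)]
        model = fit_pca(arrays, k=2)
        chars = np.column_stack([
            np.zeros(6), rng.uniform(20, 80, 6),
            rng.uniform(1.5, 1.9, 6), rng.uniform(18, 30, 6),
        ])
        with pytest.raises(ValueError, match="gender"):
            fit_characteristic_regression(model, chars)

    def test_noiseless_recovery_of_true_effects(self, noiseless_population):
        pop = noiseless_population
        model = LandmarkShapeModel(n_components=40, align="none").fit(pop.landmarks)
        reg = CharacteristicRegression().fit(model, pop.characteristic_matrix)
        recovered = model.basis_ @ reg.raw_coef_
        truth = pop.true_effects_raw
        rel = np.linalg.norm(recovered - truth) / np.linalg.norm(truth)
        assert rel < 1e-8

    def test_recovery_error_decreases_with_noise(self):
        errs = []
        for sigma in (2.0, 0.2, 0.0):
            pop = generate_population(PopulationSpec(noise_sigma=sigma, seed=11))
            model = LandmarkShapeModel(n_components=40, align="none").fit(pop.landmarks)
            reg = CharacteristicRegression().fit(model, pop.characteristic_matrix)
            rec = model.basis_ @ reg.raw_coef_
            errs.append(np.linalg.norm(rec - pop.true_effects_raw)
                        / np.linalg.norm(pop.true_effects_raw))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.01


class TestPrediction:
    def test_mean_characteristics_predict_mean_shape(self, noiseless_population):
        pop = noiseless_population
        model = LandmarkShapeModel(n_components=10, align="none").fit(pop.landmarks)
        reg = CharacteristicRegression().fit(model, pop.characteristic_matrix)
        pred = predict_landmarks(model, reg, pop.characteristic_matrix.mean(axis=0))
        assert np.allclose(pred.ravel(), model.mean_shape_, atol=1e-9)

    def test_noiseless_prediction_matches_ground_truth(self, noiseless_population):
        pop = noiseless_population
        model = LandmarkShapeModel(n_components=40, align="none").fit(pop.landmarks)
        reg = CharacteristicRegression().fit(model, pop.characteristic_matrix)
        pred = predict_landmarks(model, reg, pop.characteristics[5])
        assert np.abs(pred - pop.landmarks[5]).max() < 1e-6

    def test_extrapolation_warns(self, noiseless_population):
        pop = noiseless_population
        model = LandmarkShapeModel(n_components=5, align="none").fit(pop.landmarks)
        reg = CharacteristicRegression().fit(model, pop.characteristic_matrix)
        with pytest.warns(UserWarning, match="outside training"):
            predict_landmarks(model, reg, np.array([1.0, 150.0, 1.7, 25.0]))

    def test_batch_prediction_over_grid(self, noiseless_population):
        pop = noiseless_population
        model = LandmarkShapeModel(n_components=10, align="none").fit(pop.landmarks)
        reg = CharacteristicRegression().fit(model, pop.characteristic_matrix)
        grid = sample_design_grid()
        preds = [predict_landmarks(model, reg, c) for c in grid]
        assert len(preds) == 200
        assert all(p.shape == (69, 3) for p in preds)


class TestDesignGrid:
    def test_default_grid_yields_200(self):
        grid = sample_design_grid()
        assert len(grid) == 200
        assert len({c.gender for c in grid}) == 2
        assert len({c.age for c in grid}) == 5
        assert len({c.height for c in grid}) == 5
        assert len({c.bmi for c in grid}) == 4

    def test_single_level_axes_sit_at_midpoints(self):
        grid = sample_design_grid(counts=(1, 1, 1), gender_levels=(0,))
        assert len(grid) == 1
        c = grid[0]
        assert c.age == pytest.approx(50.0)
        assert c.height == pytest.approx(1.7)
        assert c.bmi == pytest.approx(25.0)

    def test_2x2x2x2_grid_has_all_extremes(self):
        grid = sample_design_grid(counts=(2, 2, 2))
        assert len(grid) == 16
        ages = {c.age for c in grid}
        assert ages == {10.0, 90.0}
        combos = {(c.gender, c.age, c.height, c.bmi) for c in grid}
        assert len(combos) == 16

    def test_infeasible_total_raises_with_factorizations(self):
        with pytest.raises(ValueError, match="factorizations"):
            sample_design_grid(counts=(3, 3, 3), total=200)
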
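"""PVS estimator: z-map, thresholding, regularized inverse, scoring, CV."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import polyvoxel as pv
from polyvoxel.datatypes import EmptyModelError, InputError, MatrixContractError
from polyvoxel.pvs import UnivariateStats, threshold_voxels


def _stats_from_z(z):
    z = np.asarray(z, float)
    p = 2 * stats.norm.sf(np.abs(z))
    return UnivariateStats(z=z, p=p, retained=np.zeros(len(z), bool))


class TestUnivariateZ:
    def test_closed_form_four_point_example(self):
        # x=(1,2,3,4), y=(0,0,1,1): r=0.894, slope t=2.828 at df=2
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0, 0, 1, 1])
        out = pv.univariate_z(X, y)
        r = 2.0 / np.sqrt(5.0)
        t = r * np.sqrt(2.0 / (1.0 - r**2))
        np.testing.assert_allclose(t, 2.8284271, atol=1e-6)
        p = 2 * stats.t.sf(t, 2)
        z_expected = stats.norm.isf(p / 2)
        np.testing.assert_allclose(out.z[0], z_expected, atol=1e-10)
        np.testing.assert_allclose(out.p[0], p, atol=1e-12)

    def test_orthogonal_column_gives_zero(self):
        y = np.array([0, 0, 1, 1])
        X = np.array([[1.0], [-1.0], [1.0], [-1.0]])  # orthogonal to y - mean
        out = pv.univariate_z(X, y)
        np.testing.assert_allclose(out.z[0], 0.0, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 6))
        y = rng.integers(0, 2, size=40)
        y[0], y[1] = 0, 1  # both classes
        perm = rng.permutation(40)
        a = pv.univariate_z(X, y)
        b = pv.univariate_z(X[perm], y[perm])
        np.testing.assert_allclose(a.z, b.z, atol=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            pv.univariate_z(np.ones((5, 2)), np.zeros(5))


class TestThreshold:
    def test_two_sided_boundary_at_default(self):
        # Phi^-1(0.995) = 2.5758: |z|=2.58 retained, 2.57 excluded
        ustats = _stats_from_z([0.0, 2.57, 2.58, -2.58, -3.5])
        retained = threshold_voxels(ustats, p_thresh=0.01)
        assert retained.tolist() == [False, False, True, True, True]

    def test_threshold_one_retains_all(self):
        ustats = _stats_from_z([0.0, 0.1, -5.0])
        assert threshold_voxels(ustats, p_thresh=1.0000001).all()

    def test_empty_model_error(self):
        with pytest.raises(EmptyModelError):
            threshold_voxels(_stats_from_z([0.0, 0.5]), p_thresh=0.01)


class TestRegularizedInverse:
    def test_identity_any_rank(self):
        for r in (1, 2, 5):
            np.testing.assert_allclose(
                pv.regularized_inverse(np.eye(5), r), np.eye(5), atol=1e-12
            )

    def test_2x2_rank1_closed_form(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        # eigenvalues (1.6, 0.4); S_1 = diag(1.6, 1.6) -> 0.625 * I
        np.testing.assert_allclose(
            pv.regularized_inverse(R, 1), 0.625 * np.eye(2), atol=1e-12
        )

    def test_2x2_full_rank_exact_inverse(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        expected = np.array([[1.5625, -0.9375], [-0.9375, 1.5625]])
        np.testing.assert_allclose(pv.regularized_inverse(R, 2), expected, atol=1e-12)

    def test_full_rank_matches_direct_solve(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = rng.integers(3, 40)
            A = rng.normal(size=(m + 30, m))
            R = np.corrcoef(A, rowvar=False)
            z = rng.normal(size=m)
            w = pv.fit_weights(z, R, m)
            direct = np.linalg.solve(R, z)
            err = np.linalg.norm(w - direct) / np.linalg.norm(direct)
            assert err < 1e-8

    def test_condition_number_bounded_by_floor(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(50, 10)) @ (np.eye(10) + 0.5 * np.ones((10, 10)))
        R = np.corrcoef(A, rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(R))[::-1]
        for r in (1, 3, 10):
            inv = pv.regularized_inverse(R, r)
            cond = np.linalg.cond(inv)
            assert np.isfinite(cond)
            assert cond <= evals[0] / evals[r - 1] * (1 + 1e-8)

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[1.0, 0.5], [0.1, 1.0]]),  # asymmetric
            np.array([[2.0, 0.5], [0.5, 2.0]]),  # wrong diagonal
            np.ones((2, 3)),  # not square
        ],
    )
    def test_contract_violations_rejected(self, bad):
        with pytest.raises(MatrixContractError):
            pv.regularized_inverse(bad, 1)

    def test_rank_below_one_rejected(self):
        with pytest.raises(InputError):
            pv.regularized_inverse(np.eye(3), 0)


class TestFitWeights:
    def test_identity_returns_z_for_every_rank(self):
        z = np.array([1.5, -0.3, 0.8])
        for r in (1, 2, 3):
            np.testing.assert_allclose(pv.fit_weights(z, np.eye(3), r), z, atol=1e-12)

    def test_2x2_closed_forms(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        z = np.array([1.0, 0.0])
        np.testing.assert_allclose(pv.fit_weights(z, R, 1), [0.625, 0.0], atol=1e-12)
        np.testing.assert_allclose(
            pv.fit_weights(z, R, 2), [1.5625, -0.9375], atol=1e-12
        )


class TestScore:
    def _model(self, weights, n_voxels):
        idx = np.arange(len(weights))
        spec = pv.TransformSpec(
            train_sorted=np.zeros((2, n_voxels)),
            train_mapped=np.zeros((2, n_voxels)),
            coef=np.zeros((1, n_voxels)),
            design_columns=["intercept"],
            scanner_levels=["sc0"],
        )
        return pv.PVSModel(
            retained_idx=idx, z=np.asarray(weights, float), r=1,
            weights=np.asarray(weights, float), spec=spec,
        )

    def test_arithmetic_example(self):
        model = self._model([1.0, -1.0], 2)
        out = pv.score(np.array([[2.0, 3.0]]), model)
        np.testing.assert_allclose(out, [-1.0])

    def test_linear_in_weights(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        m1 = self._model(rng.normal(size=4), 4)
        m2 = dataclasses.replace(m1, weights=3.5 * m1.weights)
        np.testing.assert_allclose(pv.score(X, m2), 3.5 * pv.score(X, m1), atol=1e-12)

    def test_identity_model_matches_dot_product_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 5))
        z = rng.normal(size=5)
        w = pv.fit_weights(z, np.eye(5), 5)  # identity R -> w = z
        model = self._model(w, 5)
        out = pv.score(X, model)
        oracle = np.array([sum(X[i, v] * z[v] for v in range(5)) for i in range(10)])
        np.testing.assert_allclose(out, oracle, atol=1e-10)


class TestCrossval:
    def test_perfect_separation_auc_one_everywhere(self):
        # every voxel carries the pattern and there is no noise or confound:
        # held-out scores order subjects exactly by latent iron
        cfg = pv.GeneratorConfig(
            n_subjects=200, n_voxels=40, n_pattern_voxels=40,
            homozygote_rate=0.25, heterozygote_rate=0.0,
            archetype_effect=3.0, noise_sd=0.0,
            covariate_effects=(0.0,) * 13, covariate_image_sd=0.0, seed=21,
        )
        study = pv.simulate_all(cfg)
        y = (study.subjects["genotype_class"] == "homozygote").to_numpy(int)
        cv = pv.crossval_select_r(
            study.t2w.data, study.subjects, y,
            grid=(1, 5, "M"), k=3, seed=0,
        )
        np.testing.assert_allclose(cv.auc, 1.0)
        # ties break to the smallest grid value
        assert (cv.fold_optima == 1).all()
        assert cv.selected_r == 1

    def test_regularization_beats_no_regularization_under_correlation(self):
        """With few samples and correlated voxels, some r < M should match
        or beat the unregularized r = M on held-out AUC (Monte Carlo)."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = pv.GeneratorConfig(
                n_subjects=150, n_voxels=80, n_pattern_voxels=40,
                homozygote_rate=0.3, heterozygote_rate=0.0,
                archetype_effect=1.0, spatial_corr=0.9, seed=seed,
            )
            study = pv.simulate_all(cfg)
            y = (study.subjects["genotype_class"] == "homozygote").to_numpy(int)
            cv = pv.crossval_select_r(
                study.t2w.data, study.subjects, y, grid=(1, 5, 20, "M"),
                k=3, seed=seed,
            )
            mean_auc = cv.auc.mean(axis=0)
            if mean_auc[:-1].max() >= mean_auc[-1]:
                wins += 1
        assert wins / n_seeds >= 0.8

    def test_single_class_fold_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        with pytest.raises(InputError):
            pv.crossval_select_r(X, pd.DataFrame(), np.zeros(10), k=2)


class TestFitPVS:
    def test_refit_is_deterministic(self, tiny_study, labelled_subjects):
        table_a = labelled_subjects[labelled_subjects["subsample"] == "A"]
        table_a = table_a.reset_index(drop=True)
        y = (table_a["genotype_class"] == "homozygote").to_numpy(int)
        images = tiny_study.t2w.select_subjects(table_a["subject_id"])
        m1 = pv.fit_pvs(images, table_a, y, r=10, seed=0)
        m2 = pv.fit_pvs(images, table_a, y, r=10, seed=0)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(m1.retained_idx, m2.retained_idx)

    def test_null_retained_count_binomially_calibrated(self):
        cfg = pv.GeneratorConfig(
            n_subjects=300, n_voxels=2000, n_pattern_voxels=10,
            homozygote_rate=0.3, archetype_effect=0.0, spatial_corr=0.0,
            covariate_effects=(0.0,) * 13, seed=17,
        )
        study = pv.simulate_all(cfg)
        y = (study.subjects["genotype_class"] == "homozygote").to_numpy(int)
        model = pv.fit_pvs(study.t2w, study.subjects, y, r=1)
        lo, hi = stats.binom.interval(0.95, 2000, 0.01)
        assert lo <= len(model.retained_idx) <= hi

    def test_orientation_convention(self, tiny_study, fitted_model, labelled_subjects):
        """Mean training homozygote score exceeds mean control score."""
        table_a = labelled_subjects[labelled_subjects["subsample"] == "A"]
        table_a = table_a.reset_index(drop=True)
        y = (table_a["genotype_class"] == "homozygote").to_numpy(int)
        images = tiny_study.t2w.select_subjects(table_a["subject_id"])
        scores = pv.score_images(fitted_model, images, table_a)
        assert scores[y == 1].mean() > scores[y == 0].mean()

    def test_save_load_round_trip(self, fitted_model, tmp_path):
        path = tmp_path / "model.npz"
        fitted_model.save(path)
        loaded = pv.PVSModel.load(path)
        np.testing.assert_array_equal(loaded.weights, fitted_model.weights)
        np.testing.assert_array_equal(loaded.retained_idx, fitted_model.retained_idx)
        np.testing.assert_array_equal(
            loaded.spec.train_sorted, fitted_model.spec.train_sorted
        )
        assert loaded.meta["n_retained"] == fitted_model.meta["n_retained"]
        assert loaded.spec.scanner_levels == fitted_model.spec.scanner_levels
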